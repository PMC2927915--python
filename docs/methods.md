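# Methods

## The forward allosteric model

All estimators in this package invert terms of one log-linear model of the
half-saturation pressure P50 of hemoglobin (or whole blood):

    log10 P50(c) = log10 P50_ref
                 + φ · (pH − pH_ref)
                 + k_Cl · (log10[Cl−] − log10[Cl−]_ref)
                 + ΔlogP50_DPG · (occ(r) − occ(r_ref)),  occ(r) = min(1, r/50)
                 + (ΔH_app / (ln10 · R)) · (1/T − 1/T_ref)

with T in kelvin (T_K = T_C + 273.15), R = 8.314 J mol⁻¹ K⁻¹, and
ΔH_app = ΔH_corr + ΔH_sol where ΔH_sol = −12.5 kJ per mol O2 is the heat of
O2 solubilization. Saturation at a given PO2 follows the Hill equation with
a single cooperativity parameter n. The model's assumptions:

- Within each term the response is log-linear over the ranges used
  (pH ~6.8–8.6, [Cl−] 0.01–0.3 M, 32–40 °C). This is the standard
  Wyman-linkage description at the level of summary coefficients; no
  two-state (MWC) or four-constant (Adair) machinery is implied, and n is
  treated as condition-independent.
- The DPG dose–response is linear in the DPG:Hb4 ratio up to a saturating
  ratio of 50 and flat above — the simplest monotone form consistent with
  experiments that only distinguish "stripped" from "saturating DPG".
  The occupancy difference form (occ(r) − occ(r_ref)) keeps the
  identity-at-reference property for any reference; with a stripped
  reference it reduces to ΔlogP50_DPG·occ(r).
- Temperature scaling uses the *apparent* enthalpy, so the generator and
  the van't Hoff estimator are exact inverses by construction: the
  estimator recovers ΔH_corr because both sides share the same ΔH_sol.
- Chloride enters only through log10[Cl−], so a stripped (zero-chloride)
  condition has no finite image; if the chloride coefficient is nonzero
  and exactly one of query/reference is stripped, the model refuses
  ("chloride reference mismatch") rather than approximating with a
  pseudo-count.

## Parameters that matter

| parameter | units | typical value | notes |
|---|---|---|---|
| P50_ref | mmHg | 5–30 | reference affinity; lower = higher affinity |
| n (Hill) | — | 2.4–3.0 | tetramer cooperativity; validated range (0.5, 4] |
| φ (Bohr) | Δlog10 P50/ΔpH | −0.4 … −0.8 | negative for a normal Bohr effect |
| k_Cl | Δlog10 P50/Δlog10[Cl−] | 0.2–0.35 | 0 disables the chloride term |
| ΔlogP50_DPG | log10 units | 0–0.26 | ~0 marks a DPG-insensitive Hb |
| ΔH_corr | kJ/mol O2 | −1 … −42 | exothermic oxygenation is negative |
| saturation SD | absolute | ≤ 0.05 | additive Gaussian noise on Y |

## What the generator emulates — and what it does not

The generator stands in for diffusion-chamber/tonometer equilibration
series: a strictly increasing PO2 grid, Hill-shaped saturations at the
condition-specific P50, additive Gaussian noise on saturation (absorbance-
derived) clipped to [0, 1]. PO2 steps are treated as exact because
gas-mixing pumps are far more precise than the optical saturation readout.
Defaults used throughout the tests: a 12-step grid placing ~10 steps inside
the 30–70 % saturation window around a P50 of ~29 mmHg, saturation SD 0.01.
The step count and spacing are a design choice, not a reproduction of any
published trace (none are available); real tonometry also exhibits drift,
methemoglobin formation and pH re-equilibration between steps, none of
which are modelled. Passing recovery tests therefore demonstrates estimator
correctness under the stated noise model, not robustness to every
instrumental artefact.

Hematology draws are i.i.d. normal per group with SD reconstructed from the
published SE as SE·√n. Single-animal groups (n = 1) are carried as data but
excluded from testing rather than given a fabricated variance.

## Estimators and numerical choices

- **Hill fit**: OLS in (log10 PO2, log10(Y/(1−Y))) restricted to
  0.30 ≤ Y ≤ 0.70, bounds inclusive, minimum four steps (callers may widen
  the window explicitly, never silently). OLS — not errors-in-variables —
  is the standard practice for these plots and is deterministic; r², point
  count and window are recorded in the result. Steps are not weighted;
  duplicate PO2 values are all used. Steps at exactly Y ∈ {0, 1} are
  untransformable and rejected.
- **Equilibration-curve construction**: from a fit, direct Hill evaluation;
  from points, a monotone piecewise-linear interpolant in Hill coordinates
  with linear extrapolation of the two terminal segments. The classical
  nomogram construction is cited in the literature only by reference, so
  this interpolant is a documented, transparent stand-in rather than a
  reproduction of the original procedure.
- **Linkage slopes**: OLS of log10 P50 on the driver; with exactly two
  measurements this is the two-point quotient, which is how published
  tables derive them from paired runs. The CO2 Bohr coefficient reuses the
  Bohr arithmetic on deoxygenated-subsample pH at the two CO2 tensions and
  is tagged `co2_bohr`. The DPG effect is a paired log difference, not a
  regression. The chloride slope optionally pH-corrects each P50 to the
  mean pH first (requires a Bohr slope), removing pH drift as a confounder.
- **van't Hoff**: OLS of ln P50 on 1/T (quotient at n = 2);
  ΔH_app = R·slope. The solubilization constant lives in one place,
  defaults to −12.5 kJ/mol, and is an argument for sensitivity analyses.
  With three temperatures (e.g. 32/36/40 °C) OLS is used; recomputing
  enthalpies from *rounded* published P50 values can differ from printed
  values by up to ~0.7 kJ/mol, which is why table-input recomputation is
  held to a percent-level band while synthetic-data recovery is exact.
- **Welch's t**: computed from summary statistics,
  t = Δmean/√(SE1²+SE2²), Welch–Satterthwaite df on the squared SEs,
  two-sided p from the t survival function; no multiple-testing correction
  is applied. Cross-checked in tests against scipy's Welch test on raw
  samples.
- **Red-cell indices**: MCV = Hct·10/RBC (fL), MCH = Hb·10/RBC (pg),
  MCHC = Hb·1000/Hct (g/L). Applied to group means these need not equal a
  table of per-animal means of the same indices.
- **Substitution audit**: charge classes at pH 7 are {D, E} negative and
  {K, R} positive; histidine is counted neutral — its context-dependent
  pKa is acknowledged, not modelled. Numbering is mature-chain, 1-based
  (initiator Met removed); gap columns are skipped. The shipped δ-chain
  FASTA is synthetic: a human β-globin mature chain as scaffold carrying
  the three named eastern-mole-like substitutions (3 Leu→Met, 128 Ala→Thr,
  136 Gly→Glu), sufficient for the audit logic since only the named
  positions are attested.

## Reproducibility and problem sizes

Every stochastic routine takes an explicit integer seed and uses one
`numpy.random.default_rng` stream per call; identical seeds give bit-identical
output. The CLI derives per-dataset streams by CRC-hashing dataset labels
against the config seed. Simulation studies use 500 seeds for the noisy
P50-recovery rate and 2000 seeds for the Welch type-I calibration — sizes
at which the binomial uncertainty on the reported rates (≈1 % and ≈0.5 %)
is comfortably inside the asserted bands; both finish in seconds.

## Known limitations

- Hill-level summaries only: no Adair constants, no MWC states, no
  cooperativity-vs-saturation profiles, no kinetics, no methemoglobin.
- The CO2/carbamate competition story is qualitative; no proton-release
  stoichiometry or carbamate chemistry is computed.
- Chloride and DPG are independent additive terms; competitive multi-anion
  binding at shared sites is not modelled.
- The buffering-capacity and myoglobin assay math is out of scope; those
  values pass through as data.
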