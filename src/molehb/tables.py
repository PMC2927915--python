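"""Derived whole-blood and hematology summaries from the shipped printed tables.

These functions recompute, from the published primary measurements shipped
with the package (per-species pH/P50 at paired CO2 tensions and at 32/36/40
degC, plus group hematology summaries), the derived columns a respiratory
physiology table reports: CO2 Bohr coefficients, temperature coefficients,
van't Hoff oxygenation enthalpies, pH-standardised P50 values, and the
narrative group contrasts.
"""

from __future__ import annotations

import pandas as pd

from .hematology import PanelVariable, compare_groups, fold_ratio, percent_difference
from .io import data_path
from .linkage import co2_bohr_coefficient, ph_correct_p50
from .thermo import vant_hoff_enthalpy


def load_whole_blood_table() -> pd.DataFrame:
    return pd.read_csv(data_path("whole_blood_table.csv"))


def load_hematology_table() -> pd.DataFrame:
    return pd.read_csv(data_path("hematology_table.csv"))


def load_hb_components_table() -> pd.DataFrame:
    return pd.read_csv(data_path("hb_components_table.csv"))


def whole_blood_derived(ph_target: float = 7.4) -> pd.DataFrame:
    """Per-species derived respiratory quantities from the whole-blood table.

    Columns: the CO2 Bohr coefficient (two-point slope between the
    PCO2 = 38 mmHg and CO2-free states), the pH-standardised P50 at
    ``ph_target`` using that same slope, the apparent and
    solubilization-corrected oxygenation enthalpies from the 32/40 degC
    pair, and dlog10 P50/dT.
    """
    rows = []
    for _, r in load_whole_blood_table().iterrows():
        bohr = co2_bohr_coefficient(
            [(r.ph_pco2_38, r.p50_36C_mmHg), (r.ph_co2_free, r.p50_co2_free_mmHg)]
        )
        thermo = vant_hoff_enthalpy([(32.0, r.p50_32C_mmHg), (40.0, r.p50_40C_mmHg)])
        rows.append(
            {
                "species": r.species,
                "p50_36C_mmHg": r.p50_36C_mmHg,
                "ph_36C": r.ph_pco2_38,
                "co2_bohr": bohr.value,
                "p50_ph_corrected_mmHg": ph_correct_p50(
                    r.p50_36C_mmHg, r.ph_pco2_38, ph_target, bohr
                ),
                "dH_apparent_kJ_per_mol": thermo.dh_apparent,
                "dH_corrected_kJ_per_mol": thermo.dh_corrected,
                "dlog10P50_per_degC": thermo.temp_coefficient,
            }
        )
    return pd.DataFrame(rows)


def hematology_contrasts() -> dict:
    """Group contrasts behind the hematology narrative.

    DPG fold difference (coast over eastern), percent excess of eastern
    hematocrit and hemoglobin over coast, and the Welch test on red-cell
    DPG content.
    """
    df = load_hematology_table()

    def get(variable: str, group: str) -> PanelVariable:
        r = df[(df.variable == variable) & (df.group == group)].iloc[0]
        return PanelVariable(
            label=variable, mean=float(r["mean"]), se=float(r.se), n=int(r.n),
            units=str(r.units),
        )

    dpg_e, dpg_c = get("dpg", "eastern_mole"), get("dpg", "coast_mole")
    hct_e, hct_c = get("hematocrit", "eastern_mole"), get("hematocrit", "coast_mole")
    hb_e, hb_c = get("hemoglobin", "eastern_mole"), get("hemoglobin", "coast_mole")
    return {
        "dpg_fold_ratio_coast_over_eastern": fold_ratio(dpg_c.mean, dpg_e.mean),
        "hematocrit_percent_higher_eastern": percent_difference(hct_e.mean, hct_c.mean),
        "hemoglobin_percent_higher_eastern": percent_difference(hb_e.mean, hb_c.mean),
        "dpg_welch": compare_groups(dpg_e, dpg_c),
    }


def stripped_affinity_contrast() -> dict:
    """Fold difference in stripped-Hb P50 between species, per component."""
    df = load_hb_components_table()

    def p50(species: str, component: str) -> float:
        return float(
            df[(df.species == species) & (df.component == component)]
            .iloc[0]
            .p50_stripped_37C_mmHg
        )

    return {
        "Hb_I": fold_ratio(p50("eastern_mole", "Hb_I"), p50("coast_mole", "Hb_I")),
        "Hb_II": fold_ratio(p50("eastern_mole", "Hb_II"), p50("coast_mole", "Hb_II")),
    }
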