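"""Substitution audit of beta-type (delta) globin chains.

Enumerates amino-acid differences between an aligned query and reference
chain in mature-chain numbering (position 1 = the N-terminal valine,
initiator methionine removed), classifies the charge consequence of each
substitution at physiological pH, and checks conservation of the canonical
2,3-DPG binding residues of beta-type chains: 1Val, 2His, 82Lys and 143His.
Histidine is counted as neutral at pH 7; its context-dependent protonation
is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

from Bio import SeqIO

from .synthetic import ValidationError

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
NEGATIVE = {"D", "E"}
POSITIVE = {"K", "R"}

DPG_SITES = {1: "V", 2: "H", 82: "K", 143: "H"}
"""Canonical DPG-pocket residues of beta-type globin chains (mature numbering)."""


@dataclass(frozen=True)
class GlobinChain:
    """An amino-acid chain in one-letter code, mature numbering from 1."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - AMINO_ACIDS - {"-"}
        if bad:
            raise ValidationError(f"invalid residue codes: {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based mature-chain position."""
        if not 1 <= position <= len(self.residues):
            raise ValidationError(f"position {position} outside chain of length {len(self)}")
        return self.residues[position - 1]


@dataclass(frozen=True)
class SubstitutionRecord:
    position: int
    ref_aa: str
    query_aa: str
    charge_change: str


def _charge(aa: str) -> int:
    if aa in NEGATIVE:
        return -1
    if aa in POSITIVE:
        return +1
    return 0


def classify_charge_change(ref_aa: str, query_aa: str) -> str:
    """Charge-class transition of a substitution at pH ~7.

    D/E negative, K/R positive, everything else (including His) neutral.
    Reversing query and reference swaps gain/loss labels and fixes 'swap'
    and 'none'.
    """
    cr, cq = _charge(ref_aa), _charge(query_aa)
    if cr == cq:
        return "none"
    if cr != 0 and cq != 0:
        return "swap"
    if cq == -1:
        return "gain_negative"
    if cq == +1:
        return "gain_positive"
    return "loss_negative" if cr == -1 else "loss_positive"


def list_substitutions(query: GlobinChain, reference: GlobinChain) -> list:
    """All positions where aligned query and reference differ (gaps skipped)."""
    if len(query) != len(reference):
        raise ValidationError("chains must be aligned to equal length")
    records = []
    for i, (q, r) in enumerate(zip(query.residues, reference.residues), start=1):
        if q == r or q == "-" or r == "-":
            continue
        records.append(
            SubstitutionRecord(
                position=i, ref_aa=r, query_aa=q,
                charge_change=classify_charge_change(r, q),
            )
        )
    return records


def dpg_site_audit(chain: GlobinChain) -> dict:
    """Conservation status of the four canonical DPG-binding residues.

    Returns ``{"sites": {pos: {"expected", "observed", "conserved"}},
    "all_conserved": bool}``.
    """
    if len(chain) < max(DPG_SITES):
        raise ValidationError(
            f"chain length {len(chain)} shorter than position {max(DPG_SITES)}"
        )
    sites = {}
    for pos, expected in DPG_SITES.items():
        observed = chain.residue(pos)
        sites[pos] = {
            "expected": expected,
            "observed": observed,
            "conserved": observed == expected,
        }
    return {"sites": sites, "all_conserved": all(s["conserved"] for s in sites.values())}


def read_fasta(path: Union[str, Path]) -> list:
    """Read globin chains from a FASTA file (aligned or equal-length)."""
    chains = [GlobinChain(id=rec.id, residues=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not chains:
        raise ValidationError(f"no sequences in {path}")
    return chains


def substitution_table(records: list) -> str:
    """TSV report of substitution records."""
    lines = ["position\tref_aa\tquery_aa\tcharge_change"]
    for r in records:
        lines.append(f"{r.position}\t{r.ref_aa}\t{r.query_aa}\t{r.charge_change}")
    return "\n".join(lines) + "\n"
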