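"""Readers and writers: the OEC CSV dialect, result JSON, YAML configs.

One CSV dialect everywhere: comma separated, '.' decimal, UTF-8, header
row, units embedded in column names. An equilibration dataset is one row
per step with the condition columns repeated.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .synthetic import AllostericParams, Conditions, OECDataset, ValidationError

OEC_COLUMNS = [
    "label",
    "temperature_C",
    "pH",
    "chloride_M",
    "dpg_ratio",
    "pco2_mmHg",
    "po2_mmHg",
    "saturation",
]


def data_path(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(resources.files("molehb.data") / name)


def oec_to_frame(datasets: list) -> pd.DataFrame:
    rows = []
    for ds in datasets:
        c = ds.conditions
        for po2, sat in ds.steps:
            rows.append(
                {
                    "label": ds.label,
                    "temperature_C": c.temperature_c,
                    "pH": c.ph,
                    "chloride_M": c.chloride_m,
                    "dpg_ratio": c.dpg_ratio,
                    "pco2_mmHg": c.pco2_mmhg,
                    "po2_mmHg": po2,
                    "saturation": sat,
                }
            )
    return pd.DataFrame(rows, columns=OEC_COLUMNS)


def write_oec_csv(datasets: list, path: Union[str, Path]) -> None:
    """Write one or more equilibration datasets to the package CSV dialect."""
    # %.17g keeps every float bit-exact through the text round trip
    oec_to_frame(datasets).to_csv(path, index=False, float_format="%.17g")


def read_oec_csv(path: Union[str, Path]) -> list:
    """Read equilibration datasets back; one dataset per distinct label."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(OEC_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"OEC CSV missing columns: {sorted(missing)}")
    datasets = []
    for label, grp in df.groupby("label", sort=False):
        first = grp.iloc[0]
        cl = first["chloride_M"]
        pco2 = first["pco2_mmHg"]
        c = Conditions(
            temperature_c=float(first["temperature_C"]),
            ph=float(first["pH"]),
            chloride_m=None if pd.isna(cl) else float(cl),
            dpg_ratio=float(first["dpg_ratio"]),
            pco2_mmhg=None if pd.isna(pco2) else float(pco2),
        )
        grp = grp.sort_values("po2_mmHg")
        datasets.append(
            OECDataset(
                po2=tuple(grp["po2_mmHg"].astype(float)),
                saturation=tuple(grp["saturation"].astype(float)),
                conditions=c,
                label=str(label),
            )
        )
    return datasets


def write_json(obj, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML generator config; a seed is mandatory."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValidationError("config must be a YAML mapping")
    if "seed" not in cfg:
        raise ValidationError("config must set a seed")
    return cfg


def params_from_config(spec: dict) -> AllostericParams:
    """Build AllostericParams from one species block of a generator config."""
    import math

    ref = Conditions(
        temperature_c=float(spec.get("ref_temperature_C", 37.0)),
        ph=float(spec.get("ref_ph", 7.4)),
        chloride_m=spec.get("ref_chloride_M"),
        dpg_ratio=float(spec.get("ref_dpg_ratio", 0.0)),
    )
    return AllostericParams(
        logp50_ref=math.log10(float(spec["p50_ref_mmHg"])),
        hill_n=float(spec["hill_n"]),
        bohr_phi=float(spec.get("bohr_phi", 0.0)),
        k_cl=float(spec.get("k_cl", 0.0)),
        dpg_shift=float(spec.get("dpg_shift", 0.0)),
        dh_corr=float(spec.get("dh_corr_kJ_per_mol", 0.0)),
        ref_conditions=ref,
    )
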