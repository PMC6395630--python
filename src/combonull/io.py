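"""Reading and writing the plain-text interchange formats.

Monotherapy CSV: columns drug, dose, effect, replicate (header required,
"." decimal separator, doses in user units).  Checkerboard CSV: columns
drug_a, drug_b, dose_a, dose_b, effect, replicate.  Curve parameter files
are YAML mappings drug -> {e_min, e_max, ec50, n}.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .dose_response import HillCurve
from .null_models import CurvePair

__all__ = [
    "read_monotherapy_csv",
    "read_checkerboard_csv",
    "read_curves_yaml",
    "write_curves_yaml",
    "pair_from_yaml",
]

_MONO_COLS = {"dose", "effect"}
_CHECKER_COLS = {"dose_a", "dose_b", "effect"}


def read_monotherapy_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = _MONO_COLS - set(df.columns)
    if missing:
        raise ValueError(f"monotherapy CSV missing columns: {sorted(missing)}")
    if (df["dose"] < 0).any() or not df["dose"].map(lambda v: v == v).all():
        raise ValueError("doses must be finite and non-negative")
    return df


def read_checkerboard_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = _CHECKER_COLS - set(df.columns)
    if missing:
        raise ValueError(f"checkerboard CSV missing columns: {sorted(missing)}")
    if (df[["dose_a", "dose_b"]] < 0).any().any():
        raise ValueError("doses must be non-negative")
    return df


def read_curves_yaml(path) -> dict[str, HillCurve]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    curves = {}
    for drug, params in raw.items():
        curves[drug] = HillCurve(
            e_min=float(params["e_min"]),
            e_max=float(params["e_max"]),
            ec50=float(params["ec50"]),
            n=float(params["n"]),
        )
    return curves


def write_curves_yaml(curves: dict[str, HillCurve], path) -> None:
    payload = {
        drug: {
            "e_min": float(c.e_min),
            "e_max": float(c.e_max),
            "ec50": float(c.ec50),
            "n": float(c.n),
        }
        for drug, c in curves.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def pair_from_yaml(path, drug_a: str | None = None, drug_b: str | None = None) -> CurvePair:
    """Build a CurvePair from a two-entry (or larger) curve YAML."""
    curves = read_curves_yaml(path)
    names = list(curves)
    if drug_a is None or drug_b is None:
        if len(names) != 2:
            raise ValueError(
                "curve file holds more than two drugs; pass drug_a and drug_b"
            )
        drug_a, drug_b = names
    return CurvePair(curves[drug_a], curves[drug_b])
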