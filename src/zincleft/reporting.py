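"""Tabular writers and unit conversion helpers.

Machine-facing tables are SI (columns named ``r_m``, ``t_s``,
``c_mol_per_m3``); human-facing tables convert to micrometres,
milliseconds and micromolar (``r_um``, ``t_ms``, ``c_uM``).  1 mol/m^3 is
1 mM, so mol/m^3 -> uM multiplies by 1000.
"""
from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .params import RadialField

__all__ = [
    "profile_frame",
    "result_frame",
    "to_human_units",
    "write_csv",
    "write_json",
]

_UNIT_MAP = {
    "r_m": ("r_um", 1e6),
    "S_m": ("S_um", 1e6),
    "t_s": ("t_ms", 1e3),
    "tau_max_s": ("tau_max_ms", 1e3),
    "c_mol_per_m3": ("c_uM", 1e3),
    "c_max_mol_per_m3": ("c_max_uM", 1e3),
}


def profile_frame(field: RadialField, **labels) -> pd.DataFrame:
    """Tidy SI table of a radial profile; extra keyword labels become columns."""
    df = pd.DataFrame({"r_m": field.r, "c_mol_per_m3": field.c})
    for key, val in labels.items():
        df[key] = val
    return df


def result_frame(result, probe_radii) -> pd.DataFrame:
    """Tidy SI table (t_s, r_m, c_mol_per_m3) of probe series from an FV run."""
    from .fv import probe  # local import to avoid a cycle

    frames = []
    for r in probe_radii:
        frames.append(pd.DataFrame({
            "t_s": result.times,
            "r_m": r,
            "c_mol_per_m3": probe(result, r),
        }))
    return pd.concat(frames, ignore_index=True)


def to_human_units(df: pd.DataFrame) -> pd.DataFrame:
    """Convert recognised SI columns to um / ms / uM (copies the frame)."""
    out = df.copy()
    for col, (new, factor) in _UNIT_MAP.items():
        if col in out.columns:
            out[new] = out.pop(col) * factor
    return out


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")
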