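"""Delimited-text readers/writers and trial preparation.

Everything on disk is TSV or JSON: trial tables, per-subject connectivity
matrices, the ROI definition table, feature tables and model reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .circular import deg_to_pirad, wrap_angle

__all__ = [
    "prepare_trials",
    "read_trials",
    "write_trials",
    "read_fc_matrix",
    "write_fc_matrix",
    "read_roi_table",
    "write_roi_table",
    "write_json",
]

TRIAL_KEY_COLS = ["subject", "task", "trial", "target_deg", "response_deg"]


def _nontarget_cols(df: pd.DataFrame) -> list[str]:
    return sorted(c for c in df.columns if c.startswith("nontarget") and c.endswith("_deg"))


def prepare_trials(trials: pd.DataFrame, drop_swaps: bool = True) -> pd.DataFrame:
    """Derive circular errors and nontarget offsets (πrad) from a trial table.

    Adds ``error_pirad`` (minimal signed response error) and one
    ``nontarget_delta{i}_pirad`` column per nontarget (offset of the
    nontarget's feature from the target). Location trials whose response
    lands in the uncued hemifield (|error| > 90°) are dropped; their count is
    stored in ``result.attrs["n_hemifield_swaps"]``.
    """
    missing = [c for c in TRIAL_KEY_COLS[:2] + ["target_deg", "response_deg"] if c not in trials]
    if missing:
        raise ValueError(f"trial table lacks columns {missing}")
    out = trials.copy()
    err_deg = wrap_angle(
        np.asarray(out["response_deg"], dtype=float) - np.asarray(out["target_deg"], dtype=float),
        period=360.0,
    )
    # orientation lives on the 180°-periodic space
    ori = out["task"] == "orientation"
    err_deg = np.where(ori, wrap_angle(err_deg, period=180.0), err_deg)
    swaps = (~ori) & (np.abs(err_deg) > 90.0)
    n_swaps = int(swaps.sum())
    out["error_pirad"] = deg_to_pirad(err_deg)
    for i, col in enumerate(_nontarget_cols(out), start=1):
        delta = np.asarray(out[col], dtype=float) - np.asarray(out["target_deg"], dtype=float)
        # nontarget offsets are folded onto the same transformed circle for
        # both tasks (the ±90° range spans 2π; location is treated like
        # orientation once hemifield swaps are excluded)
        out[f"nontarget_delta{i}_pirad"] = deg_to_pirad(wrap_angle(delta, period=180.0))
    if n_swaps and drop_swaps:
        out = out.loc[~swaps].reset_index(drop=True)
    out.attrs["n_hemifield_swaps"] = n_swaps
    return out


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trials(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in trials.columns if not c.endswith("_pirad")]
    trials[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_fc_matrix(path) -> pd.DataFrame:
    z = pd.read_csv(path, sep="\t", index_col=0)
    z.columns.name = None
    return z


def write_fc_matrix(z: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    z.to_csv(path, sep="\t", float_format="%.6f")
    return path


def read_roi_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"label", "x_mm", "y_mm", "z_mm"}
    if not need.issubset(df.columns):
        raise ValueError(f"ROI table must have columns {sorted(need)}")
    return df


def write_roi_table(rois: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rois.to_csv(path, sep="\t", index=False)
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default, sort_keys=True))
    return path
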