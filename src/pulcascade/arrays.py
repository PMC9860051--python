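"""Carbohydrate-microarray epitope-deletion analysis.

Polysaccharide extracts are spotted in replicate onto arrays; identical
arrays are treated with an enzyme or with buffer (control) and probed with a
monoclonal antibody. Loss of antibody signal on the treated array relative
to the buffer control indicates the enzyme destroyed the antibody's epitope.

The analysis follows the heatmap convention: replicate spots are averaged
(cells with fewer than two replicates are flagged and excluded), the highest
mean signal within each dataset is set to 100 with all other values scaled
accordingly, and the deletion score for an (extract, probe) cell is the
percent reduction of the treated signal against the buffer control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SPOT_COLUMNS = ["extract_id", "probe_id", "treatment", "replicate", "signal"]


def _check_spots(spots: pd.DataFrame) -> None:
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise ValueError(f"spot table lacks columns {missing}")
    if (spots["signal"] < 0).any():
        raise ValueError("spot signals must be >= 0")


def mean_replicates(spots: pd.DataFrame, min_replicates: int = 2):
    """Mean signal per (extract, probe, treatment) cell.

    Cells with fewer than ``min_replicates`` spots violate the replication
    rule; they are excluded from the mean table and returned separately.

    Returns ``(means, flagged)`` DataFrames.
    """
    _check_spots(spots)
    grouped = (
        spots.groupby(["extract_id", "probe_id", "treatment"], sort=True)["signal"]
        .agg(mean_signal="mean", n_spots="size")
        .reset_index()
    )
    ok = grouped["n_spots"] >= min_replicates
    return (
        grouped[ok].reset_index(drop=True),
        grouped[~ok].reset_index(drop=True),
    )


def normalize_dataset(means: pd.DataFrame, scope: str = "treatment") -> pd.DataFrame:
    """Scale mean signals so each dataset's maximum is exactly 100.

    A "dataset" is one treatment sub-heatmap by default (``scope=
    'treatment'``); ``scope='global'`` normalizes the whole table at once.
    Scale-invariant: multiplying all raw signals of a dataset by a positive
    constant leaves the output unchanged.
    """
    if means.empty:
        return means.copy()
    out = means.copy()

    def _scale(group: pd.Series) -> pd.Series:
        top = group.max()
        if not top > 0:
            raise ValueError("all-zero dataset cannot be normalized")
        return group / top * 100.0

    if scope == "global":
        out["normalized"] = _scale(out["mean_signal"])
    elif scope == "treatment":
        out["normalized"] = out.groupby("treatment")["mean_signal"].transform(_scale)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return out


def epitope_deletion_score(
    normalized: pd.DataFrame, treatment: str, control: str = "buffer"
) -> pd.DataFrame:
    """Percent signal reduction of a treatment against the buffer control.

    For each (extract, probe): reduction = 100 * (1 - treated/control),
    floored at 0 (signal increases are reported as 0, with the raw ratio
    preserved). A zero control signal leaves the score undefined (NaN,
    flagged).
    """
    value = "normalized" if "normalized" in normalized.columns else "mean_signal"
    t = normalized[normalized["treatment"] == treatment]
    c = normalized[normalized["treatment"] == control]
    if t.empty or c.empty:
        raise ValueError(
            f"treatment {treatment!r} and control {control!r} must both be present"
        )
    merged = t.merge(
        c,
        on=["extract_id", "probe_id"],
        suffixes=("_treated", "_control"),
        how="inner",
    )
    treated = merged[f"{value}_treated"].to_numpy(float)
    ctrl = merged[f"{value}_control"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = treated / ctrl
    undefined = ctrl == 0
    reduction = np.clip(100.0 * (1.0 - ratio), 0.0, None)
    reduction[undefined] = np.nan
    return pd.DataFrame(
        {
            "extract_id": merged["extract_id"],
            "probe_id": merged["probe_id"],
            "treatment": treatment,
            "control": control,
            "reduction": reduction,
            "raw_ratio": ratio,
            "undefined_control": undefined,
        }
    )
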