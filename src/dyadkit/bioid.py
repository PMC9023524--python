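"""BioID enrichment ranking.

Proteins are ranked by the ratio of the mean of the two biosensor channels
to the control channel.  Proteins never observed in the control arm
(control intensity exactly zero) cannot be assigned a finite ratio and are
grouped ahead of all finite-ratio proteins; retention requires a ratio
strictly greater than the threshold (default 5).  The screen is a single
pooled replicate per arm, so no variance model is fitted -- the ranking is
the statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RATIO_THRESHOLD_DEFAULT = 5.0
_REQUIRED = ("protein_id", "sensor_A", "sensor_B", "control")


def compute_enrichment(table: pd.DataFrame) -> pd.DataFrame:
    """Per-protein mean sensor intensity and sensor/control ratio.

    Rows with zero signal in all three channels carry no information and are
    dropped (noted in the ``qc_dropped`` DataFrame attr).  Control-zero rows
    get ``ratio = inf`` as the undefined-ratio class marker alongside
    ``control_zero = True``.
    """
    for col in _REQUIRED:
        if col not in table.columns:
            raise ValueError(f"missing required column: {col}")
    if table["protein_id"].duplicated().any():
        raise ValueError("protein_id values must be unique")
    vals = table[["sensor_A", "sensor_B", "control"]].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("intensities must be finite")
    if (vals < 0).any():
        raise ValueError("intensities must be non-negative")

    out = table.copy()
    out["mean_sensor"] = (out["sensor_A"] + out["sensor_B"]) / 2.0
    out["control_zero"] = out["control"] == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["mean_sensor"] / out["control"]
    out["ratio"] = np.where(out["control_zero"], np.inf, ratio)

    dropped = out[(out["mean_sensor"] == 0.0) & out["control_zero"]]
    out = out[~((out["mean_sensor"] == 0.0) & out["control_zero"])].reset_index(drop=True)
    out.attrs["qc_dropped"] = list(dropped["protein_id"])
    return out


def rank_and_filter(results: pd.DataFrame,
                    threshold: float = RATIO_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Order and filter enrichment results.

    Order: control-zero block first (mean_sensor descending, ties by
    protein_id), then finite-ratio block (ratio descending, ties by
    mean_sensor then protein_id).  Retained = the whole control-zero block
    plus finite rows with ratio strictly > threshold; 1-based ranks are
    assigned over the retained rows.
    """
    df = results.copy()
    zero = df[df["control_zero"]].sort_values(
        ["mean_sensor", "protein_id"], ascending=[False, True])
    finite = df[~df["control_zero"]].sort_values(
        ["ratio", "mean_sensor", "protein_id"], ascending=[False, False, True])
    ordered = pd.concat([zero, finite]).reset_index(drop=True)
    ordered["retained"] = ordered["control_zero"] | (ordered["ratio"] > threshold)
    ordered["rank"] = pd.NA
    ordered.loc[ordered["retained"], "rank"] = np.arange(
        1, int(ordered["retained"].sum()) + 1)
    return ordered


def rank_table(table: pd.DataFrame,
               threshold: float = RATIO_THRESHOLD_DEFAULT) -> pd.DataFrame:
    """Convenience: compute_enrichment then rank_and_filter."""
    return rank_and_filter(compute_enrichment(table), threshold=threshold)
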