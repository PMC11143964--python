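"""Plate Z-score statistics, replicate hit calling and ddCt quantification.

The screen statistic is the plate Z score of a well-level readout (mean
relaxation velocity in the screening campaign): z = (x - mu) / sigma, where
mu and sigma are the mean and SD of the readout over the wells of that plate.
A miRNA is validated as a hit when its Z score reaches the threshold (2 by
default) in at least ``min_replicates`` of the replicates AND its mean Z
score over all replicates also reaches the threshold. The weaker single-
replicate criterion (z >= threshold in at least one replicate, the screen's
"accelerated in at least 1 replicate" count) is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ZScoreConfig", "plate_zscores", "call_hits", "ddct"]


@dataclass(frozen=True)
class ZScoreConfig:
    """Conventions of the plate Z score.

    ddof=1 (sample SD) is the screening default; negative-control wells are
    included in mu/sigma unless ``exclude_controls`` is set.
    """

    ddof: int = 1
    exclude_controls: bool = False


def plate_zscores(
    wells: pd.DataFrame,
    value_col: str = "value",
    cfg: ZScoreConfig | None = None,
) -> pd.DataFrame:
    """Per-well plate Z scores and two-sided normal tail probabilities.

    ``wells`` needs columns plate_id, well, mirna_id, ``value_col`` and
    optionally is_negative_control / replicate. Each plate with sigma == 0 or
    fewer than 2 wells is rejected with a diagnostic.
    """
    cfg = cfg or ZScoreConfig()
    required = {"plate_id", "mirna_id", value_col}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = wells.copy()
    group_cols = ["plate_id"]
    if "replicate" in out.columns:
        group_cols = ["replicate", "plate_id"]
    stat = out
    if cfg.exclude_controls and "is_negative_control" in out.columns:
        stat = out[~out["is_negative_control"].astype(bool)]
    agg = (
        stat.groupby(group_cols)[value_col]
        .agg(
            plate_mu="mean",
            n_wells="size",
            plate_sigma=lambda x: np.std(x, ddof=cfg.ddof),
        )
        .reset_index()
    )
    bad = agg[agg["n_wells"] < 2]
    if len(bad):
        raise ValueError(
            f"plate(s) with fewer than 2 wells: {bad[group_cols].to_dict('records')}"
        )
    degenerate = agg[agg["plate_sigma"] == 0]
    if len(degenerate):
        raise ValueError(
            "plate(s) with zero SD, Z scores undefined: "
            f"{degenerate[group_cols].to_dict('records')}"
        )
    out = out.merge(agg.drop(columns="n_wells"), on=group_cols, how="left")
    out["z"] = (out[value_col] - out["plate_mu"]) / out["plate_sigma"]
    out["p"] = 2.0 * stats.norm.sf(np.abs(out["z"]))
    return out


def call_hits(
    zscores: pd.DataFrame,
    z_threshold: float = 2.0,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Replicate-aggregated hit table under the two-of-three rule.

    ``zscores`` needs columns mirna_id, replicate, z (output of
    :func:`plate_zscores` over all replicates). Per miRNA the table reports
    the per-replicate z values, their mean, how many replicates reach the
    threshold, and the hit flag:

        is_hit  <=>  (#replicates with z >= threshold) >= min_replicates
                     AND mean z >= threshold.

    ``n_any_replicate`` flags the weaker z >= threshold in >= 1 replicate
    criterion. miRNAs with fewer replicates than ``min_replicates`` are
    excluded with a warning, not silently dropped.
    """
    required = {"mirna_id", "replicate", "z"}
    if missing := required - set(zscores.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    excluded = []
    for mid, grp in zscores.groupby("mirna_id", sort=True):
        z = grp.sort_values("replicate")["z"].to_numpy(dtype=float)
        if len(z) < min_replicates:
            excluded.append(mid)
            continue
        n_ge = int(np.sum(z >= z_threshold))
        mean_z = float(np.mean(z))
        rows.append(
            {
                "mirna_id": mid,
                "n_replicates": len(z),
                "z_by_replicate": tuple(np.round(z, 12)),
                "mean_z": mean_z,
                "n_replicates_ge_threshold": n_ge,
                "any_replicate_ge_threshold": n_ge >= 1,
                "is_hit": (n_ge >= min_replicates) and (mean_z >= z_threshold),
            }
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} miRNA(s) excluded from hit calling for having "
            f"fewer than {min_replicates} replicate Z scores: "
            f"{excluded[:5]}{'...' if len(excluded) > 5 else ''}",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def ddct(
    records: pd.DataFrame,
    control_group: str,
    target_col: str = "target_ct",
    reference_col: str = "reference_ct",
    group_col: str = "group",
) -> pd.DataFrame:
    """Relative expression by the ddCt method.

    dCt = target Ct - reference Ct per sample; ddCt = dCt minus the mean dCt
    of the control group; RQ = 2^(-ddCt). Undetermined Ct values (NaN)
    propagate as missing, with their count attached to ``df.attrs``.
    """
    for col in (target_col, reference_col, group_col):
        if col not in records.columns:
            raise ValueError(f"missing column: {col}")
    out = records.copy()
    out["delta_ct"] = out[target_col] - out[reference_col]
    ctrl = out.loc[out[group_col] == control_group, "delta_ct"]
    if len(ctrl) == 0:
        raise ValueError(f"control group {control_group!r} is empty")
    ctrl_mean = float(ctrl.mean())  # NaN-aware mean
    out["delta_delta_ct"] = out["delta_ct"] - ctrl_mean
    out["rq"] = 2.0 ** (-out["delta_delta_ct"])
    out.attrs["n_missing_ct"] = int(out["delta_ct"].isna().sum())
    out.attrs["control_mean_delta_ct"] = ctrl_mean
    return out
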