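"""Differential statistics for circRNA levels.

Per-circRNA log2 fold changes (DM vs control) with Welch t-tests and
Benjamini-Hochberg FDR control, a chi-square goodness-of-fit test for
direction bias (observed up/down counts against equal proportions), and a
cumulative group comparison of tier-restricted circRNA, linear, and FCR
levels. Welch's unequal-variance t-test is used uniformly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import JunctionCounts, SampleMeta
from .quantify import compute_fcr, compute_rpm

log = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.01  # RPM pseudocount for fold changes over zeros


def log2_fold_change(mean_dm: float, mean_ctrl: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """log2((mean_dm + eps) / (mean_ctrl + eps)); 0 when both means are 0."""
    if mean_dm < 0 or mean_ctrl < 0:
        raise ValueError("means must be >= 0")
    if mean_dm == 0 and mean_ctrl == 0:
        return 0.0
    if epsilon <= 0 and (mean_dm == 0 or mean_ctrl == 0):
        raise ValueError("epsilon must be > 0 when a mean is 0")
    return float(np.log2((mean_dm + epsilon) / (mean_ctrl + epsilon)))


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's t statistic, Satterthwaite degrees of freedom, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        # degenerate: no within-group variability
        return (0.0, float(len(x) + len(y) - 2), 1.0) if x.mean() == y.mean() else (
            math.inf if x.mean() > y.mean() else -math.inf,
            float(len(x) + len(y) - 2),
            0.0,
        )
    se2x, se2y = vx / len(x), vy / len(y)
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (len(x) - 1) + se2y**2 / (len(y) - 1)
    )
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(df), float(p)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DirectionBias:
    n_up: int
    n_down: int
    chi2: float
    p: float


def direction_bias_test(n_up: int, n_down: int) -> DirectionBias:
    """One-df chi-square goodness of fit of up/down counts vs equal occurrence.

    No continuity correction; ties must be excluded before tallying.
    """
    if n_up < 0 or n_down < 0:
        raise ValueError("counts must be >= 0")
    total = n_up + n_down
    if total == 0:
        raise ValueError("need at least one non-tie direction")
    chi2, p = stats.chisquare([n_up, n_down])
    return DirectionBias(n_up=n_up, n_down=n_down, chi2=float(chi2), p=float(p))


def direction_summary(n_up: int, n_down: int) -> dict[str, float]:
    """Percent of increased and decreased circRNAs among a non-tie tally."""
    if n_up + n_down <= 0:
        raise ValueError("need at least one non-tie direction")
    total = n_up + n_down
    return {"pct_up": 100.0 * n_up / total, "pct_down": 100.0 * n_down / total}


def _group_columns(meta: Sequence[SampleMeta], columns: Sequence[str]) -> tuple[list[str], list[str]]:
    group_of = {m.sample_id: m.group for m in meta}
    ctrl = [c for c in columns if group_of.get(c) == "control"]
    dm = [c for c in columns if group_of.get(c) == "DM"]
    return ctrl, dm


def diff_table(
    counts: JunctionCounts,
    meta: Sequence[SampleMeta],
    metrics: Sequence[str] = ("RPM", "FCR"),
    epsilon: float = DEFAULT_EPSILON,
    circ_subset: Sequence[str] | None = None,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Volcano table: per circRNA and metric, log2fc, Welch p, BH-adjusted p.

    BH adjustment is applied within each metric family. A circRNA's FCR row
    is omitted (and logged) when FCR is undefined in more than half of the
    samples; otherwise undefined values are dropped pairwise. The
    significance flag applies the volcano thresholds (p below
    ``p_threshold`` and |log2fc| at or above ``lfc_threshold``).
    """
    bsj, linear = counts.bsj, counts.linear
    if circ_subset is not None:
        bsj, linear = bsj.loc[list(circ_subset)], linear.loc[list(circ_subset)]
    ctrl_cols, dm_cols = _group_columns(meta, bsj.columns)
    if len(ctrl_cols) < 2 or len(dm_cols) < 2:
        raise ValueError("need >= 2 samples per group")
    mappable = counts.mappable_reads()

    values: dict[str, pd.DataFrame] = {}
    if "RPM" in metrics:
        values["RPM"] = compute_rpm(bsj, mappable)
    if "FCR" in metrics:
        values["FCR"] = compute_fcr(bsj, linear)
    if "hk_norm" in metrics:
        raise ValueError("pass housekeeping-normalized levels via compute-then-diff instead")

    frames = []
    for metric, mat in values.items():
        rows = []
        for cid in mat.index:
            x = mat.loc[cid, dm_cols].astype(float)
            y = mat.loc[cid, ctrl_cols].astype(float)
            n_undef = int(x.isna().sum() + y.isna().sum())
            if n_undef > (len(x) + len(y)) / 2:
                log.info("%s: %s undefined in more than half of samples; omitted", cid, metric)
                continue
            x, y = x.dropna(), y.dropna()
            if len(x) < 2 or len(y) < 2:
                log.info("%s: %s has <2 defined values in a group; omitted", cid, metric)
                continue
            t, df, p = welch_t(x, y)
            lfc = log2_fold_change(float(x.mean()), float(y.mean()), epsilon)
            rows.append(
                {
                    "circ_id": cid,
                    "metric": metric,
                    "log2fc": lfc,
                    "t": t,
                    "p": p,
                    "direction": "up" if lfc > 0 else ("down" if lfc < 0 else "tie"),
                }
            )
        fam = pd.DataFrame(rows)
        if not fam.empty:
            fam["fdr_p"] = bh_fdr(fam["p"].to_numpy())
            fam["significant"] = (fam["p"] < p_threshold) & (fam["log2fc"].abs() >= lfc_threshold)
        frames.append(fam)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return out


def global_level_compare(
    counts: JunctionCounts,
    meta: Sequence[SampleMeta],
    circ_subset: Sequence[str] | None = None,
    fcr_mode: str = "sum",
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Compare per-sample cumulative circ RPM, linear RPM, and cumulative FCR.

    ``fcr_mode="sum"`` uses sum(circ)/(sum(circ)+sum(linear)) per sample;
    ``"mean"`` averages defined per-circRNA FCR values instead. BH adjusts
    across the three quantities.
    """
    bsj, linear = counts.bsj, counts.linear
    if circ_subset is not None:
        if len(circ_subset) == 0:
            raise ValueError("empty circRNA subset")
        bsj, linear = bsj.loc[list(circ_subset)], linear.loc[list(circ_subset)]
    ctrl_cols, dm_cols = _group_columns(meta, bsj.columns)
    mappable = counts.mappable_reads()
    circ_rpm = (bsj.sum(axis=0) * 1e6 / mappable).astype(float)
    lin_rpm = (linear.sum(axis=0) * 1e6 / mappable).astype(float)
    if fcr_mode == "sum":
        denom = bsj.sum(axis=0) + linear.sum(axis=0)
        fcr = (bsj.sum(axis=0) / denom.where(denom > 0)).astype(float)
    elif fcr_mode == "mean":
        fcr = compute_fcr(bsj, linear).mean(axis=0, skipna=True)
    else:
        raise ValueError(f"unknown fcr_mode: {fcr_mode!r}")

    rows = []
    for name, series in (("circ_RPM", circ_rpm), ("linear_RPM", lin_rpm), ("FCR", fcr)):
        x = series[dm_cols].dropna()
        y = series[ctrl_cols].dropna()
        t, df, p = welch_t(x, y)
        rows.append(
            {
                "quantity": name,
                "mean_control": float(y.mean()),
                "mean_dm": float(x.mean()),
                "log2fc": log2_fold_change(float(x.mean()), float(y.mean()), epsilon),
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["fdr_p"] = bh_fdr(out["p"].to_numpy())
    return out
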