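"""Correlation of circRNA levels with disease-severity covariates.

Severity covariates are muscle strength (ankle dorsiflexion force, arbitrary
units) and percent-spliced-in (PSI) of disease-responsive alternative exons.
Levels (global burden, individual circRNAs, or per-gene pools) are related
to covariates by the sample Pearson correlation with a t-transform p-value;
correlations are computed within DM samples by default, with BH adjustment
per covariate family.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SampleMeta
from .diffexp import bh_fdr


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson R with two-sided p (t-transform, n-2 df).

    Pairs with a missing value are dropped; constant vectors raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), n


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Smallest |R| reaching two-sided significance at level alpha for n pairs."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    t_star = stats.t.ppf(1 - alpha / 2, n - 2)
    return float(t_star / math.sqrt(t_star**2 + n - 2))


def correlate_levels(
    levels: Mapping[str, pd.Series],
    meta: Sequence[SampleMeta],
    dm_only: bool = True,
) -> pd.DataFrame:
    """Correlate each named level with each available covariate.

    ``levels`` maps level ids (e.g. "global", "circ:<id>", "pool:<gene>") to
    per-sample series. Covariates are taken from the metadata: ``strength``
    and every ``psi:<exon>`` entry. Samples lacking either value are dropped
    pairwise; rows with fewer than 3 complete pairs are skipped. BH
    adjustment is applied within each covariate family.
    """
    use = [m for m in meta if (m.group == "DM" or not dm_only)]
    covariates: dict[str, dict[str, float]] = {}
    for m in use:
        if m.strength is not None:
            covariates.setdefault("strength", {})[m.sample_id] = m.strength
        for exon, v in m.psi.items():
            covariates.setdefault(f"psi:{exon}", {})[m.sample_id] = v

    rows = []
    for cov_name, cov_vals in covariates.items():
        cov = pd.Series(cov_vals)
        for level_id, series in levels.items():
            joint = pd.concat([series, cov], axis=1, join="inner").dropna()
            if len(joint) < 3:
                continue
            try:
                r, p, n = pearson_r(joint.iloc[:, 0], joint.iloc[:, 1])
            except ValueError:
                continue
            rows.append({"level_id": level_id, "covariate": cov_name, "R": r, "p": p, "n": n})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr_p"] = np.nan
    for cov_name, idx in out.groupby("covariate").groups.items():
        out.loc[idx, "fdr_p"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out
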