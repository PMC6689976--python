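"""Multi-circRNA genes (MCGs) and per-gene circRNA pools.

An MCG gives rise to more than one distinct circRNA; a top-MCG to more than
``top_threshold`` (strictly). CircRNAs without a gene assignment ("n/a")
are kept in circRNA-level tallies but excluded from gene-level lists. A
gene's circRNA pool is quantified per sample as the sum of member BSJ RPMs
and a pooled FCR over member junction counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .data_model import CircCatalog, JunctionCounts, SampleMeta
from .diffexp import bh_fdr, log2_fold_change, welch_t, DEFAULT_EPSILON
from .quantify import compute_fcr, compute_rpm

DEFAULT_TOP_THRESHOLD = 10


def find_mcgs(
    gene_map: Mapping[str, str], top_threshold: int = DEFAULT_TOP_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Return (MCG gene ids, top-MCG gene ids) from a circ -> gene map."""
    counts: dict[str, int] = {}
    for cid, gid in gene_map.items():
        if gid == "n/a":
            continue
        counts[gid] = counts.get(gid, 0) + 1
    mcgs = sorted(g for g, n in counts.items() if n > 1)
    top = sorted(g for g, n in counts.items() if n > top_threshold)
    return mcgs, top


def mcg_summary(gene_map: Mapping[str, str]) -> pd.DataFrame:
    """Per n-circRNA stratum: fraction of genes and fraction of circRNAs.

    Fractions are over all circRNA-generating genes (with an assigned gene)
    and over their circRNAs; each column sums to 1.
    """
    counts: dict[str, int] = {}
    for cid, gid in gene_map.items():
        if gid != "n/a":
            counts[gid] = counts.get(gid, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["n_circ", "n_genes", "gene_fraction", "circ_fraction"])
    strata: dict[int, int] = {}
    for n in counts.values():
        strata[n] = strata.get(n, 0) + 1
    total_genes = sum(strata.values())
    total_circ = sum(n * g for n, g in strata.items())
    rows = [
        {
            "n_circ": n,
            "n_genes": g,
            "gene_fraction": g / total_genes,
            "circ_fraction": n * g / total_circ,
        }
        for n, g in sorted(strata.items())
    ]
    return pd.DataFrame(rows)


@dataclass
class GenePool:
    gene_id: str
    circ_ids: list[str]
    pooled_rpm: pd.Series  # per sample
    pooled_fcr: pd.Series  # per sample

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)


def pool_levels(
    counts: JunctionCounts, gene_id: str, members: Sequence[str]
) -> GenePool:
    """Per-sample pooled RPM (sum of member RPMs) and pooled FCR (sum-based)."""
    members = list(members)
    if not members:
        raise ValueError(f"empty pool for gene {gene_id}")
    bsj = counts.bsj.loc[members]
    lin = counts.linear.loc[members]
    rpm = compute_rpm(bsj, counts.mappable_reads()).sum(axis=0)
    tot_b, tot_l = bsj.sum(axis=0), lin.sum(axis=0)
    fcr = compute_fcr(tot_b, tot_l)
    return GenePool(gene_id=gene_id, circ_ids=members, pooled_rpm=rpm, pooled_fcr=fcr)


def build_pools(
    counts: JunctionCounts, gene_map: Mapping[str, str], genes: Sequence[str]
) -> list[GenePool]:
    pools = []
    for gid in genes:
        members = [c for c, g in gene_map.items() if g == gid and c in counts.bsj.index]
        pools.append(pool_levels(counts, gid, members))
    return pools


def diff_pools(
    pools: Sequence[GenePool],
    meta: Sequence[SampleMeta],
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Per-pool Welch test and log2fc on pooled RPM and pooled FCR.

    BH adjustment is applied across pools, separately per metric.
    """
    group_of = {m.sample_id: m.group for m in meta}
    frames = []
    for metric in ("pooled_RPM", "pooled_FCR"):
        rows = []
        for pool in pools:
            series = pool.pooled_rpm if metric == "pooled_RPM" else pool.pooled_fcr
            x = series[[s for s in series.index if group_of.get(s) == "DM"]].dropna()
            y = series[[s for s in series.index if group_of.get(s) == "control"]].dropna()
            if len(x) < 2 or len(y) < 2:
                continue
            t, df, p = welch_t(x, y)
            rows.append(
                {
                    "gene_id": pool.gene_id,
                    "n_circ": pool.n_circ,
                    "metric": metric,
                    "log2fc": log2_fold_change(float(x.mean()), float(y.mean()), epsilon),
                    "t": t,
                    "p": p,
                }
            )
        fam = pd.DataFrame(rows)
        if not fam.empty:
            fam["fdr_p"] = bh_fdr(fam["p"].to_numpy())
        frames.append(fam)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def export_gene_map(
    catalog: CircCatalog, genes: Sequence[str], path: str | Path
) -> int:
    """Write member circRNA spans of the given genes as BED lines; returns count."""
    n = 0
    with open(path, "w") as fh:
        for gid in genes:
            for rec in catalog.records:
                if rec.gene_id != gid:
                    continue
                iv = rec.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.circ_id}\t0\t.\n")
                n += 1
    return n
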