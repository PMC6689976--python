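"""Per-sample circRNA levels: junction-read detection and normalization.

The detector is a deliberately simplified, annotation-guided back-splice
junction caller: it enumerates every candidate head-to-tail junction
(downstream exon end joined to an upstream exon start within one gene) and
every canonical exon-exon junction, builds their exact sequences at all
admissible junction offsets, and assigns each read by exact match. Reads
with multiple equally valid placements are dropped and counted. It assumes
error-free reads and exact exon-boundary back-splicing — the regime the
synthetic read simulator produces — and makes no attempt at mismatch-
tolerant or de novo discovery.

Normalizations: RPM (reads per million mappable reads), FCR (fraction of
circRNA-specific reads among circ plus corresponding linear junction
reads), and division by a housekeeping gene's per-sample read count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CircCatalog,
    CircRecord,
    GeneModel,
    JunctionCounts,
    SampleMeta,
)

DEFAULT_ANCHOR_LEN = 20


@dataclass
class DetectionReport:
    """Bookkeeping from one detector run."""

    n_reads: int = 0
    n_bsj: int = 0
    n_linear: int = 0
    n_ambiguous: int = 0
    n_unmatched: int = 0
    n_too_short: int = 0
    skipped_circs: list[str] = field(default_factory=list)


def _junction_index(
    annotation: Sequence[GeneModel],
    genome: Mapping[str, str],
    read_len: int,
    anchor_len: int,
) -> dict[str, tuple[str, tuple]]:
    """Map junction-spanning sequences to their unique (kind, junction) labels.

    Keys are read-length sequences crossing a junction at any offset with at
    least ``anchor_len`` nt on each side. Sequences matching more than one
    distinct junction map to the sentinel ("ambiguous", ()).
    """
    index: dict[str, tuple[str, tuple]] = {}

    def add(seq_str: str, label: tuple[str, tuple]) -> None:
        prev = index.get(seq_str)
        if prev is None:
            index[seq_str] = label
        elif prev[1] != label[1] or prev[0] != label[0]:
            index[seq_str] = ("ambiguous", ())

    for gene in annotation:
        seq = genome[gene.chrom]
        n_e = len(gene.exons)
        # back-splice candidates: donor = exon j end, acceptor = exon i start, i <= j
        for i in range(n_e):
            for j in range(i, n_e):
                donor = gene.exons[j].end
                acceptor = gene.exons[i].start
                label = ("bsj", (gene.gene_id, acceptor, donor))
                for left in range(anchor_len, read_len - anchor_len + 1):
                    right = read_len - left
                    if donor - left < gene.exons[j].start or acceptor + right > gene.exons[i].end:
                        continue  # keep each arm within its exon
                    add(seq[donor - left : donor] + seq[acceptor : acceptor + right], label)
        # canonical junctions between consecutive exons
        for k in range(n_e - 1):
            donor = gene.exons[k].end
            acceptor = gene.exons[k + 1].start
            label = ("linear", (gene.gene_id, donor, acceptor))
            for left in range(anchor_len, read_len - anchor_len + 1):
                right = read_len - left
                if donor - left < gene.exons[k].start or acceptor + right > gene.exons[k + 1].end:
                    continue
                add(seq[donor - left : donor] + seq[acceptor : acceptor + right], label)
    return index


def _boundary_junctions(circ: CircRecord, gene: GeneModel) -> list[tuple]:
    starts = [e.start for e in gene.exons]
    ends = [e.end for e in gene.exons]
    if circ.interval.start not in starts or circ.interval.end not in ends:
        return []
    i = starts.index(circ.interval.start)
    j = ends.index(circ.interval.end)
    out = []
    if i > 0:
        out.append((gene.gene_id, gene.exons[i - 1].end, circ.interval.start))
    if j < len(gene.exons) - 1:
        out.append((gene.gene_id, circ.interval.end, gene.exons[j + 1].start))
    return out


def detect_junction_reads(
    reads_by_sample: Mapping[str, Sequence[tuple[str, str]]],
    annotation: Sequence[GeneModel],
    genome: Mapping[str, str],
    catalog: CircCatalog,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    meta: Sequence[SampleMeta] | None = None,
) -> tuple[JunctionCounts, DetectionReport]:
    """Count BSJ and corresponding linear junction reads per catalog circRNA.

    ``reads_by_sample`` maps sample ids to (read_id, sequence) pairs; all
    reads in one run must share a single read length of at least
    ``2 * anchor_len`` (shorter reads are skipped and counted). The
    corresponding linear count of a circRNA is the floor of the mean of
    junction-spanning read counts over its available canonical boundary
    junctions.
    """
    report = DetectionReport()
    genes = {g.gene_id: g for g in annotation}
    lengths = set()
    for recs in reads_by_sample.values():
        for _, s in recs:
            if len(s) >= 2 * anchor_len:
                lengths.add(len(s))
            else:
                report.n_too_short += 1
                report.n_reads += 1
    if report.n_too_short:
        warnings.warn(
            f"{report.n_too_short} reads shorter than 2 x anchor_len skipped", stacklevel=2
        )
    sample_ids = list(reads_by_sample)
    circ_ids = [r.circ_id for r in catalog.records]
    bsj = pd.DataFrame(0, index=circ_ids, columns=sample_ids)
    lin_junction_counts: dict[str, dict[tuple, int]] = {s: {} for s in sample_ids}

    if lengths:
        if len(lengths) > 1:
            raise ValueError(f"mixed read lengths not supported: {sorted(lengths)}")
        read_len = lengths.pop()
        index = _junction_index(annotation, genome, read_len, anchor_len)
        bsj_locus_to_circ: dict[tuple, str] = {}
        for rec in catalog.records:
            key = (rec.gene_id, rec.interval.start, rec.interval.end)
            bsj_locus_to_circ[key] = rec.circ_id
        for sid, recs in reads_by_sample.items():
            for _, seq in recs:
                if len(seq) < 2 * anchor_len:
                    continue  # already tallied above
                report.n_reads += 1
                hit = index.get(seq.upper())
                if hit is None:
                    report.n_unmatched += 1
                    continue
                kind, junction = hit
                if kind == "ambiguous":
                    report.n_ambiguous += 1
                elif kind == "bsj":
                    cid = bsj_locus_to_circ.get(junction)
                    if cid is None:
                        report.n_unmatched += 1  # BSJ outside the catalog
                    else:
                        bsj.loc[cid, sid] += 1
                        report.n_bsj += 1
                else:
                    d = lin_junction_counts[sid]
                    d[junction] = d.get(junction, 0) + 1
                    report.n_linear += 1

    linear = pd.DataFrame(0, index=circ_ids, columns=sample_ids)
    for rec in catalog.records:
        gene = genes.get(rec.gene_id)
        if gene is None:
            report.skipped_circs.append(rec.circ_id)
            continue
        boundary = _boundary_junctions(rec, gene)
        if not boundary:
            continue
        for sid in sample_ids:
            counts_here = [lin_junction_counts[sid].get(b, 0) for b in boundary]
            linear.loc[rec.circ_id, sid] = int(math.floor(float(np.mean(counts_here))))
    counts = JunctionCounts(bsj, linear, samples=meta)
    return counts, report


# ---------------------------------------------------------------------------
# Normalization


def compute_rpm(counts: pd.DataFrame, mappable_reads: pd.Series) -> pd.DataFrame:
    """Reads per million mappable reads, column-wise."""
    mappable = mappable_reads.reindex(counts.columns)
    if mappable.isna().any():
        missing = list(mappable[mappable.isna()].index)
        raise ValueError(f"missing mappable-read totals for samples: {missing}")
    if (mappable <= 0).any():
        bad = list(mappable[mappable <= 0].index)
        raise ValueError(f"non-positive mappable-read totals for samples: {bad}")
    return counts * 1e6 / mappable


def compute_fcr(bsj, linear):
    """Fraction of circRNA-specific reads: bsj / (bsj + linear).

    Works element-wise on scalars, Series, or DataFrames; NaN marks the
    undefined case where both counts are zero.
    """
    if np.isscalar(bsj):
        if bsj < 0 or linear < 0:
            raise ValueError("counts must be >= 0")
        return bsj / (bsj + linear) if bsj + linear > 0 else math.nan
    bsj = bsj.astype(float)
    linear = linear.astype(float)
    total = bsj + linear
    return bsj / total.where(total > 0)


def normalize_housekeeping(levels: pd.DataFrame, hk_counts: pd.Series) -> pd.DataFrame:
    """Divide per-sample levels by a housekeeping gene's read count.

    Samples with a zero housekeeping count get NaN and a warning; report one
    housekeeping gene at a time.
    """
    hk = hk_counts.reindex(levels.columns).astype(float)
    if hk.isna().any():
        raise ValueError(f"missing housekeeping counts for: {list(hk[hk.isna()].index)}")
    zero = hk == 0
    if zero.any():
        warnings.warn(
            f"zero housekeeping count for samples {list(hk[zero].index)}; values undefined",
            stacklevel=2,
        )
    return levels / hk.where(~zero)


# ---------------------------------------------------------------------------
# Tiers and annotation status


def classify_tiers(
    counts: JunctionCounts,
    meta: Sequence[SampleMeta],
    presence_min: int = 1,
    validated_reads: int = 5,
    validated_samples: int = 2,
) -> pd.DataFrame:
    """Assign each circRNA its highest tier: all < validated < common.

    *validated*: at least ``validated_samples`` samples (any group) with at
    least ``validated_reads`` BSJ reads. *common*: within the control group
    or within the DM group, at least (group size - 1) samples show at least
    ``presence_min`` BSJ reads.
    """
    group_of = {m.sample_id: m.group for m in meta}
    ctrl_cols = [c for c in counts.bsj.columns if group_of.get(c) == "control"]
    dm_cols = [c for c in counts.bsj.columns if group_of.get(c) == "DM"]
    for name, cols in (("control", ctrl_cols), ("DM", dm_cols)):
        if 0 < len(cols) < 2:
            warnings.warn(f"group {name} has <2 samples; 'common' undefined there", stacklevel=2)
    bsj = counts.bsj
    validated = (bsj >= validated_reads).sum(axis=1) >= validated_samples
    common = pd.Series(False, index=bsj.index)
    for cols in (ctrl_cols, dm_cols):
        if len(cols) >= 2:
            present = (bsj[cols] >= presence_min).sum(axis=1)
            common |= present >= len(cols) - 1
    tier = pd.Series("all", index=bsj.index)
    tier[validated] = "validated"
    tier[common] = "common"
    return pd.DataFrame({"tier": tier, "validated": validated, "common": common})


def tier_fractions(n_all: int, n_validated: int, n_common: int) -> dict[str, float]:
    """Validated and common tier sizes as percentages of all detected circRNAs."""
    if n_all <= 0:
        raise ValueError("n_all must be > 0")
    if not 0 <= n_common <= n_validated <= n_all:
        raise ValueError("expected n_common <= n_validated <= n_all")
    return {
        "validated_pct": 100.0 * n_validated / n_all,
        "common_pct": 100.0 * n_common / n_all,
    }


def annotate_known(
    circs: Sequence[CircRecord], catalog: CircCatalog, tolerance: int = 1
) -> pd.Series:
    """Flag circRNAs matching a catalog record within +/-tolerance per boundary.

    The boundary tolerance absorbs the one-base inconsistencies between
    published catalog coordinate conventions.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for rec in catalog.records:
        by_chrom.setdefault(rec.interval.chrom, []).append(
            (rec.interval.start, rec.interval.end)
        )
    flags = {}
    for c in circs:
        hits = by_chrom.get(c.interval.chrom, [])
        flags[c.circ_id] = any(
            abs(c.interval.start - s) <= tolerance and abs(c.interval.end - e) <= tolerance
            for s, e in hits
        )
    return pd.Series(flags, name="known")
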