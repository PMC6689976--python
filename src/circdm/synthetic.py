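"""Synthetic data generation for the full pipeline.

Everything downstream of this module (junction detection, normalization,
differential statistics, pooling, motif scanning, severity correlation) is
exercised on data produced here: a toy genome with multi-exon genes,
exon-boundary circRNAs (including planted multi-circRNA genes), overdispersed
negative-binomial junction counts with a multiplicative circRNA-specific
group effect, error-free 60-nt junction-spanning reads, Poisson-partitioned
droplet runs, and phenotypes linearly coupled to per-sample circRNA burden.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    CircCatalog,
    CircRecord,
    GeneModel,
    GenomicInterval,
    JunctionCounts,
    SampleMeta,
)

BASES = np.array(list("ACGT"))


@dataclass
class SimDesign:
    """Study design for the two-group count simulation.

    ``global_fold`` multiplies every circRNA's mean abundance in the DM
    group; a ``de_fraction`` of circRNAs receive an extra per-circRNA fold
    drawn from ``de_fold_range`` on top of it. Linear junction counts carry
    no group effect, so the circ-to-linear fraction rises in DM.
    """

    n_control: int = 11
    n_dm: int = 12
    global_fold: float = 1.5
    de_fraction: float = 0.1
    de_fold_range: tuple[float, float] = (1.5, 4.0)
    libsize_range: tuple[int, int] = (500_000, 2_000_000)
    nb_dispersion: float = 0.2
    base_rpm_log_mean: float = np.log(5.0)
    base_rpm_log_sd: float = 1.0
    linear_ratio_range: tuple[float, float] = (9.0, 19.0)
    tissue: str = "TA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_dm < 1:
            raise ValueError("sample counts must be >= 1")
        if self.global_fold <= 0:
            raise ValueError("global_fold must be > 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0,1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class SimTruth:
    """Planted ground truth for one simulated data set."""

    base_rpm: pd.Series  # per-circ base abundance (RPM scale, control group)
    fold: pd.Series  # per-circ total DM fold (global x extra)
    is_de: pd.Series  # bool: received an extra per-circ effect
    gene_of: pd.Series  # circ_id -> gene_id
    strength_slope: float | None = None
    psi_slopes: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Annotation + genome


def make_annotation(
    n_genes: int = 20,
    exons_per_gene_range: tuple[int, int] = (4, 8),
    exon_len_range: tuple[int, int] = (120, 300),
    intron_len_range: tuple[int, int] = (200, 800),
    intergenic: int = 400,
    chrom: str = "chrS",
    seed: int = 0,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Lay out ``n_genes`` multi-exon genes on one synthetic chromosome.

    Returns the gene models and the genome as a chrom -> sequence mapping
    with uniform base composition.
    """
    for name, rng_ in (
        ("exons_per_gene_range", exons_per_gene_range),
        ("exon_len_range", exon_len_range),
        ("intron_len_range", intron_len_range),
    ):
        if rng_[0] < 1 or rng_[1] < rng_[0]:
            raise ValueError(f"invalid {name}: {rng_}")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    pos = intergenic
    for g in range(n_genes):
        n_exons = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
        exons = []
        for e in range(n_exons):
            length = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + length))
            pos += length
            if e < n_exons - 1:
                pos += int(rng.integers(intron_len_range[0], intron_len_range[1] + 1))
        genes.append(GeneModel(gene_id=f"gene{g:03d}", name=f"GENE{g:03d}", exons=tuple(exons)))
        pos += intergenic
    seq = "".join(rng.choice(BASES, size=pos + intergenic))
    return genes, {chrom: seq}


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# circRNA catalog


def make_catalog(
    annotation: Sequence[GeneModel],
    circ_per_gene_range: tuple[int, int] = (1, 3),
    n_top_mcg: int = 0,
    top_mcg_circs: tuple[int, int] = (11, 14),
    distinct_boundaries: bool = False,
    seed: int = 0,
) -> tuple[CircCatalog, dict[str, str]]:
    """Plant exon-boundary circRNAs on the annotation.

    Every circRNA spans whole exons: its start is an annotated exon start
    and its end an annotated exon end of the same gene. Exactly
    ``n_top_mcg`` genes (the ones with the most exon pairs) receive more
    than 10 circRNAs. Returns the catalog and the circ -> gene truth map.

    With ``distinct_boundaries`` the circRNAs of a gene share no canonical
    boundary junction (distinct first exons beyond the gene start, distinct
    last exons before the gene end), so corresponding linear junction reads
    are attributable to exactly one circRNA — the regime in which the
    detector recovers the simulated linear count matrix exactly. This caps
    circRNAs per gene near the exon count and is incompatible with planted
    top-MCGs.
    """
    rng = np.random.default_rng(seed)
    if n_top_mcg > len(annotation):
        raise ValueError("n_top_mcg exceeds number of genes")
    if distinct_boundaries and n_top_mcg > 0:
        raise ValueError("distinct_boundaries is incompatible with planted top-MCGs")

    def _pairs(gene: GeneModel) -> list[tuple[int, int]]:
        # all whole-exon spans; the full-gene span is excluded because it has
        # no canonical boundary junction to carry corresponding linear reads
        n_e = len(gene.exons)
        return [
            (i, j)
            for i in range(n_e)
            for j in range(i, n_e)
            if not (i == 0 and j == n_e - 1)
        ]

    capacity = {g.gene_id: len(_pairs(g)) for g in annotation}
    by_capacity = sorted(annotation, key=lambda g: capacity[g.gene_id], reverse=True)
    top_genes = {g.gene_id for g in by_capacity[:n_top_mcg]}
    for gid in top_genes:
        if capacity[gid] < top_mcg_circs[0]:
            raise ValueError(
                f"gene {gid} has only {capacity[gid]} exon pairs; cannot host a top-MCG"
            )

    records: list[CircRecord] = []
    support: dict[str, list[int]] = {}
    ratio: dict[str, float] = {}
    gene_map: dict[str, str] = {}
    k = 0
    for gene in annotation:
        if gene.gene_id in top_genes:
            want = int(rng.integers(top_mcg_circs[0], top_mcg_circs[1] + 1))
        else:
            want = int(rng.integers(circ_per_gene_range[0], circ_per_gene_range[1] + 1))
        want = min(want, capacity[gene.gene_id])
        pairs = _pairs(gene)
        if want == 0:
            continue
        if distinct_boundaries:
            order = rng.permutation(len(pairs))
            n_e = len(gene.exons)
            # the canonical junction between exons k and k+1 is the upstream
            # boundary of a circ starting at k+1 and the downstream boundary
            # of one ending at k; all used junctions must be distinct
            used: set[int] = set()
            picked: list[int] = []
            for idx in order:
                i, j = pairs[int(idx)]
                needed = []
                if i > 0:
                    needed.append(i - 1)
                if j < n_e - 1:
                    needed.append(j)
                if any(k in used for k in needed):
                    continue
                picked.append(int(idx))
                used.update(needed)
                if len(picked) == want:
                    break
            chosen = np.array(picked)
        else:
            chosen = rng.choice(len(pairs), size=want, replace=False)
        for idx in sorted(int(c) for c in chosen):
            i, j = pairs[idx]
            interval = GenomicInterval(
                gene.chrom, gene.exons[i].start, gene.exons[j].end
            )
            cid = f"circ{k:04d}"
            k += 1
            records.append(CircRecord(circ_id=cid, interval=interval, gene_id=gene.gene_id))
            gene_map[cid] = gene.gene_id
            support[cid] = [int(x) for x in rng.poisson(30, size=2) + 1]
            ratio[cid] = float(np.exp(rng.normal(np.log(0.08), 1.0)))
    return CircCatalog(records=records, support=support, ratio=ratio), gene_map


# ---------------------------------------------------------------------------
# Junction counts


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB with variance mean + dispersion * mean^2 (Poisson when dispersion=0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, p[pos])
    return out


def simulate_counts(
    catalog: CircCatalog, design: SimDesign
) -> tuple[JunctionCounts, list[SampleMeta], SimTruth]:
    """Draw BSJ and linear junction counts under the two-group design."""
    rng = np.random.default_rng(design.seed)
    circ_ids = [r.circ_id for r in catalog.records]
    n_circ = len(circ_ids)
    sample_ids = [f"ctrl{i:02d}" for i in range(design.n_control)] + [
        f"dm{i:02d}" for i in range(design.n_dm)
    ]
    groups = ["control"] * design.n_control + ["DM"] * design.n_dm
    libsizes = rng.integers(design.libsize_range[0], design.libsize_range[1] + 1, len(sample_ids))

    base_rpm = np.exp(rng.normal(design.base_rpm_log_mean, design.base_rpm_log_sd, n_circ))
    is_de = rng.random(n_circ) < design.de_fraction
    extra = np.where(
        is_de, rng.uniform(design.de_fold_range[0], design.de_fold_range[1], n_circ), 1.0
    )
    fold = design.global_fold * extra
    lin_ratio = rng.uniform(design.linear_ratio_range[0], design.linear_ratio_range[1], n_circ)

    bsj = np.zeros((n_circ, len(sample_ids)), dtype=int)
    lin = np.zeros_like(bsj)
    for s, (lib, grp) in enumerate(zip(libsizes, groups)):
        scale = lib / 1e6
        mean_bsj = base_rpm * scale * (fold if grp == "DM" else 1.0)
        mean_lin = base_rpm * lin_ratio * scale
        bsj[:, s] = _nb_sample(rng, mean_bsj, design.nb_dispersion)
        lin[:, s] = _nb_sample(rng, mean_lin, design.nb_dispersion)

    meta = [
        SampleMeta(sample_id=sid, group=grp, tissue=design.tissue, mappable_reads=int(lib))
        for sid, grp, lib in zip(sample_ids, groups, libsizes)
    ]
    counts = JunctionCounts(
        pd.DataFrame(bsj, index=circ_ids, columns=sample_ids),
        pd.DataFrame(lin, index=circ_ids, columns=sample_ids),
        samples=meta,
    )
    truth = SimTruth(
        base_rpm=pd.Series(base_rpm, index=circ_ids),
        fold=pd.Series(fold, index=circ_ids),
        is_de=pd.Series(is_de, index=circ_ids),
        gene_of=pd.Series(catalog.gene_map()),
    )
    return counts, meta, truth


# ---------------------------------------------------------------------------
# Droplets


def simulate_droplets(
    lambda_true: float,
    n_droplets: int = 20_000,
    seed: int = 0,
    *,
    well_id: str = "A01",
    sample_id: str = "s1",
    circ_id: str = "circ",
    target: str = "circular",
    dilution: float = 1.0,
):
    """One ddPCR well: positives ~ Binomial(n, 1 - exp(-lambda))."""
    from .ddpcr import DropletRun

    if lambda_true < 0:
        raise ValueError("lambda_true must be >= 0")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    rng = np.random.default_rng(seed)
    p_pos = 1.0 - np.exp(-lambda_true)
    positives = int(rng.binomial(n_droplets, p_pos))
    return DropletRun(
        well_id=well_id,
        sample_id=sample_id,
        circ_id=circ_id,
        target=target,
        positives=positives,
        total=n_droplets,
        dilution=dilution,
    )


# ---------------------------------------------------------------------------
# Reads


def _circ_boundary_junctions(
    circ: CircRecord, gene: GeneModel
) -> list[tuple[int, int]]:
    """Canonical (donor_end, acceptor_start) junctions at the circ boundaries.

    Upstream junction: preceding exon -> first circ exon; downstream:
    last circ exon -> following exon. Terminal circ exons have no junction
    on that side.
    """
    starts = [e.start for e in gene.exons]
    ends = [e.end for e in gene.exons]
    if circ.interval.start not in starts or circ.interval.end not in ends:
        raise ValueError(f"{circ.circ_id}: boundaries not on exon boundaries of {gene.gene_id}")
    i = starts.index(circ.interval.start)
    j = ends.index(circ.interval.end)
    out = []
    if i > 0:
        out.append((gene.exons[i - 1].end, circ.interval.start))
    if j < len(gene.exons) - 1:
        out.append((circ.interval.end, gene.exons[j + 1].start))
    return out


def simulate_reads(
    catalog: CircCatalog,
    counts: JunctionCounts,
    annotation: Sequence[GeneModel],
    genome: Mapping[str, str],
    read_len: int = 60,
    seed: int = 0,
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Emit error-free junction-spanning reads realizing the count matrices.

    For each BSJ count unit one read centered on the head-to-tail junction is
    produced. Each linear count unit is emitted once at *every* available
    canonical boundary junction of the circRNA, so the detector's
    average-over-boundaries rule recovers the matrix exactly. circRNAs with
    an exon shorter than half the read length are skipped with a warning.

    Returns per-sample ``(read_id, sequence)`` lists and a truth table.
    """
    import warnings

    genes = {g.gene_id: g for g in annotation}
    half_l = read_len // 2
    half_r = read_len - half_l
    reads: dict[str, list[tuple[str, str]]] = {s: [] for s in counts.sample_ids}
    truth_rows = []
    n = 0
    for rec in catalog.records:
        gene = genes.get(rec.gene_id)
        if gene is None:
            warnings.warn(f"{rec.circ_id}: gene {rec.gene_id} not in annotation; skipped")
            continue
        seq = genome[rec.interval.chrom]
        circ_exons = [
            e for e in gene.exons if rec.interval.start <= e.start and e.end <= rec.interval.end
        ]
        if not circ_exons or min(len(e) for e in circ_exons) < max(half_l, half_r):
            warnings.warn(f"{rec.circ_id}: exon shorter than half read length; skipped")
            continue
        # head-to-tail: end of last circ exon joined to start of first circ exon
        bsj_seq = (
            seq[rec.interval.end - half_l : rec.interval.end]
            + seq[rec.interval.start : rec.interval.start + half_r]
        )
        boundary = _circ_boundary_junctions(rec, gene)
        lin_seqs = [
            seq[d - half_l : d] + seq[a : a + half_r] for d, a in boundary
        ]
        for sid in counts.sample_ids:
            for _ in range(int(counts.bsj.loc[rec.circ_id, sid])):
                rid = f"{sid}|bsj|{rec.circ_id}|{n}"
                reads[sid].append((rid, bsj_seq))
                truth_rows.append((rid, sid, rec.circ_id, "bsj", ""))
                n += 1
            for _ in range(int(counts.linear.loc[rec.circ_id, sid])):
                for (d, a), ls in zip(boundary, lin_seqs):
                    rid = f"{sid}|lin|{rec.circ_id}|{n}"
                    reads[sid].append((rid, ls))
                    truth_rows.append(
                        (rid, sid, rec.circ_id, "linear", f"{rec.gene_id}:{d}-{a}")
                    )
                    n += 1
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "sample_id", "circ_id", "kind", "junction"]
    )
    return reads, truth


def expected_linear_counts(
    catalog: CircCatalog,
    annotation: Sequence[GeneModel],
    truth: pd.DataFrame,
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Linear count matrix a lossless detector should report for these reads.

    Canonical junctions can be shared by circRNAs of the same gene, so the
    per-circRNA linear count is the floor of the mean of emitted junction
    read totals over the circRNA's boundary junctions — identical to the
    detector's accounting. On a ``distinct_boundaries`` catalog this equals
    the simulated linear matrix.
    """
    genes = {g.gene_id: g for g in annotation}
    lin = truth[truth["kind"] == "linear"]
    per_junction = lin.groupby(["sample_id", "junction"]).size()
    circ_ids = [r.circ_id for r in catalog.records]
    out = pd.DataFrame(0, index=circ_ids, columns=list(sample_ids))
    for rec in catalog.records:
        gene = genes.get(rec.gene_id)
        if gene is None:
            continue
        try:
            boundary = _circ_boundary_junctions(rec, gene)
        except ValueError:
            continue
        keys = [f"{rec.gene_id}:{d}-{a}" for d, a in boundary]
        if not keys:
            continue
        for sid in sample_ids:
            vals = [int(per_junction.get((sid, k), 0)) for k in keys]
            out.loc[rec.circ_id, sid] = int(np.floor(np.mean(vals)))
    return out


def write_reads_fasta(reads: Mapping[str, list[tuple[str, str]]], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sid, recs in reads.items():
        p = outdir / f"{sid}.reads.fasta"
        with open(p, "w") as fh:
            for rid, s in recs:
                fh.write(f">{rid}\n{s}\n")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Phenotypes


def circ_burden(counts: JunctionCounts) -> pd.Series:
    """Per-sample cumulative circRNA RPM (the phenotype-coupled burden)."""
    mappable = counts.mappable_reads()
    return counts.bsj.sum(axis=0) * 1e6 / mappable


def simulate_phenotypes(
    counts: JunctionCounts,
    meta: Sequence[SampleMeta],
    strength_slope: float = -1.0,
    psi_slopes: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[SampleMeta]:
    """Couple strength and PSI phenotypes linearly to circRNA burden.

    ``strength = intercept + strength_slope * burden + N(0, noise_sd)`` with
    the intercept chosen so strengths stay positive. PSI values are built
    the same way around 0.5 (per-exon signed slope on standardized burden,
    noise on the same scale) and clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    burden = circ_burden(counts)
    psi_slopes = dict(psi_slopes or {})
    intercept = -strength_slope * float(burden.max()) * 1.2 if strength_slope < 0 else 0.0
    z = (burden - burden.mean()) / (burden.std(ddof=1) or 1.0)
    out = []
    for m in meta:
        b = float(burden[m.sample_id])
        strength = intercept + strength_slope * b + float(rng.normal(0.0, noise_sd))
        psi = {}
        for exon, slope in psi_slopes.items():
            noise = float(rng.normal(0.0, noise_sd / (burden.std(ddof=1) or 1.0)))
            psi[exon] = float(np.clip(0.5 + slope * float(z[m.sample_id]) + noise, 0.0, 1.0))
        out.append(
            SampleMeta(
                sample_id=m.sample_id,
                group=m.group,
                tissue=m.tissue,
                mappable_reads=m.mappable_reads,
                strength=strength,
                psi=psi,
            )
        )
    return out


def noise_for_target_r(burden_sd: float, slope: float, target_r: float) -> float:
    """Noise SD making the population |R| between burden and phenotype equal
    ``|target_r|`` for the given slope and burden spread."""
    if not 0 < abs(target_r) <= 1:
        raise ValueError("target_r must be in (0, 1]")
    return abs(slope) * burden_sd * np.sqrt(1.0 / target_r**2 - 1.0)
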