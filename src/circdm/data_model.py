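"""Core domain types, file I/O, locus parsing, and circRNA candidate selection.

Coordinate convention: every interval stored by this package is 0-based,
half-open ``[start, end)``. circBase-style locus strings (``"chrom:a|b"``)
are parsed verbatim with ``a`` treated as the 0-based start; published
catalogs are internally inconsistent by one base at some boundaries, so
catalog matching elsewhere tolerates +/-1 on either coordinate rather than
resolving the convention.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class LocusParseError(ValueError):
    """Raised when a circBase-style locus string cannot be parsed."""


class AnnotationError(ValueError):
    """Raised when a gene annotation file is malformed."""


VALID_STRANDS = ("+", "-", "unknown")


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval: start={self.start} end={self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


_LOCUS_RE = re.compile(r"^([^:|\s]+):(\d+)\|(\d+)$")


def parse_locus(text: str) -> GenomicInterval:
    """Parse a circBase-style locus string such as ``"11:33307958|33309057"``."""
    m = _LOCUS_RE.match(text.strip())
    if m is None:
        raise LocusParseError(f"malformed locus string: {text!r}")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start >= end:
        raise LocusParseError(f"locus has start >= end: {text!r}")
    return GenomicInterval(chrom, start, end)


def format_locus(interval: GenomicInterval) -> str:
    """Inverse of :func:`parse_locus`."""
    return f"{interval.chrom}:{interval.start}|{interval.end}"


@dataclass(frozen=True)
class GeneModel:
    """A gene as an ordered, non-overlapping exon chain on one chromosome.

    Introns are derived: exactly the gaps between consecutive exons.
    """

    gene_id: str
    name: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise AnnotationError(f"gene {self.gene_id}: exons on multiple chromosomes")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted "
                    f"({a.start}-{a.end} then {b.start}-{b.end})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start))
        return tuple(out)


@dataclass
class CircRecord:
    """One circRNA species: back-splice donor/acceptor span plus bookkeeping."""

    circ_id: str
    interval: GenomicInterval
    gene_id: str = "n/a"
    catalog_id: str | None = None
    motif_count: int | None = None

    @property
    def locus(self) -> str:
        return format_locus(self.interval)


@dataclass
class CircCatalog:
    """A set of circRNAs with optional per-study read support and circ:mRNA ratio."""

    records: list[CircRecord]
    support: dict[str, list[int]] = field(default_factory=dict)
    ratio: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.circ_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate circ_id in catalog")
        for cid, counts in self.support.items():
            if any(c < 0 for c in counts):
                raise ValueError(f"negative support count for {cid}")
        for cid, r in self.ratio.items():
            if r < 0:
                raise ValueError(f"negative ratio for {cid}")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, circ_id: str) -> CircRecord:
        for r in self.records:
            if r.circ_id == circ_id:
                return r
        raise KeyError(circ_id)

    def gene_map(self) -> dict[str, str]:
        return {r.circ_id: r.gene_id for r in self.records}

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "circ_id": r.circ_id,
                    "locus": r.locus,
                    "gene": r.gene_id,
                    "catalog_id": r.catalog_id if r.catalog_id is not None else ".",
                    "support": ";".join(str(c) for c in self.support.get(r.circ_id, [])) or ".",
                    "ratio": self.ratio.get(r.circ_id, "."),
                    "motif_count": r.motif_count if r.motif_count is not None else ".",
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CircCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str)
        records, support, ratio = [], {}, {}
        for _, row in df.iterrows():
            rec = CircRecord(
                circ_id=row["circ_id"],
                interval=parse_locus(row["locus"]),
                gene_id=row["gene"],
                catalog_id=None if row["catalog_id"] == "." else row["catalog_id"],
                motif_count=None if row["motif_count"] == "." else int(row["motif_count"]),
            )
            records.append(rec)
            if row["support"] != ".":
                support[rec.circ_id] = [int(x) for x in row["support"].split(";")]
            if row["ratio"] != ".":
                ratio[rec.circ_id] = float(row["ratio"])
        return cls(records=records, support=support, ratio=ratio)


@dataclass
class SampleMeta:
    """Per-sample metadata: group label, tissue, sequencing depth, phenotypes."""

    sample_id: str
    group: str  # "control" or "DM"
    tissue: str = "TA"
    mappable_reads: int | None = None
    strength: float | None = None
    psi: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("control", "DM"):
            raise ValueError(f"group must be 'control' or 'DM', got {self.group!r}")
        if self.mappable_reads is not None and self.mappable_reads <= 0:
            raise ValueError(f"mappable_reads must be > 0 for {self.sample_id}")
        for exon, v in self.psi.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"PSI out of [0,1] for {self.sample_id} {exon}: {v}")


def write_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    psi_keys = sorted({k for m in meta for k in m.psi})
    rows = []
    for m in meta:
        row = {
            "sample_id": m.sample_id,
            "group": m.group,
            "tissue": m.tissue,
            "mappable_reads": m.mappable_reads if m.mappable_reads is not None else ".",
            "strength": m.strength if m.strength is not None else ".",
        }
        for k in psi_keys:
            row[f"psi:{k}"] = m.psi.get(k, ".")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        psi = {}
        for col in df.columns:
            if col.startswith("psi:") and row[col] != ".":
                psi[col[4:]] = float(row[col])
        out.append(
            SampleMeta(
                sample_id=row["sample_id"],
                group=row["group"],
                tissue=row.get("tissue", "TA"),
                mappable_reads=None if row["mappable_reads"] == "." else int(row["mappable_reads"]),
                strength=None if row["strength"] == "." else float(row["strength"]),
                psi=psi,
            )
        )
    return out


class JunctionCounts:
    """Back-splice and corresponding linear junction read counts.

    Two integer matrices (circRNAs x samples) sharing index and columns,
    plus the sample metadata they refer to.
    """

    def __init__(
        self,
        bsj: pd.DataFrame,
        linear: pd.DataFrame,
        samples: Sequence[SampleMeta] | None = None,
    ) -> None:
        if not bsj.index.equals(linear.index) or not bsj.columns.equals(linear.columns):
            raise ValueError("bsj and linear matrices must share index and columns")
        for name, df in (("bsj", bsj), ("linear", linear)):
            _validate_count_frame(df, name)
        if samples is not None:
            sample_ids = {m.sample_id for m in samples}
            missing = [c for c in bsj.columns if c not in sample_ids]
            if missing:
                raise ValueError(f"count columns missing from metadata: {missing}")
        self.bsj = bsj.astype(int)
        self.linear = linear.astype(int)
        self.samples = list(samples) if samples is not None else None

    @property
    def circ_ids(self) -> list[str]:
        return list(self.bsj.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.bsj.columns)

    def mappable_reads(self) -> pd.Series:
        if self.samples is None:
            raise ValueError("no sample metadata attached")
        vals = {}
        for m in self.samples:
            if m.sample_id in self.bsj.columns:
                if m.mappable_reads is None:
                    raise ValueError(f"sample {m.sample_id} lacks mappable_reads")
                vals[m.sample_id] = m.mappable_reads
        return pd.Series(vals).reindex(self.bsj.columns)


def _validate_count_frame(df: pd.DataFrame, name: str) -> None:
    arr = df.to_numpy()
    if arr.size and not np.issubdtype(arr.dtype, np.number):
        raise ValueError(f"{name}: non-numeric cells present")
    if arr.size:
        if np.any(arr < 0):
            i, j = map(int, next(zip(*np.nonzero(arr < 0))))
            raise ValueError(
                f"{name}: negative count at row {df.index[i]!r} column {df.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            bad = np.nonzero(arr != np.round(arr))
            i, j = int(bad[0][0]), int(bad[1][0])
            raise ValueError(
                f"{name}: non-integer count at row {df.index[i]!r} column {df.columns[j]!r}"
            )


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    _validate_count_frame(df, str(path))
    return df.astype(int)


def read_counts(
    bsj_path: str | Path,
    linear_path: str | Path,
    meta: Sequence[SampleMeta] | None = None,
) -> JunctionCounts:
    """Read paired BSJ / linear count TSVs (rows: circ_id; columns: sample ids)."""
    return JunctionCounts(
        read_count_matrix(bsj_path), read_count_matrix(linear_path), samples=meta
    )


def write_counts(counts: JunctionCounts, bsj_path: str | Path, linear_path: str | Path) -> None:
    counts.bsj.to_csv(bsj_path, sep="\t", index_label="circ_id")
    counts.linear.to_csv(linear_path, sep="\t", index_label="circ_id")


# ---------------------------------------------------------------------------
# Annotation I/O


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene models from a GTF (Ensembl dialect) or BED12 file.

    GTF 1-based inclusive coordinates are converted to the internal 0-based
    half-open convention. Exons are grouped by ``gene_id``.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff", ".gff3"):
        return _read_gtf(path)
    if suffix in (".bed", ".bed12"):
        return _read_bed12(path)
    raise AnnotationError(f"unknown annotation format: {path.name}")


def _read_gtf(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_gene: dict[str, list[GenomicInterval]] = {}
    names: dict[str, str] = {}
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        gid = feat.attributes.get("gene_id", ["?"])[0]
        if feat.start > feat.end:
            raise AnnotationError(f"gene {gid}: exon start > end at {feat.seqid}:{feat.start}")
        strand = feat.strand if feat.strand in ("+", "-") else "unknown"
        by_gene.setdefault(gid, []).append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
        )
        names.setdefault(gid, feat.attributes.get("gene_name", [gid])[0])
    genes = []
    for gid, exons in by_gene.items():
        exons = sorted(exons, key=lambda e: e.start)
        try:
            genes.append(GeneModel(gene_id=gid, name=names[gid], exons=tuple(exons)))
        except AnnotationError as err:
            raise AnnotationError(str(err)) from None
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(f"{path.name}:{lineno}: expected 12 BED columns")
            chrom, chrom_start, name = fields[0], int(fields[1]), fields[3]
            strand = fields[5] if fields[5] in ("+", "-") else "unknown"
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != int(fields[9]) or len(starts) != int(fields[9]):
                raise AnnotationError(f"{path.name}:{lineno}: blockCount mismatch for {name}")
            exons = tuple(
                GenomicInterval(chrom, chrom_start + s, chrom_start + s + sz, strand)
                for s, sz in zip(starts, sizes)
            )
            genes.append(GeneModel(gene_id=name, name=name, exons=exons))
    return genes


def write_annotation_bed12(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            starts = ",".join(str(e.start - span.start) for e in g.exons)
            sizes = ",".join(str(len(e)) for e in g.exons)
            strand = g.exons[0].strand if g.exons[0].strand in ("+", "-") else "."
            fh.write(
                "\t".join(
                    [
                        span.chrom,
                        str(span.start),
                        str(span.end),
                        g.gene_id,
                        "0",
                        strand,
                        str(span.start),
                        str(span.end),
                        "0",
                        str(len(g.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Candidate selection


def select_candidate_circrnas(
    catalog: CircCatalog,
    min_reads: int = 20,
    min_studies: int = 2,
    min_ratio: float = 0.10,
    min_motifs: int = 10,
) -> tuple[list[CircRecord], list[CircRecord]]:
    """Apply the two candidate-selection filters to a supported catalog.

    Both filters first require read support of at least ``min_reads`` in at
    least ``min_studies`` source studies. The *high-level* set additionally
    requires a circRNA:mRNA ratio of at least ``min_ratio``; the *motif* set
    requires at least ``min_motifs`` YGCY motifs in the flanking-intron
    windows. The two sets may overlap.
    """
    high, motif = [], []
    for rec in catalog.records:
        support = catalog.support.get(rec.circ_id)
        if support is None:
            warnings.warn(f"no support data for {rec.circ_id}; skipped", stacklevel=2)
            continue
        if sum(1 for c in support if c >= min_reads) < min_studies:
            continue
        if catalog.ratio.get(rec.circ_id, 0.0) >= min_ratio:
            high.append(rec)
        if rec.motif_count is not None and rec.motif_count >= min_motifs:
            motif.append(rec)
    return high, motif
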