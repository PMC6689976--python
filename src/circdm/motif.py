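"""YGCY (MBNL-binding) motif counting in circRNA-flanking intron windows.

MBNL splicing factors bind YGCY elements (Y = C or T). For each circRNA
whose boundaries coincide with exon boundaries of its gene, two fixed
windows of the flanking introns are scanned: the last ``w`` nt of the
intron preceding the circRNA's first exon and the first ``w`` nt of the
intron following its last exon (truncated to the intron length; absent for
terminal exons). Overlapping occurrences are each counted, and a motif must
lie entirely inside the window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .data_model import CircRecord, GeneModel, GenomicInterval

DEFAULT_WINDOW = 300

_YGCY = re.compile(r"(?=[CT]GC[CT])")
_VALID = re.compile(r"^[ACGTN]*$")


def count_ygcy(sequence: str) -> int:
    """Count YGCY occurrences, overlapping matches included; N never matches."""
    seq = sequence.upper()
    if not _VALID.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"invalid characters in sequence: {bad}")
    return len(_YGCY.findall(seq))


def flanking_windows(
    circ: CircRecord, gene: GeneModel, w: int = DEFAULT_WINDOW
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """Intronic windows abutting the circRNA's first and last exons.

    Returns (upstream, downstream); ``None`` marks an absent flanking intron
    (circRNA starting or ending at a terminal exon).
    """
    starts = [e.start for e in gene.exons]
    ends = [e.end for e in gene.exons]
    if circ.interval.start not in starts or circ.interval.end not in ends:
        raise ValueError(
            f"{circ.circ_id}: boundaries not on exon boundaries of {gene.gene_id}"
        )
    i = starts.index(circ.interval.start)
    j = ends.index(circ.interval.end)
    upstream = downstream = None
    if i > 0:
        intron_start, intron_end = gene.exons[i - 1].end, gene.exons[i].start
        if intron_end > intron_start:
            wlen = min(w, intron_end - intron_start)
            upstream = GenomicInterval(gene.chrom, intron_end - wlen, intron_end)
    if j < len(gene.exons) - 1:
        intron_start, intron_end = gene.exons[j].end, gene.exons[j + 1].start
        if intron_end > intron_start:
            wlen = min(w, intron_end - intron_start)
            downstream = GenomicInterval(gene.chrom, intron_start, intron_start + wlen)
    return upstream, downstream


@dataclass
class MotifReport:
    circ_id: str
    upstream_count: int
    downstream_count: int

    @property
    def n(self) -> int:
        return self.upstream_count + self.downstream_count


def motif_report(
    circs: Sequence[CircRecord],
    annotation: Sequence[GeneModel],
    genome: Mapping[str, str],
    w: int = DEFAULT_WINDOW,
) -> list[MotifReport]:
    """Count YGCY motifs in both flanking windows; fills ``motif_count``."""
    genes = {g.gene_id: g for g in annotation}
    out = []
    for circ in circs:
        gene = genes.get(circ.gene_id)
        if gene is None:
            continue
        up, down = flanking_windows(circ, gene, w=w)
        seq = genome[circ.interval.chrom]
        n_up = count_ygcy(seq[up.start : up.end]) if up is not None else 0
        n_down = count_ygcy(seq[down.start : down.end]) if down is not None else 0
        report = MotifReport(circ.circ_id, n_up, n_down)
        circ.motif_count = report.n
        out.append(report)
    return out


def motif_table(reports: Sequence[MotifReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "circ_id": r.circ_id,
                "upstream": r.upstream_count,
                "downstream": r.downstream_count,
                "n": r.n,
            }
            for r in reports
        ]
    )
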