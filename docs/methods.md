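# Methods

This note records the models, conventions, and design choices behind the
package, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and domain objects

All intervals are 0-based half-open. circBase-style locus strings
(`chrom:a|b`) are parsed verbatim with `a` as the 0-based start. Published
circRNA catalogs are internally inconsistent by one base at some boundaries
(the same circHIPK3 locus appears with starts differing by 1 in different
tables of the literature), and no authoritative convention exists for these
strings; rather than resolve it, catalog matching (`quantify.annotate_known`)
tolerates ±1 on either boundary. Strand is carried but never used for
matching — the relevant catalogs do not state it. A circRNA is assigned to
the gene whose annotated exon boundaries both of its back-splice coordinates
touch, otherwise `"n/a"`; `"n/a"` circRNAs stay in circRNA-level tallies but
are excluded from gene-level MCG statistics.

## ddPCR quantification

Template molecules distribute over droplets as Poisson, so
`λ = −ln((total − positives)/total)`; a fully positive well is a saturation
error, not an estimate. Copies per µl are `λ·dilution/volume` with a
droplet volume default of 0.00085 µl (QX200 convention); FCP is invariant
to this volume and to any dilution shared by the circular and linear assay,
which the tests assert. The "more than half excluded" drop rule is a strict
inequality: 3 excluded of 6 retains the circRNA, 4 drops it. Group
comparisons use Welch's unequal-variance t-test uniformly (the pooled
variant is nowhere used); direction ties (zero mean difference) are
excluded from the χ² tally.

## Back-splice junction detection

The detector is annotation-guided and exact-match: for every gene it
enumerates all head-to-tail junctions (exon-j end joined to exon-i start,
i ≤ j) and all canonical consecutive-exon junctions, builds each junction's
spanning sequence at every offset leaving ≥ `anchor_len` (default 20) nt on
both sides with each arm inside its exon, and assigns reads by exact
sequence lookup. Reads matching more than one junction are dropped and
counted as ambiguous; reads shorter than twice the anchor are skipped with
a warning. This is deliberately a simplified detector for error-free
synthetic reads — it does no mismatch tolerance, no de-novo boundary
discovery, and no repeat-aware filtering — and its central correctness
oracle is the read-simulation round-trip.

"Corresponding linear reads" for a circRNA are reads spanning a canonical
junction at either circRNA boundary (preceding exon → first circ exon, or
last circ exon → following exon); the counts at the available boundary
junctions are averaged and floored. Canonical junctions may be shared by
several circRNAs of one gene, in which case junction reads are inherently
not attributable to a single circRNA. The read simulator therefore emits
each linear count unit at every available boundary junction, making the
averaging rule exactly invertible; the catalog generator's
`distinct_boundaries` mode additionally plants circRNAs whose boundary
junctions are private, the regime in which the detector recovers the
simulated count matrices exactly (recall = precision = 1), which the tests
and the acceptance script verify. CircRNAs spanning a whole gene have no
boundary junction and are not planted by the generator.

## Tiers and candidate filters

*validated*: ≥ 5 BSJ reads in ≥ 2 samples, counted across both groups (the
phrasing of the source criterion carries no group restriction).
*common*: ≥ 1 BSJ read in at least (group size − 1) samples of either the
control or the DM group — the either-group reading is adopted because the
published common-tier counts are identical across the control, DM, and
combined columns. The experimental candidate filters require read support
≥ 20 in ≥ 2 source studies, plus either a circRNA:mRNA ratio ≥ 10% (the
high-level set) or ≥ 10 YGCY motifs in the flanking windows (the motif
set); the sets may overlap.

## Differential statistics

Log₂ fold changes use an ε = 0.01 RPM pseudocount (configurable) since
zero counts occur; both-zero means are ties with log2fc 0. BH-FDR families:
one per metric for the per-circRNA volcano table, one family of three
(cumulative circ RPM, cumulative linear RPM, cumulative FCR) for the global
comparison, one across pools per metric for MCG pools, one per covariate
for severity correlations. The direction-bias test is a one-df χ²
goodness-of-fit against equal up/down proportions with no continuity
correction. Undefined FCR values (bsj + linear = 0) are NaN, dropped
pairwise; a circRNA's FCR row is omitted when undefined in more than half
of the samples. Cumulative FCR is Σcirc/(Σcirc + Σlinear) by default, with
a mean-of-defined-member-FCRs mode available, mirroring the two summaries
in circulation.

## Motif scanning

YGCY (Y ∈ {C,T}) occurrences are counted with overlaps (sliding window);
this choice changes totals versus non-overlapping counting and is therefore
fixed and documented. Windows are the 300 nt (default) of flanking intron
abutting the circRNA's terminal exons, truncated to the intron length;
terminal exons without a flanking intron contribute an empty window. A
motif must lie entirely inside the window — edge-straddling matches are
excluded so counts are window-local and reproducible. Counting is
strand-naive on the given sequence.

## Synthetic data generator

The generator emulates the study conditions end to end on one synthetic
chromosome: multi-exon genes (default 4–8 exons of 120–300 nt, introns
200–800 nt, uniform base composition), exon-boundary circRNAs with planted
top-MCGs, and negative-binomial junction counts,
`BSJ_is ~ NB(mean = lib_s/10⁶ · a_i · fold_i^[s∈DM], dispersion 0.2)`,
with per-circRNA base abundance `a_i` lognormal (median 5 RPM, σ = 1).
Defaults follow the real cohorts where they state a value: group sizes
11 control vs 12 DM, 60-nt error-free reads, droplet wells up to 20,000
droplets. Library sizes default to 0.5–2 million mappable reads — scaled
down from the tens of millions of the real libraries to keep simulations
light; RPM normalization makes downstream results scale-free in
expectation. Linear junction counts use a per-circRNA linear:circ abundance
ratio drawn uniformly from 9–19, putting baseline FCR in the ~5–10% band
reported for common circRNAs, and carry no group effect, so FCR rises in DM
by construction. The default global DM fold of 1.5 is a moderate effect
consistent with the observed global increase and is the condition under
which the power properties are stated. Phenotypes are linear in the
per-sample cumulative circRNA RPM ("burden"): strength with negative slope
and Gaussian noise (a helper computes the noise SD giving a target
population R, e.g. −0.85), PSI around 0.5 on standardized burden, clipped
to [0,1].

What the generator does *not* emulate: sequencing errors, multimapping and
repeat-derived false junctions, PCR duplicates, isoform structure of the
linear transcripts, paired-end reads, batch effects, or count correlation
between circRNAs. Passing tests therefore demonstrate the correctness of
the bookkeeping and the statistical machinery under the assumed generative
model, not detector robustness on real reads — the real-data analogue of
this detector is a maximum-likelihood multi-seed caller, which is out of
scope here.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which the stated properties are stable: power and null
calibration at 200 circRNAs × (12 vs 12) samples over 50 seeds; severity
recovery at n = 21 DM samples over 200 seeds; droplet-estimator recovery at
λ = 0.5, 10,000 droplets, 200 wells; oracle equivalence for BH-FDR, YGCY
counting, Pearson R, and tier classification on 250 random instances each;
the detector round-trip on a ~10-gene genome with 40–80 k-read libraries.

## Known limitations

- The detector requires a single uniform read length per run and exact
  anchor matches; mismatch tolerance is not implemented.
- Tier classification assumes two groups; "common" is undefined for groups
  of fewer than two samples (warned, not an error).
- The χ² direction test is asymptotic; at very small tallies (e.g. 5↑/1↓)
  its p-value is approximate, matching the convention of the summaries it
  reproduces.
- Housekeeping normalization divides by one gene's counts at a time;
  a multi-gene composite reference is not provided.
- `critical_r(21) ≈ 0.433` by t-inversion; the corresponding published
  threshold is printed as 0.434, a third-decimal discrepancy whose exact n
  or rounding provenance is unknown. Similarly, one published panel χ²
  p-value (0.17) is not reproducible from its printed up/down arrows
  (13↑/7↓ gives 0.18); both are recorded here and excluded from automated
  comparison.
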