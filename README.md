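# circdm

Quantification and group comparison of circular RNAs (circRNAs) in myotonic
dystrophy (DM) muscle transcriptomes.

In DM1, expanded CUG repeats sequester the MBNL splicing factors, which have
also been proposed as circRNA biogenesis factors. Testing whether circRNA
levels change in DM therefore needs careful normalization: circRNA abundance
must be separated from the expression of the host gene. This package
implements the two complementary quantification routes used for that
question, the surrounding differential and correlation statistics, and a
synthetic-data generator that reproduces the statistical structure of the
real study designs, so the whole pipeline is testable without any external
download.

## What it computes

**ddPCR route.** A droplet digital PCR well partitions the reaction into up
to ~20,000 droplets; with `p` the fraction of positive droplets, the mean
template copies per droplet is the Poisson estimate `λ = −ln(1 − p)`.
Dilution-corrected circular (C) and linear (L) template quantities give the
fraction of circular particles

    FCP = C / (C + L)        (standard)
    FCP = C / L              (ratio mode, single-exon CDR1as-style assays)

with two QC rules: a sample is excluded for a circRNA when its linear assay
has < 10 positive droplets, and the circRNA is dropped when more than half
of the samples are excluded. Per-circRNA groups are compared with Welch
t-tests, and the up/down tally across a panel is tested against equal
proportions with a one-df χ² goodness-of-fit test.

**RNA-Seq route.** An annotation-guided detector counts back-splice
junction (BSJ) reads — reads whose two anchors map head-to-tail across
annotated exon boundaries of one gene — and corresponding linear junction
reads. Levels are normalized as RPM (reads per million mappable reads), FCR
= bsj/(bsj + linear) (the sequencing analogue of FCP), or against a
housekeeping gene. Detected circRNAs are tiered ("all" / "validated": ≥5
reads in ≥2 samples / "common": present in all or all-but-one sample of
either group), compared between groups (log₂ fold change, Welch t,
Benjamini–Hochberg FDR), pooled per multi-circRNA gene (MCG: >1 circRNA;
top-MCG: >10), scanned for MBNL-binding YGCY motifs in 300-nt
flanking-intron windows, and correlated (Pearson R with t-transform p)
with severity covariates: muscle strength and the percent-spliced-in (PSI)
of DM-responsive exons.

## Worked example

```python
from circdm import synthetic as syn
from circdm.diffexp import global_level_compare
from circdm.quantify import classify_tiers
from circdm.synthetic import SimDesign

genes, genome = syn.make_annotation(n_genes=50, seed=0)
catalog, gene_map = syn.make_catalog(genes, n_top_mcg=2, seed=1)
design = SimDesign(n_control=11, n_dm=12, global_fold=1.5, seed=2)
counts, meta, truth = syn.simulate_counts(catalog, design)

tiers = classify_tiers(counts, meta)
common = list(tiers.index[tiers["common"]])
print(f"{len(catalog)} circRNAs simulated, {len(common)} in the 'common' tier")
print(global_level_compare(counts, meta, circ_subset=common).round(4).to_string(index=False))
```

prints

```
127 circRNAs simulated, 115 in the 'common' tier
  quantity  mean_control    mean_dm  log2fc       t      p  fdr_p
  circ_RPM     1037.5182  1816.0309  0.8076 20.4176 0.0000 0.0000
linear_RPM    13813.5347 13694.1945 -0.0125 -0.4247 0.6764 0.6764
       FCR        0.0700     0.1171  0.6680 18.3248 0.0000 0.0000
```

The simulated DM group carries a 1.5× multiplicative effect on circRNA
abundance only: the cumulative circRNA RPM and the cumulative FCR rise
significantly, while the cumulative linear RPM — which carries no group
effect by construction — does not. Control-group FCR sits at ~7%, i.e.
circRNAs at a few percent of their linear counterparts.

The same stages are available from the shell:

```sh
circdm run-all --seed 7 --outdir out/
circdm ddpcr --droplets wells.tsv --meta meta.tsv --outdir out/
```

`run-all` writes per-stage TSVs plus `manifest.json`; identical config and
seed give byte-identical outputs.

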