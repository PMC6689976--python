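import numpy as np
import pytest

from circdm import synthetic as syn
from circdm.mcg import find_mcgs
from circdm.synthetic import SimDesign


class TestMakeAnnotation:
    def test_deterministic_per_seed(self):
        g1, f1 = syn.make_annotation(n_genes=5, seed=42)
        g2, f2 = syn.make_annotation(n_genes=5, seed=42)
        assert f1 == f2
        assert [g.exons for g in g1] == [g.exons for g in g2]

    def test_exon_and_intron_counts(self):
        genes, genome = syn.make_annotation(
            n_genes=5, exons_per_gene_range=(4, 4), seed=0
        )
        assert len(genes) == 5
        assert all(len(g.exons) == 4 and len(g.introns) == 3 for g in genes)
        assert all(len(genome[g.chrom]) >= g.span.end for g in genes)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            syn.make_annotation(n_genes=1, exon_len_range=(0, 10), seed=0)


class TestMakeCatalog:
    def test_planted_top_mcgs_recovered(self):
        genes, _ = syn.make_annotation(n_genes=10, exons_per_gene_range=(6, 8), seed=5)
        catalog, gene_map = syn.make_catalog(genes, n_top_mcg=2, seed=6)
        _, top = find_mcgs(gene_map)
        assert len(top) == 2

    def test_single_circ_per_gene_gives_no_mcgs(self):
        genes, _ = syn.make_annotation(n_genes=6, seed=5)
        _, gene_map = syn.make_catalog(genes, circ_per_gene_range=(1, 1), seed=6)
        mcgs, top = find_mcgs(gene_map)
        assert mcgs == [] and top == []

    def test_boundaries_on_exon_boundaries(self, small_annotation, small_catalog):
        genes, _ = small_annotation
        catalog, _ = small_catalog
        by_id = {g.gene_id: g for g in genes}
        for rec in catalog.records:
            gene = by_id[rec.gene_id]
            assert rec.interval.start in {e.start for e in gene.exons}
            assert rec.interval.end in {e.end for e in gene.exons}

    def test_too_small_gene_for_top_mcg(self):
        genes, _ = syn.make_annotation(n_genes=2, exons_per_gene_range=(2, 2), seed=1)
        with pytest.raises(ValueError, match="gene"):
            syn.make_catalog(genes, n_top_mcg=1, seed=2)

    def test_seed_reproducibility(self, small_annotation):
        genes, _ = small_annotation
        c1, m1 = syn.make_catalog(genes, seed=3)
        c2, m2 = syn.make_catalog(genes, seed=3)
        assert m1 == m2
        assert [r.interval for r in c1.records] == [r.interval for r in c2.records]


class TestSimulateCounts:
    def test_null_design_has_no_group_effect(self, small_catalog):
        catalog, _ = small_catalog
        from scipy import stats

        pvals = []
        for seed in range(100):
            design = SimDesign(
                n_control=5, n_dm=5, global_fold=1.0, de_fraction=0.0, seed=seed
            )
            counts, meta, _ = syn.simulate_counts(catalog, design)
            ctrl = [m.sample_id for m in meta if m.group == "control"]
            dm = [m.sample_id for m in meta if m.group == "DM"]
            burden_c = (counts.bsj[ctrl].sum() / counts.mappable_reads()[ctrl]).to_numpy()
            burden_d = (counts.bsj[dm].sum() / counts.mappable_reads()[dm]).to_numpy()
            pvals.append(stats.ttest_ind(burden_c, burden_d, equal_var=False).pvalue)
        # p-values roughly uniform under the null
        assert 0.01 < np.mean(np.array(pvals) < 0.25) < 0.45

    def test_twofold_effect_recovered_in_pooled_means(self):
        genes, _ = syn.make_annotation(n_genes=100, seed=7)
        catalog, _ = syn.make_catalog(genes, seed=8)
        assert len(catalog) >= 150
        design = SimDesign(n_control=10, n_dm=10, global_fold=2.0, de_fraction=0.0, seed=9)
        counts, meta, _ = syn.simulate_counts(catalog, design)
        ctrl = [m.sample_id for m in meta if m.group == "control"]
        dm = [m.sample_id for m in meta if m.group == "DM"]
        rpm = counts.bsj * 1e6 / counts.mappable_reads()
        ratio = rpm[dm].mean(axis=1).sum() / rpm[ctrl].mean(axis=1).sum()
        assert 1.8 <= ratio <= 2.2
        lin_rpm = counts.linear * 1e6 / counts.mappable_reads()
        lin_ratio = lin_rpm[dm].mean(axis=1).sum() / lin_rpm[ctrl].mean(axis=1).sum()
        assert 0.9 <= lin_ratio <= 1.1


class TestSimulateDroplets:
    def test_zero_lambda_gives_zero_positives(self):
        run = syn.simulate_droplets(0.0, 1000, seed=1)
        assert run.positives == 0

    def test_positive_fraction_near_poisson_expectation(self):
        run = syn.simulate_droplets(0.5, 20_000, seed=2)
        frac = run.positives / run.total
        assert abs(frac - (1 - np.exp(-0.5))) < 0.02

    def test_seed_determinism_and_negative_lambda(self):
        assert syn.simulate_droplets(0.3, 5000, seed=3).positives == syn.simulate_droplets(
            0.3, 5000, seed=3
        ).positives
        with pytest.raises(ValueError):
            syn.simulate_droplets(-0.1, 100, seed=0)


class TestSimulateReads:
    def test_zero_counts_give_no_reads(self, small_annotation, small_catalog):
        genes, genome = small_annotation
        catalog, _ = small_catalog
        design = SimDesign(n_control=1, n_dm=1, seed=1)
        counts, meta, _ = syn.simulate_counts(catalog, design)
        counts.bsj.iloc[:, :] = 0
        counts.linear.iloc[:, :] = 0
        reads, truth = syn.simulate_reads(catalog, counts, genes, genome)
        assert sum(len(v) for v in reads.values()) == 0 and truth.empty

    def test_single_bsj_read_spans_head_to_tail_junction(self, small_annotation, small_catalog):
        genes, genome = small_annotation
        catalog, _ = small_catalog
        design = SimDesign(n_control=1, n_dm=1, seed=1)
        counts, meta, _ = syn.simulate_counts(catalog, design)
        counts.bsj.iloc[:, :] = 0
        counts.linear.iloc[:, :] = 0
        rec = catalog.records[0]
        sid = counts.sample_ids[0]
        counts.bsj.loc[rec.circ_id, sid] = 1
        reads, truth = syn.simulate_reads(catalog, counts, genes, genome, read_len=60)
        (read,) = reads[sid]
        seq = genome[rec.interval.chrom]
        assert read[1][:30] == seq[rec.interval.end - 30 : rec.interval.end]
        assert read[1][30:] == seq[rec.interval.start : rec.interval.start + 30]


class TestSimulatePhenotypes:
    def test_noiseless_negative_slope_gives_perfect_anticorrelation(self, small_dataset):
        counts, meta, _ = small_dataset
        out = syn.simulate_phenotypes(counts, meta, strength_slope=-2.0, noise_sd=0.0, seed=4)
        burden = syn.circ_burden(counts)
        strength = np.array([m.strength for m in out])
        r = np.corrcoef(burden[[m.sample_id for m in out]], strength)[0, 1]
        assert r == pytest.approx(-1.0)

    def test_zero_slope_null_calibration(self, small_dataset):
        counts, meta, _ = small_dataset
        from circdm.severity import pearson_r

        sig = 0
        n_seeds = 60
        for seed in range(n_seeds):
            out = syn.simulate_phenotypes(
                counts, meta, strength_slope=0.0, noise_sd=1.0, seed=seed
            )
            burden = syn.circ_burden(counts)
            strength = [m.strength for m in out]
            r, p, n = pearson_r(burden[[m.sample_id for m in out]], strength)
            sig += p < 0.05
        assert sig / n_seeds < 0.15

    def test_target_r_noise_calibration(self):
        assert syn.noise_for_target_r(2.0, -1.0, -1.0) == pytest.approx(0.0)
        # R^2 = s^2 v / (s^2 v + n^2) with v = burden variance
        noise = syn.noise_for_target_r(2.0, -1.0, -0.85)
        r2 = 4.0 / (4.0 + noise**2)
        assert np.sqrt(r2) == pytest.approx(0.85)
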