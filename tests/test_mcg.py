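import numpy as np
import pytest

from circdm import synthetic as syn
from circdm.mcg import (
    build_pools,
    diff_pools,
    export_gene_map,
    find_mcgs,
    mcg_summary,
    pool_levels,
)
from circdm.data_model import parse_locus
from circdm.synthetic import SimDesign


class TestFindMcgs:
    @pytest.mark.parametrize(
        "n_circ,is_mcg,is_top",
        [(1, False, False), (2, True, False), (10, True, False), (11, True, True)],
    )
    def test_strict_thresholds(self, n_circ, is_mcg, is_top):
        gene_map = {f"c{i}": "gA" for i in range(n_circ)}
        mcgs, top = find_mcgs(gene_map)
        assert (("gA" in mcgs) is is_mcg) and (("gA" in top) is is_top)

    def test_na_genes_excluded_from_gene_lists(self):
        gene_map = {f"c{i}": "n/a" for i in range(12)}
        mcgs, top = find_mcgs(gene_map)
        assert mcgs == [] and top == []


class TestMcgSummary:
    def test_single_stratum(self):
        gene_map = {f"c{i}": f"g{i}" for i in range(10)}
        out = mcg_summary(gene_map)
        assert len(out) == 1
        assert out.loc[0, "gene_fraction"] == 1.0 and out.loc[0, "circ_fraction"] == 1.0

    def test_top_stratum_fractions(self):
        gene_map = {f"a{i}": f"g{i}" for i in range(9)}
        gene_map.update({f"b{i}": "gBig" for i in range(11)})
        out = mcg_summary(gene_map).set_index("n_circ")
        assert out.loc[11, "gene_fraction"] == pytest.approx(0.10)
        assert out.loc[11, "circ_fraction"] == pytest.approx(0.55)

    def test_conservation_over_strata(self, small_catalog):
        _, gene_map = small_catalog
        out = mcg_summary(gene_map)
        assert out["gene_fraction"].sum() == pytest.approx(1.0)
        assert out["circ_fraction"].sum() == pytest.approx(1.0)
        total_circ = sum(1 for g in gene_map.values() if g != "n/a")
        assert int((out["n_circ"] * out["n_genes"]).sum()) == total_circ


class TestPoolLevels:
    def test_pooled_rpm_is_sum_of_members(self, small_dataset, small_catalog):
        counts, meta, _ = small_dataset
        catalog, gene_map = small_catalog
        gid = catalog.records[0].gene_id
        members = [c for c, g in gene_map.items() if g == gid]
        pool = pool_levels(counts, gid, members)
        from circdm.quantify import compute_rpm

        expected = compute_rpm(counts.bsj.loc[members], counts.mappable_reads()).sum(axis=0)
        assert np.allclose(pool.pooled_rpm, expected)

    def test_single_member_pool_identity(self, small_dataset, small_catalog):
        counts, _, _ = small_dataset
        catalog, _ = small_catalog
        cid = catalog.records[0].circ_id
        pool = pool_levels(counts, "g", [cid])
        from circdm.quantify import compute_fcr, compute_rpm

        assert np.allclose(
            pool.pooled_rpm, compute_rpm(counts.bsj.loc[[cid]], counts.mappable_reads()).iloc[0]
        )

    def test_pooled_fcr_bounded_by_member_fcrs(self, small_dataset, small_catalog):
        counts, _, _ = small_dataset
        catalog, gene_map = small_catalog
        from circdm.quantify import compute_fcr

        for gid in set(gene_map.values()):
            members = [c for c, g in gene_map.items() if g == gid]
            if len(members) < 2:
                continue
            pool = pool_levels(counts, gid, members)
            member_fcr = compute_fcr(counts.bsj.loc[members], counts.linear.loc[members])
            lo, hi = member_fcr.min(axis=0), member_fcr.max(axis=0)
            ok = pool.pooled_fcr.between(lo - 1e-12, hi + 1e-12) | pool.pooled_fcr.isna()
            assert ok.all()

    def test_additivity_of_disjoint_subpools(self, small_dataset, small_catalog):
        counts, _, _ = small_dataset
        catalog, gene_map = small_catalog
        gid = max(set(gene_map.values()), key=lambda g: sum(v == g for v in gene_map.values()))
        members = [c for c, g in gene_map.items() if g == gid]
        a, b = members[: len(members) // 2], members[len(members) // 2 :]
        whole = pool_levels(counts, gid, members)
        assert np.allclose(
            whole.pooled_rpm,
            pool_levels(counts, gid, a).pooled_rpm + pool_levels(counts, gid, b).pooled_rpm,
        )

    def test_empty_pool_rejected(self, small_dataset):
        counts, _, _ = small_dataset
        with pytest.raises(ValueError):
            pool_levels(counts, "g", [])


class TestDiffPools:
    def test_pooling_gains_power_over_members(self):
        # all members of the top gene share a modest 1.5x fold; the pooled
        # test should flag the gene even in seeds where no individual member
        # survives FDR adjustment
        from circdm.diffexp import diff_table

        genes, _ = syn.make_annotation(n_genes=40, exons_per_gene_range=(6, 8), seed=51)
        catalog, gene_map = syn.make_catalog(genes, n_top_mcg=1, seed=52)
        _, top = find_mcgs(gene_map)
        members = [c for c, g in gene_map.items() if g == top[0]]
        pool_hits = member_miss_seeds = 0
        n_seeds = 5
        for seed in range(n_seeds):
            counts, meta, _ = syn.simulate_counts(
                catalog,
                SimDesign(n_control=10, n_dm=10, global_fold=1.5, de_fraction=0.0,
                          seed=100 + seed),
            )
            pools = build_pools(counts, gene_map, top)
            out = diff_pools(pools, meta)
            pool_p = out.loc[out["metric"] == "pooled_RPM", "p"].iloc[0]
            pool_hits += pool_p < 0.05
            table = diff_table(counts, meta, metrics=("RPM",)).set_index("circ_id")
            mem = table.loc[[m for m in members if m in table.index]]
            member_miss_seeds += int((mem["fdr_p"] >= 0.05).all())
        assert pool_hits >= 4
        assert member_miss_seeds >= 2  # pooling detects what per-member FDR misses

    def test_identical_groups_give_p_one(self, small_catalog):
        catalog, gene_map = small_catalog
        counts, meta, _ = syn.simulate_counts(
            catalog, SimDesign(n_control=4, n_dm=4, seed=54)
        )
        ctrl = [m.sample_id for m in meta if m.group == "control"]
        dm = [m.sample_id for m in meta if m.group == "DM"]
        counts.bsj[dm] = counts.bsj[ctrl].to_numpy()
        counts.linear[dm] = counts.linear[ctrl].to_numpy()
        for m in meta:
            m.mappable_reads = 1_000_000
        mcgs, _ = find_mcgs(gene_map)
        out = diff_pools(build_pools(counts, gene_map, mcgs), meta)
        assert (out["p"] == 1.0).all()

    def test_shared_fold_pool_lfc_equals_member_lfc(self):
        # deterministic construction: every member scaled by exactly 2 in DM
        from conftest import make_counts

        counts, meta = make_counts(
            [[10, 10, 20, 20], [30, 30, 60, 60]],
            ["a", "b", "c", "d"],
            linear_rows=[[50, 50, 50, 50], [70, 70, 70, 70]],
            groups=["control", "control", "DM", "DM"],
        )
        pool = pool_levels(counts, "g", ["c0", "c1"])
        out = diff_pools([pool], meta, epsilon=1e-12)
        lfc = out.loc[out["metric"] == "pooled_RPM", "log2fc"].iloc[0]
        assert lfc == pytest.approx(1.0)


class TestExportGeneMap:
    def test_bed_lines_roundtrip_and_containment(self, tmp_path, small_catalog, small_annotation):
        catalog, gene_map = small_catalog
        genes, _ = small_annotation
        gid = catalog.records[0].gene_id
        members = [c for c, g in gene_map.items() if g == gid]
        path = tmp_path / "map.bed"
        n = export_gene_map(catalog, [gid], path)
        lines = path.read_text().strip().split("\n")
        assert n == len(members) == len(lines)
        gene = next(g for g in genes if g.gene_id == gid)
        for line in lines:
            chrom, start, end, name = line.split("\t")[:4]
            iv = parse_locus(f"{chrom}:{start}|{end}")
            assert gene.span.contains(iv)
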