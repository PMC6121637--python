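"""Feature index, metagene profiles, grouping procedures and TE density."""

import numpy as np
import pandas as pd
import pytest

from methlink.features import (
    AnnotationError,
    FeatureIndex,
    GeneModel,
    GroupingError,
    expression_groups,
    group_expression_table,
    metagene_profile,
    methylation_groups,
    positions_in_intervals,
    region_methylation,
    te_density_profile,
)


def toy_index() -> FeatureIndex:
    """10-kb toy annotation: a + gene, a - gene, and one TE inside the
    + gene's body."""
    genes = [
        GeneModel("gplus", "chr1", "+", 3000, 5000, exons=[(3000, 3800), (4200, 5000)]),
        GeneModel("gminus", "chr1", "-", 6500, 7500, exons=[(6500, 7500)]),
    ]
    tes = pd.DataFrame(
        [
            {"chrom": "chr1", "start": 4300, "end": 4600, "te_id": "te1",
             "te_class": "classI", "family": "Copia", "strand": "+"},
            {"chrom": "chr1", "start": 100, "end": 400, "te_id": "te2",
             "te_class": "classII", "family": "Helitron", "strand": "-"},
        ]
    )
    return FeatureIndex(genes=genes, tes=tes, chrom_lengths={"chr1": 10_000})


def brute_force_labels(index: FeatureIndex, pos0: int) -> set[str]:
    """Per-base oracle computed directly from the gene definitions."""
    labels = set()
    for g in index.genes:
        if g.start <= pos0 < g.end:
            labels.add("body")
            in_exon = any(s <= pos0 < e for s, e in g.exons)
            labels.add("exon" if in_exon else "intron")
        plo, phi, _ = g.promoter(10_000)
        if plo <= pos0 < phi:
            labels.update({"promoter", "up2k"})
        dlo, dhi, _ = g.downstream(10_000)
        if dlo <= pos0 < dhi:
            labels.add("down2k")
    for te in index.tes.itertuples():
        if te.start <= pos0 < te.end:
            labels.add("TE")
    return labels or {"intergenic"}


class TestFeatureIndex:
    def test_labels_match_brute_force_everywhere(self):
        index = toy_index()
        for pos0 in range(0, 10_000, 7):  # dense scan of the toy locus
            assert index.labels_at("chr1", pos0) == brute_force_labels(index, pos0), pos0

    def test_minus_strand_promoter_is_numerically_downstream(self):
        index = toy_index()
        # 500 bp 5' of the minus-strand gene's TSS = coordinate 7500 + 500
        assert {"promoter", "up2k"} <= index.labels_at("chr1", 8000)
        # and its down2k flank sits below start
        assert "down2k" in index.labels_at("chr1", 6000)

    def test_exon_position_carries_body(self):
        assert {"exon", "body"} <= toy_index().labels_at("chr1", 3100)

    def test_te_intragenic_status(self):
        index = toy_index()
        flags = index.te_intragenic()
        assert flags.tolist() == [True, False]

    def test_bad_gene_interval_rejected(self):
        with pytest.raises(AnnotationError):
            GeneModel("bad", "chr1", "+", 500, 400)

    def test_positions_in_intervals_oracle(self, rng):
        pos = np.sort(rng.choice(10_000, size=500, replace=False))
        ivs = np.array([[100, 300], [250, 400], [9000, 9500]])
        mask = positions_in_intervals(pos, ivs)
        expected = [any(s <= p < e for s, e in ivs) for p in pos]
        assert mask.tolist() == expected


class TestRegionMethylation:
    def test_uniform_levels_everywhere(self):
        index = toy_index()
        pos = np.arange(1, 10_001, 10)
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "context": "CG", "strand": "+"}
        )
        out = region_methylation(sites, {"s1": np.full(len(pos), 0.5)}, index)
        cg = out[(out["context"] == "CG") & (out["n_sites"] > 0)]
        assert np.allclose(cg["mean_level"], 0.5)

    def test_empty_region_is_missing_not_zero(self):
        index = toy_index()
        sites = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1], "context": ["CG"], "strand": ["+"]}
        )
        out = region_methylation(sites, {"s1": np.array([0.9])}, index)
        body = out[(out["label"] == "body") & (out["context"] == "CG")]
        assert body["n_sites"].iloc[0] == 0
        assert np.isnan(body["mean_level"].iloc[0])


def _uniform_sites(chrom="chr1", lo=1, hi=12_000, step=3, level=0.3):
    pos = np.arange(lo, hi, step)
    sites = pd.DataFrame({"chrom": chrom, "pos": pos, "context": "CG", "strand": "+"})
    return sites, np.full(len(pos), level)


class TestMetageneProfile:
    def test_uniform_level_gives_flat_profile(self):
        gene = GeneModel("g1", "chr1", "+", 4000, 8000, exons=[(4000, 8000)])
        sites, levels = _uniform_sites()
        (profile,) = [
            p for p in metagene_profile(sites, levels, [gene]) if p.context == "CG"
        ]
        assert profile.n_genes == 1
        assert np.allclose(profile.bin_means, 0.3)

    def test_minus_strand_profile_mirrors_plus(self):
        """A minus-strand gene over a mirror-image methylation landscape
        produces the same oriented profile as its plus-strand twin."""
        L = 12_000
        plus = GeneModel("gp", "chr1", "+", 4000, 8000, exons=[(4000, 8000)])
        minus = GeneModel("gm", "chr1", "-", 4000, 8000, exons=[(4000, 8000)])
        pos = np.arange(1, L, 3)
        grad = (pos - 1) / L  # level increases along the chromosome
        sites = pd.DataFrame({"chrom": "chr1", "pos": pos, "context": "CG", "strand": "+"})
        # mirrored landscape: reflect positions through the chromosome midpoint
        pos_m = np.sort(L - pos + 1)
        grad_m = (L - pos_m + 1 - 1) / L
        sites_m = pd.DataFrame({"chrom": "chr1", "pos": pos_m, "context": "CG", "strand": "+"})
        (pp,) = [x for x in metagene_profile(sites, grad, [plus]) if x.context == "CG"]
        (pm,) = [x for x in metagene_profile(sites_m, grad_m, [minus]) if x.context == "CG"]
        assert np.allclose(pp.bin_means, pm.bin_means, atol=1e-3)

    def test_translation_invariance(self):
        gene = GeneModel("g1", "chr1", "+", 4000, 8000, exons=[(4000, 8000)])
        shifted = GeneModel("g1", "chr1", "+", 14_000, 18_000, exons=[(14_000, 18_000)])
        sites, levels = _uniform_sites(hi=12_000)
        rng = np.random.default_rng(0)
        levels = rng.random(len(sites))
        sites2 = sites.assign(pos=sites["pos"] + 10_000)
        (p1,) = [x for x in metagene_profile(sites, levels, [gene]) if x.context == "CG"]
        (p2,) = [x for x in metagene_profile(sites2, levels, [shifted]) if x.context == "CG"]
        assert np.allclose(p1.bin_means, p2.bin_means, equal_nan=True)

    def test_short_gene_fractional_binning(self):
        gene = GeneModel("tiny", "chr1", "+", 3000, 3030, exons=[(3000, 3030)])
        sites, levels = _uniform_sites(step=1, level=0.7)
        (profile,) = [x for x in metagene_profile(sites, levels, [gene]) if x.context == "CG"]
        body = profile.bin_means[50:100]
        assert np.nanmean(body) == pytest.approx(0.7)


class TestExpressionGroups:
    def test_percentile_oracle(self):
        fpkm = pd.Series({"a": 0.5, "b": 2.0, "c": 10.0, "d": 100.0, "e": 30.0})
        groups = expression_groups(fpkm)
        expressed = np.array([2.0, 10.0, 100.0, 30.0])
        q25, q75 = np.percentile(expressed, [25, 75])
        assert groups.fpkm_25 == pytest.approx(q25)
        assert groups.fpkm_75 == pytest.approx(q75)
        assert groups.assignment["a"] == "no"
        assert groups.assignment["b"] == "low"  # 2.0 < q25 = 8
        assert groups.assignment["d"] == "high"

    def test_all_unexpressed(self):
        with pytest.raises(GroupingError):
            expression_groups(pd.Series([0.1, 0.2, 0.9, 0.5]))

    def test_boundary_at_75th_percentile_is_high(self):
        fpkm = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0])
        groups = expression_groups(fpkm)
        boundary_gene = fpkm.index[fpkm == groups.fpkm_75][0]
        assert groups.assignment[boundary_gene] == "high"

    def test_partition(self, rng):
        fpkm = pd.Series(rng.lognormal(1, 2, 500))
        groups = expression_groups(fpkm)
        assert groups.sizes().sum() == 500


class TestMethylationGroups:
    def test_uniform_levels_split_evenly(self, rng):
        levels = pd.Series(rng.random(1000))
        mg = methylation_groups(levels)
        counts = mg.assignment.value_counts()
        assert set(counts.index) == {1, 2, 3, 4, 5}
        assert (counts >= 150).all()

    def test_degenerate_distribution_single_group(self):
        mg = methylation_groups(pd.Series([0.4] * 10))
        assert (mg.assignment == 1).all()

    def test_missing_levels_excluded_and_counted(self):
        levels = pd.Series([0.1, 0.2, np.nan, 0.4, np.nan, 0.6])
        mg = methylation_groups(levels)
        assert mg.n_excluded == 2
        assert len(mg.assignment) == 4

    def test_frequency_table_covers_all_genes(self, rng):
        levels = pd.Series(rng.random(200))
        expr = pd.Series(rng.lognormal(1, 1, 200), index=levels.index)
        mg = methylation_groups(levels)
        table = group_expression_table(mg, expr)
        assert table["n_genes"].sum() == 200


class TestTeDensity:
    def test_no_tes_gives_zero_profile(self):
        genes = [GeneModel("g", "chr1", "+", 5000, 10_000, exons=[(5000, 10_000)])]
        tes = pd.DataFrame(columns=["chrom", "start", "end", "te_id", "te_class", "family", "strand"])
        prof = te_density_profile(tes, genes)
        assert (prof["coverage_fraction"] == 0).all()

    def test_te_covering_one_body_bin_fully(self):
        # body 5000 bp -> body bins are 100 bp; a TE covering exactly bin 10
        genes = [GeneModel("g", "chr1", "+", 5000, 10_000, exons=[(5000, 10_000)])]
        tes = pd.DataFrame(
            [{"chrom": "chr1", "start": 6000, "end": 6100, "te_id": "t",
              "te_class": "classI", "family": "Copia", "strand": "+"}]
        )
        prof = te_density_profile(tes, genes)
        body = prof[prof["region"] == "body"].set_index("bin")
        assert body.loc[60, "coverage_fraction"] == pytest.approx(1.0)
        assert body["coverage_fraction"].sum() == pytest.approx(1.0)

    def test_flank_only_placement(self):
        """TEs restricted to flanks show up in flank bins, not body bins."""
        genes = [GeneModel("g", "chr1", "+", 5000, 10_000, exons=[(5000, 10_000)])]
        tes = pd.DataFrame(
            [{"chrom": "chr1", "start": 3500, "end": 4500, "te_id": "t",
              "te_class": "classI", "family": "LTR", "strand": "+"}]
        )
        prof = te_density_profile(tes, genes)
        up = prof[prof["region"] == "up2k"]["coverage_fraction"].sum()
        body = prof[prof["region"] == "body"]["coverage_fraction"].sum()
        assert up > 0 and body == 0
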