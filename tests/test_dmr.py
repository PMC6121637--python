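"""Beta-binomial differential-methylation calling: smoothing,
dispersion, the per-site Wald test and DMR merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import betaln, gammaln

from methlink.dmr import (
    DmrParams,
    annotate_dmrs,
    call_dmrs,
    dml_scan,
    dml_test,
    estimate_dispersion,
    mom_dispersion,
    smooth_levels,
)
from methlink.features import FeatureIndex, GeneModel


class TestSmoothing:
    def test_isolated_site_keeps_raw_level(self):
        out = smooth_levels(np.array([5000]), np.array([3]), np.array([10]), 500)
        assert out[0] == pytest.approx(0.3)

    def test_symmetric_window_averages_neighbours(self):
        pos = np.array([100, 200, 300])
        meth = np.array([0, 5, 10])
        depth = np.array([10, 10, 10])
        out = smooth_levels(pos, meth, depth, 500)
        assert out[1] == pytest.approx(0.5)

    def test_zero_window_is_identity(self):
        pos = np.array([10, 20, 30])
        meth = np.array([1, 2, 3])
        depth = np.array([4, 4, 4])
        assert np.allclose(smooth_levels(pos, meth, depth, 0), meth / 4)


class TestDispersion:
    def test_two_replicate_closed_form(self):
        """Hand-computed method-of-moments oracle for counts (3/10, 7/10):
        p = 0.5, s2 = 0.08, nbar = 10 -> phi = (0.8 - 0.25) / 2.25."""
        phi = mom_dispersion(np.array([[3.0, 7.0]]), np.array([[10.0, 10.0]]))
        assert phi[0] == pytest.approx((10 * 0.08 - 0.25) / (0.25 * 9))

    def test_identical_replicates_hit_floor(self):
        meth = np.tile([50.0], (5, 3))
        depth = np.tile([100.0], (5, 3))
        phi = estimate_dispersion(meth, depth)
        # zero observed spread: raw estimates are negative, shrinkage floors
        assert (phi <= 0.02).all()

    def test_mom_consistency_on_simulated_beta_binomial(self, rng):
        """Median shrunk estimate over 1000 sites at true phi = 0.05,
        depth 30, 3 replicates lands in [0.03, 0.08]."""
        n, R, phi_true, depth = 1000, 3, 0.05, 30
        conc = (1 - phi_true) / phi_true
        p = rng.beta(0.5 * conc, 0.5 * conc, size=(n, R))
        d = rng.poisson(depth, size=(n, R)).astype(float)
        m = rng.binomial(d.astype(int), p).astype(float)
        est = estimate_dispersion(m, d)
        assert 0.03 <= np.median(est) <= 0.08


class TestDmlTest:
    def test_identical_counts_are_null(self):
        m = np.array([[5.0, 6.0, 7.0]])
        d = np.array([[10.0, 12.0, 14.0]])
        phi = np.array([0.01])
        mu1, mu2, stat, p = dml_test(m, d, m, d, phi, phi)
        assert stat[0] == 0.0 and p[0] == 1.0

    def test_extreme_separation(self):
        d = np.full((1, 3), 50.0)
        phi = np.array([1e-4])
        *_, p = dml_test(d.copy(), d, np.zeros((1, 3)), d, phi, phi)
        assert p[0] < 1e-10

    def test_null_type_i_error_without_smoothing(self, rng):
        """Simulated beta-binomial null (mu equal, phi 0.05, depth 30,
        3 vs 3): empirical type-I error at alpha = 0.05 within [0.03, 0.07]."""
        n, R, phi_true, depth, mu = 10_000, 3, 0.05, 30, 0.3
        conc = (1 - phi_true) / phi_true

        def draw():
            p = rng.beta(mu * conc, (1 - mu) * conc, size=(n, R))
            d = rng.poisson(depth, size=(n, R)).astype(float)
            return rng.binomial(d.astype(int), p).astype(float), d

        m1, d1 = draw()
        m2, d2 = draw()
        phi1 = estimate_dispersion(m1, d1)
        phi2 = estimate_dispersion(m2, d2)
        *_, p = dml_test(m1, d1, m2, d2, phi1, phi2)
        assert 0.03 <= np.nanmean(p < 0.05) <= 0.07

    def test_wald_ranking_matches_likelihood_ratio_oracle(self, rng):
        """On random small sites the Wald statistic orders evidence the
        same way as a brute-force beta-binomial likelihood-ratio oracle
        (Spearman rank correlation >= 0.9)."""

        def bb_loglik(m, d, mu, phi):
            conc = (1 - phi) / phi
            a, b = mu * conc, (1 - mu) * conc
            return sum(
                gammaln(di + 1) - gammaln(mi + 1) - gammaln(di - mi + 1)
                + betaln(mi + a, di - mi + b) - betaln(a, b)
                for mi, di in zip(m, d)
            )

        def lr_stat(m1, d1, m2, d2, phi):
            grid = np.linspace(1e-4, 1 - 1e-4, 200)
            ll = lambda m, d: max(bb_loglik(m, d, g, phi) for g in grid)
            ll_alt = ll(m1, d1) + ll(m2, d2)
            ll_null = max(
                bb_loglik(m1, d1, g, phi) + bb_loglik(m2, d2, g, phi) for g in grid
            )
            return 2 * (ll_alt - ll_null)

        phi_true = 0.05
        conc = (1 - phi_true) / phi_true
        wald, lr = [], []
        for _ in range(20):
            mu1, mu2 = rng.uniform(0.1, 0.9, size=2)
            d1 = rng.poisson(25, 3).astype(float) + 1
            d2 = rng.poisson(25, 3).astype(float) + 1
            m1 = rng.binomial(d1.astype(int), rng.beta(mu1 * conc, (1 - mu1) * conc, 3)).astype(float)
            m2 = rng.binomial(d2.astype(int), rng.beta(mu2 * conc, (1 - mu2) * conc, 3)).astype(float)
            phi_arr = np.array([phi_true])
            *_, stat, _p = dml_test(m1[None], d1[None], m2[None], d2[None], phi_arr, phi_arr)
            wald.append(abs(stat[0]))
            lr.append(lr_stat(m1, d1, m2, d2, phi_true))
        rho = stats.spearmanr(wald, lr).statistic
        assert rho >= 0.9


def _dml_frame(pos, diffs, pvals, context="CG", chrom="chr1", depth=30.0):
    """Minimal DML table for merge-rule tracing; raw counts consistent
    with the given diffs around a 0.3 baseline."""
    mu2 = np.full(len(pos), 0.3)
    mu1 = mu2 + np.asarray(diffs)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": "+",
            "context": context,
            "mu1": mu1,
            "mu2": mu2,
            "diff": np.asarray(diffs),
            "phi1": 0.01,
            "phi2": 0.01,
            "stat": np.sign(diffs) * 8.0,
            "p": pvals,
            "raw_meth1": mu1 * depth * 3,
            "raw_depth1": depth * 3,
            "raw_meth2": mu2 * depth * 3,
            "raw_depth2": depth * 3,
        }
    )


class TestCallDmrs:
    def test_no_significant_sites_no_dmrs(self):
        dml = _dml_frame([100, 150, 200], [0.1, 0.1, 0.1], [0.5, 0.4, 0.3])
        assert len(call_dmrs(dml)) == 0

    def test_five_significant_sites_merge_into_one_hyper_dmr(self):
        """Hand-traced merge: 5 same-sign significant CG sites within
        200 bp, gaps <= 100 -> exactly one hyper DMR spanning them."""
        pos = [1000, 1050, 1090, 1130, 1200]
        dml = _dml_frame(pos, [0.4] * 5, [1e-8] * 5)
        dmrs = call_dmrs(dml)
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert row["direction"] == "hyper"
        assert row["start"] == 999 and row["end"] == 1200
        assert row["n_sites"] == 5

    def test_sign_flip_splits_regions(self):
        pos = [1000, 1060, 1120, 1180, 1240, 1300]
        diffs = [0.4, 0.4, 0.4, -0.4, -0.4, -0.4]
        dml = _dml_frame(pos, diffs, [1e-8] * 6)
        dmrs = call_dmrs(dml)
        assert len(dmrs) == 2
        assert dmrs["direction"].tolist() == ["hyper", "hypo"]

    def test_gap_rule_splits_regions(self):
        pos = [1000, 1050, 1100, 1600, 1650, 1700]
        dml = _dml_frame(pos, [0.4] * 6, [1e-8] * 6)
        dmrs = call_dmrs(dml, DmrParams(max_gap=100))
        assert len(dmrs) == 2

    def test_min_sites_filter(self):
        dml = _dml_frame([1000, 1100], [0.4, 0.4], [1e-8, 1e-8])
        assert len(call_dmrs(dml, DmrParams(min_sites=3))) == 0

    def test_pct_sig_filter(self):
        # 3 significant sites but 7 interleaved non-significant ones
        pos = list(range(1000, 1250, 25))
        pvals = [1e-8 if i in (0, 4, 9) else 0.5 for i in range(10)]
        dml = _dml_frame(pos, [0.4] * 10, pvals)
        assert len(call_dmrs(dml, DmrParams(pct_sig=0.5))) == 0

    def test_empty_input(self):
        dml = _dml_frame([], [], [])
        assert len(call_dmrs(dml)) == 0


@pytest.fixture(scope="module")
def called(small_fixture):
    dml = dml_scan(small_fixture.methylome)
    return dml, call_dmrs(dml)


class TestPipelineOnPlantedFixture:
    def test_direction_conserved_against_raw_counts(self, small_fixture, called):
        """For every called DMR the raw (unsmoothed) WT - RT pooled level
        difference inside the region has the sign of its direction."""
        _, dmrs = called
        sites = small_fixture.methylome.sites
        cfg = small_fixture.config
        assert len(dmrs) > 0
        for row in dmrs.itertuples():
            sel = (
                (sites["chrom"] == row.chrom)
                & (sites["pos"] - 1 >= row.start)
                & (sites["pos"] - 1 < row.end)
                & (sites["context"] == row.context)
            )
            lv = []
            for cond in cfg.conditions:
                meths = sum(sites.loc[sel, f"meth_{s}"].sum() for s in cfg.condition_map[cond])
                tots = meths + sum(
                    sites.loc[sel, f"unmeth_{s}"].sum() for s in cfg.condition_map[cond]
                )
                lv.append(meths / tots)
            diff = lv[0] - lv[1]
            assert np.sign(diff) == (1 if row.direction == "hyper" else -1)

    def test_planted_regions_recovered(self, small_fixture, called):
        """Planted DMRs with a strong realised effect are recovered with
        Jaccard >= 0.5 and the right direction."""
        _, dmrs = called
        truth = small_fixture.truth_dmrs
        strong = truth[truth["realized_effect"].abs() >= 0.3]
        assert len(strong) >= 5
        hits = 0
        for row in strong.itertuples():
            sub = dmrs[(dmrs["chrom"] == row.chrom) & (dmrs["context"] == row.context)]
            for d in sub.itertuples():
                inter = max(0, min(d.end, row.end) - max(d.start, row.start))
                union = max(d.end, row.end) - min(d.start, row.start)
                if inter / union >= 0.5:
                    assert d.direction == row.direction
                    hits += 1
                    break
        assert hits / len(strong) >= 0.8


class TestAnnotateDmrs:
    @pytest.fixture()
    def index(self):
        genes = [GeneModel("g1", "chr1", "+", 5000, 8000, exons=[(5000, 8000)])]
        tes = pd.DataFrame(
            [{"chrom": "chr1", "start": 6000, "end": 6500, "te_id": "te1",
              "te_class": "classI", "family": "Copia", "strand": "+"}]
        )
        return FeatureIndex(genes=genes, tes=tes, chrom_lengths={"chr1": 20_000})

    def _dmr(self, start, end):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": start, "end": end, "context": "CG",
              "direction": "hyper", "n_sites": 5, "n_sites_total": 5,
              "mean_diff": 0.3, "area_stat": 40.0, "mean_mu1": 0.6, "mean_mu2": 0.3}]
        )

    def test_dmr_inside_promoter_only(self, index):
        out = annotate_dmrs(self._dmr(3500, 3900), index)
        assert out["promoter_hits"].iloc[0] == "g1"
        assert out["gene_body_hits"].iloc[0] == ""

    def test_dmr_spanning_tss_hits_both(self, index):
        out = annotate_dmrs(self._dmr(4900, 5100), index)
        assert out["promoter_hits"].iloc[0] == "g1"
        assert out["gene_body_hits"].iloc[0] == "g1"

    def test_te_overlap_recorded(self, index):
        out = annotate_dmrs(self._dmr(6400, 6600), index)
        assert out["te_hits"].iloc[0] == "te1"

    def test_recovered_promoter_dmrs_appear_in_promoter_table(self, small_fixture):
        """Truth-table join: planted promoter DMRs with a strong effect
        that the caller recovers are annotated to their gene's promoter."""
        from methlink.dmr import dmr_gene_table

        dml = dml_scan(small_fixture.methylome)
        dmrs = call_dmrs(dml)
        index = FeatureIndex(
            genes=small_fixture.genes,
            tes=small_fixture.tes,
            chrom_lengths=small_fixture.chrom_lengths,
        )
        table = dmr_gene_table(annotate_dmrs(dmrs, index))
        prom_genes = set(table.loc[table["region"] == "promoter", "gene_id"])
        truth = small_fixture.truth_dmrs
        planted = truth[(truth["placement"] == "promoter") & (truth["realized_effect"].abs() >= 0.3)]
        recovered = 0
        for row in planted.itertuples():
            sub = dmrs[(dmrs["chrom"] == row.chrom) & (dmrs["context"] == row.context)]
            overlap = ((sub["start"] < row.end) & (row.start < sub["end"])).any()
            if overlap:
                recovered += 1
                assert row.gene_id in prom_genes
        assert recovered > 0
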