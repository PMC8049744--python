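import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from regenomics import diffexpr as dx
from regenomics.formats import CountExperiment
from regenomics.synthio import generate_single_cell


def _experiment(counts: np.ndarray, samples=None) -> CountExperiment:
    samples = samples or [f"s{j}" for j in range(counts.shape[1])]
    frame = pd.DataFrame(
        counts, index=[f"g{i}" for i in range(counts.shape[0])], columns=samples
    )
    design = pd.DataFrame(
        {
            "structure": ["H"] * len(samples),
            "timepoint": [0] * len(samples),
            "treatment": ["untreated"] * len(samples),
            "replicate": list(range(1, len(samples) + 1)),
        },
        index=samples,
    )
    return CountExperiment(frame, design)


class TestFilterFeatures:
    def test_rna_defaults_keep_three_of_six(self):
        # gene at CPM (3,3,3,0,0,0) with min_cpm=2, min_samples=3 -> kept
        counts = np.zeros((2, 6), dtype=int)
        counts[0] = [3000, 3000, 3000, 0, 0, 0]       # 3 cpm in 3 samples
        counts[1] = [997_000, 997_000, 997_000, 1_000_000, 1_000_000, 1_000_000]
        exp = _experiment(counts)
        kept = dx.filter_features(exp, 2, 3)
        assert "g0" in kept

    def test_all_zero_feature_dropped(self):
        counts = np.array([[0, 0, 0], [10, 10, 10]])
        exp = _experiment(counts)
        assert "g0" not in dx.filter_features(exp, 2, 1)

    def test_boundary_cpm_is_inclusive(self):
        # CPM exactly 10 in exactly 3 samples at (10, 3) -> kept
        lib = 1_000_000
        counts = np.zeros((2, 6), dtype=int)
        counts[0] = [10, 10, 10, 0, 0, 0]
        counts[1] = [lib - 10, lib - 10, lib - 10, lib, lib, lib]
        exp = _experiment(counts)
        assert "g0" in dx.filter_features(exp, 10, 3)

    def test_min_samples_exceeding_sample_count_error(self):
        exp = _experiment(np.ones((2, 3), dtype=int))
        with pytest.raises(ValueError):
            dx.filter_features(exp, 1, 4)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([100, 50, 20, 500, 5, 80])
        exp = _experiment(np.column_stack([col, col, col]))
        factors = dx.tmm_factors(exp)
        np.testing.assert_allclose(factors, 1.0, atol=1e-12)

    def test_scaled_column_gives_unit_factors(self):
        col = np.array([100, 50, 20, 500, 5, 80])
        exp = _experiment(np.column_stack([col, 5 * col]))
        factors = dx.tmm_factors(exp)
        np.testing.assert_allclose(factors, 1.0, atol=1e-9)

    def test_geometric_mean_is_one(self, experiment):
        factors = dx.tmm_factors(experiment[0])
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-9)

    def test_toy_matches_hand_computed_trimmed_weighted_mean(self):
        """Independent spreadsheet-style recomputation on 6 features."""
        y = np.array([100, 200, 300, 400, 500, 600])
        r = np.array([120, 180, 310, 350, 560, 540])
        exp = _experiment(np.column_stack([y, r]), samples=["a", "ref"])
        n, nr = y.sum(), r.sum()
        m = np.log2((y / n) / (r / nr))
        a = 0.5 * np.log2((y / n) * (r / nr))
        w = 1.0 / ((n - y) / (n * y) + (nr - r) / (nr * r))
        # trim: keep M-ranks 2..5 of 6 (30% per tail), all A-ranks (5% per tail)
        rm = stats.rankdata(m)
        keep = (rm >= 2) & (rm <= 5)
        expected_log = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
        factors = dx.tmm_factors(exp, reference="ref")
        # un-center to compare the raw pair factor
        raw = factors["a"] / factors["ref"]
        assert math.log2(raw) == pytest.approx(expected_log, abs=1e-9)

    def test_all_zero_sample_error(self):
        counts = np.array([[0, 5], [0, 10]])
        with pytest.raises(ValueError):
            dx.tmm_factors(_experiment(counts))


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            dx.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert dx.bh_adjust([0.37])[0] == 0.37

    def test_monotone_on_sorted_input(self):
        p = np.sort(np.random.default_rng(1).uniform(size=100))
        adj = dx.bh_adjust(p)
        assert (np.diff(adj) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            dx.bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_order_invariance(self, p):
        p = np.array(p)
        rng = np.random.default_rng(0)
        perm = rng.permutation(p.size)
        adj = dx.bh_adjust(p)
        adj_perm = dx.bh_adjust(p[perm])
        np.testing.assert_allclose(adj[perm], adj_perm)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0001, 1), min_size=1, max_size=50))
    def test_fdr_ge_p(self, p):
        assert (dx.bh_adjust(p) >= np.array(p) - 1e-15).all()


def _two_group_experiment(mu_a, mu_b, n=3, phi=0.0, seed=0, n_features=1):
    rng = np.random.default_rng(seed)
    mus = np.array([[mu_a] * n + [mu_b] * n] * n_features, dtype=float)
    if phi > 0:
        lam = rng.gamma(1 / phi, mus * phi)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mus)
    samples = [f"s{j}" for j in range(2 * n)]
    frame = pd.DataFrame(
        counts, index=[f"g{i}" for i in range(n_features)], columns=samples
    )
    design = pd.DataFrame(
        {
            "structure": ["H"] * (2 * n),
            "timepoint": [0] * n + [3] * n,
            "treatment": ["untreated"] * (2 * n),
            "replicate": list(range(1, n + 1)) * 2,
        },
        index=samples,
    )
    return CountExperiment(frame, design)


class TestNbQlFit:
    def test_large_count_limit_recovers_mean_ratio(self):
        # near-Poisson, large counts: log2FC -> log2 of normalized mean ratio
        exp = _two_group_experiment(40_000, 10_000, n=4, seed=1, n_features=60)
        norm = dx.normalize(exp)
        fit = dx.fit_nb_ql(norm)
        c = dx.injury_contrast(fit.levels, "H", 3)
        res = dx.ql_test(fit, c)
        counts = exp.counts.to_numpy(dtype=float)
        eff = norm.effective_lib_size.to_numpy()
        cpm = counts / eff * 1e6
        expected = np.log2(cpm[:, 4:].mean(axis=1) / cpm[:, :4].mean(axis=1))
        np.testing.assert_allclose(res["log2FC"], expected, atol=0.02)

    def test_identical_group_means_give_zero_coefficient(self):
        exp = _two_group_experiment(5000, 5000, n=4, seed=2, n_features=100)
        fit = dx.fit_nb_ql(dx.normalize(exp))
        res = dx.ql_test(fit, dx.injury_contrast(fit.levels, "H", 3))
        assert abs(res["log2FC"].mean()) < 0.02

    def test_rank_deficient_design_rejected(self, experiment):
        norm = dx.normalize(experiment[0])
        X, levels = dx.cell_means_design(experiment[0].design)
        X2 = np.column_stack([X, X[:, 0]])
        with pytest.raises(ValueError, match="rank"):
            dx.fit_nb_ql(norm, X2, levels + ["dup"])

    def test_zero_contrast_rejected(self, experiment):
        norm = dx.normalize(experiment[0].subset_features(experiment[0].features[:50]))
        fit = dx.fit_nb_ql(norm)
        with pytest.raises(ValueError, match="zero"):
            dx.ql_test(fit, np.zeros(len(fit.levels)))

    def test_deterministic(self, null_experiment):
        exp = null_experiment[0].subset_features(null_experiment[0].features[:100])
        fit = dx.fit_nb_ql(dx.normalize(exp))
        c = dx.injury_contrast(fit.levels, "H", 3)
        r1 = dx.ql_test(fit, c)
        r2 = dx.ql_test(fit, c)
        pd.testing.assert_frame_equal(r1, r2)


@pytest.fixture(scope="module")
def null_fit(null_experiment):
    rna = null_experiment[0]
    kept = dx.filter_features(rna, 2, 3)
    return dx.fit_nb_ql(dx.normalize(rna.subset_features(kept)))


class TestNullCalibration:
    def test_pvalues_uniform(self, null_fit):
        res = dx.ql_test(null_fit, dx.injury_contrast(null_fit.levels, "H", 3))
        ks = stats.kstest(res["p"], "uniform").statistic
        assert ks < 0.05  # 800 features; the 2,000-feature bound is in acceptance

    def test_type_i_error_within_two_se(self, null_fit):
        res = dx.ql_test(null_fit, dx.injury_contrast(null_fit.levels, "F", 8))
        n = len(res)
        for alpha in (0.05, 0.01):
            se = math.sqrt(alpha * (1 - alpha) / n)
            assert abs((res["p"] < alpha).mean() - alpha) < 3 * se

    def test_no_context_calls_under_null(self, null_fit):
        ctx = dx.context_effect(null_fit, 8)
        assert (ctx["call"] != "ns").sum() <= 2


class TestContextEffect:
    def test_delta_equals_difference_of_log2fcs(self, experiment):
        rna = experiment[0]
        fit = dx.fit_nb_ql(dx.normalize(rna))
        ctx = dx.context_effect(fit, 8)
        np.testing.assert_allclose(
            ctx["delta"], ctx["log2fc_head"] - ctx["log2fc_foot"], atol=1e-9
        )

    def test_divergence_timing(self, experiment):
        rna, _, truth, _ = experiment
        fit = dx.fit_nb_ql(dx.normalize(rna))
        n_sig = {
            t: (dx.context_effect(fit, t)["call"] != "ns").sum() for t in (3, 8, 12)
        }
        assert n_sig[3] == 0
        assert n_sig[8] > 0 and n_sig[12] > 0

    def test_calls_match_planted_sets(self, experiment):
        rna, _, truth, _ = experiment
        fit = dx.fit_nb_ql(dx.normalize(rna))
        ctx = dx.context_effect(fit, 8)
        head_calls = set(ctx.index[ctx["call"] == "head"])
        foot_calls = set(ctx.index[ctx["call"] == "foot"])
        assert head_calls <= set(truth.head_genes)
        assert foot_calls <= set(truth.foot_genes)

    def test_missing_cell_error(self, experiment):
        fit = dx.fit_nb_ql(dx.normalize(experiment[0]))
        with pytest.raises(ValueError, match="missing"):
            dx.context_effect(fit, 99)


def _result_frame(features, log2fc, fdr):
    return pd.DataFrame(
        {"log2FC": log2fc, "fdr": fdr, "p": fdr, "F": 1.0, "contrast": "x"},
        index=pd.Index(features, name="feature"),
    )


class TestClassifyTcf:
    def test_dependent(self):
        # up in untreated, not up under inhibitor, significant reduction
        unt = _result_frame(["g1"], [2.0], [1e-5])
        icrt = _result_frame(["g1"], [0.1], [0.5])
        cross = _result_frame(["g1"], [-1.9], [1e-5])
        assert dx.classify_tcf(unt, icrt, cross)["g1"] == "TCF-dependent"

    def test_inhibited(self):
        unt = _result_frame(["g1"], [1.0], [1e-5])
        icrt = _result_frame(["g1"], [3.0], [1e-5])
        cross = _result_frame(["g1"], [2.0], [1e-5])
        assert dx.classify_tcf(unt, icrt, cross)["g1"] == "TCF-inhibited"

    def test_unclassified_when_nothing_significant(self):
        unt = _result_frame(["g1"], [0.2], [0.9])
        icrt = _result_frame(["g1"], [0.2], [0.9])
        cross = _result_frame(["g1"], [0.0], [0.9])
        assert dx.classify_tcf(unt, icrt, cross)["g1"] == "unclassified"

    def test_feature_mismatch_error(self):
        unt = _result_frame(["g1"], [1.0], [0.5])
        other = _result_frame(["g2"], [1.0], [0.5])
        with pytest.raises(ValueError, match="differ"):
            dx.classify_tcf(unt, other, unt)


class TestStructuralEnrichment:
    def test_exact_p_matches_enumeration_123_vs_456(self):
        """All C(6,3)=20 label assignments: only 2 orderings are as extreme."""
        x, y = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        pooled = np.concatenate([x, y])
        observed = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        count = 0
        for combo in itertools.combinations(range(6), 3):
            xs = pooled[list(combo)]
            ys = pooled[[i for i in range(6) if i not in combo]]
            u = stats.mannwhitneyu(xs, ys, alternative="two-sided").statistic
            if min(u, 9 - u) <= min(observed, 9 - observed):
                count += 1
        expected = count / 20
        assert expected == pytest.approx(0.1)
        counts = pd.DataFrame([pooled], index=["g1"],
                              columns=[f"c{i}" for i in range(6)])
        labels = pd.Series(["head"] * 3 + ["foot"] * 3, index=counts.columns)
        res = dx.structural_enrichment(counts, labels, alpha=0.05)
        assert res.loc["g1", "p"] == pytest.approx(expected)

    def test_identical_clusters_no_calls(self):
        rng = np.random.default_rng(3)
        block = rng.poisson(10, size=(50, 30))
        counts = pd.DataFrame(np.hstack([block, block]),
                              index=[f"g{i}" for i in range(50)],
                              columns=[f"c{i}" for i in range(60)])
        labels = pd.Series(["head"] * 30 + ["foot"] * 30, index=counts.columns)
        res = dx.structural_enrichment(counts, labels)
        np.testing.assert_allclose(res["log2FC"], 0.0, atol=1e-12)
        assert (res["call"] == "ns").all()

    def test_planted_markers_recovered(self):
        markers_h = [f"mh{i}" for i in range(20)]
        markers_f = [f"mf{i}" for i in range(20)]
        counts, labels = generate_single_cell(300, markers_h, markers_f, 3.0, seed=8)
        res = dx.structural_enrichment(counts, labels)
        rec_h = (res.loc[markers_h, "call"] == "head").mean()
        rec_f = (res.loc[markers_f, "call"] == "foot").mean()
        assert rec_h >= 0.9 and rec_f >= 0.9

    def test_tiny_cluster_error(self):
        counts = pd.DataFrame([[1, 2, 3]], index=["g1"], columns=["a", "b", "c"])
        labels = pd.Series(["head", "foot", "foot"], index=counts.columns)
        with pytest.raises(ValueError, match=">= 2 cells"):
            dx.structural_enrichment(counts, labels)
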