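"""Phylo-spatial GLS: correlation construction, likelihood, model selection."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy import stats

from cyclemur import (
    CorrelationModel,
    SimConfig,
    aicc,
    akaike_table,
    fit_ml,
    gen_tree,
    gls_profile,
    joint_correlation,
    lrt,
    mcc_tree,
    model_table,
    percent_effect,
    phylo_correlation,
    spatial_structure,
)
from cyclemur.errors import DomainError


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def trees_from(newicks):
    tns = dendropy.TaxonNamespace()
    return [
        dendropy.Tree.get(data=s, schema="newick", taxon_namespace=tns)
        for s in newicks
    ]


class TestMccTree:
    def test_identical_sample_scores_zero(self):
        ts = trees_from(["((a:1,b:1):1,(c:1,d:1):1);"] * 5)
        best = mcc_tree(ts)
        assert best is ts[0]

    def test_majority_topology_wins(self):
        t1 = "((a:1,b:1):1,(c:1,d:1):1);"
        t2 = "((a:1,c:1):1,(b:1,d:1):1);"
        ts = trees_from([t1] * 9 + [t2])
        best = mcc_tree(ts)
        assert best in ts[:9]

    def test_winner_matches_clade_count_oracle(self):
        rng = np.random.default_rng(0)
        sample = []
        for k in range(20):
            cfg = SimConfig(n_species=6, seed=int(rng.integers(0, 5)))  # few seeds -> repeats
            sample.append(gen_tree(cfg))
        tns = dendropy.TaxonNamespace()
        sample = trees_from(
            [t.as_string(schema="newick") for t in sample]
        )
        best = mcc_tree(sample)

        # independent oracle via dendropy bipartition encoding
        counts = {}
        keys_per_tree = []
        for t in sample:
            t.encode_bipartitions()
            keys = {
                b.split_bitmask
                for b in t.bipartition_encoding
                if 1 < bin(b.split_bitmask).count("1") < 6
            }
            keys_per_tree.append(keys)
            for k in keys:
                counts[k] = counts.get(k, 0) + 1
        scores = [
            sum(math.log(counts[k] / 20) for k in keys) for keys in keys_per_tree
        ]
        assert sample.index(best) == int(np.argmax(np.round(scores, 12)))

    def test_mismatched_tips_rejected(self):
        ts = trees_from(["((a:1,b:1):1,c:2);", "((a:1,b:1):1,d:2);"])
        with pytest.raises(DomainError):
            mcc_tree(ts)


class TestPhyloCorrelation:
    def test_star_tree_is_identity(self):
        t = newick("(a:1,b:1,c:1,d:1);")
        P, labels = phylo_correlation(t)
        np.testing.assert_allclose(P, np.eye(4), atol=1e-12)

    def test_recent_sisters_share_ninety_percent(self):
        # a and b diverge at 10% of depth from the present
        t = newick("((a:0.1,b:0.1):0.9,c:1.0);")
        P, labels = phylo_correlation(t, ["a", "b", "c"])
        assert P[0, 1] == pytest.approx(0.9)
        assert P[0, 2] == pytest.approx(0.0)

    def test_random_tree_matches_mrca_traversal_oracle(self):
        cfg = SimConfig(n_species=8, seed=21)
        tree = gen_tree(cfg)
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        P, _ = phylo_correlation(tree, labels)
        depth = max(lf.distance_from_root() for lf in tree.leaf_node_iter())
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, j in itertools.combinations(range(8), 2):
            mrca = tree.mrca(taxa=[taxa[labels[i]], taxa[labels[j]]])
            expected = mrca.distance_from_root() / depth
            assert P[i, j] == pytest.approx(expected, abs=1e-9)


class TestSpatialStructure:
    def test_two_points_normalized(self):
        D = spatial_structure(np.array([[0.0, 0.0], [5.0, 0.0]]))
        np.testing.assert_allclose(D, [[0, 1], [1, 0]])

    def test_equilateral_triangle_all_unit(self):
        s = 7.0
        pts = np.array([[0, 0], [s, 0], [s / 2, s * np.sqrt(3) / 2]])
        D = spatial_structure(pts)
        off = D[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 1.0)

    def test_matches_pairwise_loop(self):
        pts = np.random.default_rng(2).uniform(0, 50, (10, 2))
        D = spatial_structure(pts)
        raw = np.array(
            [[np.hypot(*(pts[i] - pts[j])) for j in range(10)] for i in range(10)]
        )
        np.testing.assert_allclose(D, raw / raw.max(), atol=1e-12)


class TestJointCorrelation:
    def test_iid_limit(self):
        P = np.eye(4)
        D = np.random.default_rng(0).uniform(0, 1, (4, 4))
        np.fill_diagonal(D, 0)
        R = joint_correlation(P, D, CorrelationModel(0.0, 0.0, 0.5))
        np.testing.assert_allclose(R, np.eye(4))

    def test_zero_decay_gives_compound_symmetry(self):
        D = np.array([[0, 0.5], [0.5, 0]])
        R = joint_correlation(np.eye(2), D, CorrelationModel(0.0, 0.4, 0.0))
        np.testing.assert_allclose(R, [[1.0, 0.4], [0.4, 1.0]])

    def test_positive_semidefinite_on_random_inputs(self, small_world):
        rng = np.random.default_rng(31)
        for _ in range(10):
            lam, phi = rng.dirichlet([1, 1, 1])[:2]
            model = CorrelationModel(lam, phi, rng.uniform(0, 0.99))
            R = joint_correlation(small_world["P"], small_world["D"], model)
            assert np.linalg.eigvalsh(R).min() >= -1e-10
            np.testing.assert_allclose(np.diag(R), 1.0)

    def test_constraint_violation_rejected(self):
        with pytest.raises(DomainError):
            CorrelationModel(0.7, 0.5, 0.1)


class TestGlsProfile:
    def test_identity_correlation_equals_ols(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = rng.normal(size=12)
        beta, se, s2, ll = gls_profile(y, X, np.eye(12))
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-10)

    def test_loglik_matches_mvn_density_oracle(self, small_world):
        rng = np.random.default_rng(5)
        n = 6
        P = small_world["P"][:n, :n]
        D = small_world["D"][:n, :n]
        R = joint_correlation(P, D, CorrelationModel(0.4, 0.3, 0.2))
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        beta, _, s2, ll = gls_profile(y, X, R)
        oracle = stats.multivariate_normal.logpdf(
            y, mean=X @ beta, cov=s2 * R, allow_singular=True
        )
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_rank_deficiency_raises(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        with pytest.raises(DomainError, match="rank deficient"):
            gls_profile(np.random.default_rng(6).normal(size=8), X, np.eye(8))

    def test_perfect_fit_flagged_degenerate(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = X @ np.array([1.0, 2.0])
        beta, se, s2, ll = gls_profile(y, X, np.eye(8))
        assert s2 <= 1e-20 * np.var(y) and np.isfinite(ll)


class TestFitMl:
    def test_null_data_recovers_near_ols(self, small_world):
        cfg = SimConfig(n_species=20, seed=50, lambda_p=0.0, phi_s=0.0, beta=(1.0, 0.5))
        X = np.column_stack([np.ones(20), np.linspace(0, 1, 20)])
        from cyclemur import gen_traits

        y = gen_traits(small_world["tree"], small_world["ranges"], X, cfg)
        fit = fit_ml(y, X, small_world["P"], small_world["D"], n_starts=4)
        _, _, _, ll_ols = gls_profile(y, X, np.eye(20))
        assert fit.logLik >= ll_ols - 1e-6
        assert fit.AC < 0.5  # true AC is 0

    def test_optimum_beats_every_start(self, small_world):
        from cyclemur.gls import _STARTS, _unpack
        from scipy.special import logit

        rng = np.random.default_rng(51)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = rng.normal(size=20)
        fit = fit_ml(y, X, small_world["P"], small_world["D"])
        for ac0, pr0, de0 in _STARTS:
            model = _unpack(np.array([logit(ac0), logit(pr0), logit(de0)]))
            R0 = joint_correlation(small_world["P"], small_world["D"], model)
            _, _, _, ll0 = gls_profile(y, X, R0)
            assert fit.logLik >= ll0 - 1e-8

    def test_likelihood_monotone_in_nesting(self, small_world):
        rng = np.random.default_rng(52)
        x1 = rng.normal(size=20)
        x2 = rng.normal(size=20)
        y = 1.0 + 0.5 * x1 + rng.normal(size=20)
        P, D = small_world["P"], small_world["D"]
        f0 = fit_ml(y, np.ones((20, 1)), P, D, n_starts=4)
        f1 = fit_ml(y, np.column_stack([np.ones(20), x1]), P, D, n_starts=4)
        f2 = fit_ml(y, np.column_stack([np.ones(20), x1, x2]), P, D, n_starts=4)
        assert f0.logLik <= f1.logLik + 1e-6 <= f2.logLik + 2e-6


class TestModelSelection:
    def test_aicc_formula(self):
        # direct arithmetic: -2*(-10) + 2*3 + 2*3*4/(20-4)
        assert aicc(-10.0, 3, 20) == pytest.approx(20 + 6 + 1.5)

    def test_aicc_small_sample_guard(self):
        with pytest.raises(DomainError):
            aicc(-10.0, 5, 6)

    def test_singleton_table(self):
        t = akaike_table(np.array([42.0]))
        assert t["delta"].iloc[0] == 0 and t["w"].iloc[0] == 1 and t["rLL"].iloc[0] == 1

    def test_weights_sum_to_one_and_shift_invariant(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(100, 150, 8)
        t1 = akaike_table(a)
        t2 = akaike_table(a + 57.3)
        assert t1["w"].sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(t1["w"], t2["w"], atol=1e-10)
        assert list(t1["model"]) == list(t2["model"])
        assert t1["delta"].iloc[0] == 0 and t1["rLL"].iloc[0] == 1


class TestLrt:
    def _fit_pair(self, small_world):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = 1.0 + 0.8 * x + rng.normal(size=20)
        P, D = small_world["P"], small_world["D"]
        full = fit_ml(
            y, np.column_stack([np.ones(20), x]), P, D,
            names=["intercept", "x"], n_starts=4,
        )
        null = fit_ml(y, np.ones((20, 1)), P, D, names=["intercept"], n_starts=4)
        return full, null

    def test_identical_models_give_unit_p(self, small_world):
        full, _ = self._fit_pair(small_world)
        chi2, df, p = lrt(full, full)
        assert chi2 == 0 and df == 0 and p == 1.0

    def test_nested_pair_statistic_in_range(self, small_world):
        full, null = self._fit_pair(small_world)
        chi2, df, p = lrt(full, null)
        assert chi2 >= 0 and df == 1 and 0 <= p <= 1

    def test_chi2_cdf_oracle(self):
        # a 2-df statistic of 6.141 must give p just below 0.047
        p = float(stats.chi2.sf(6.141, 2))
        assert round(p, 3) == 0.046

    def test_non_nested_rejected(self, small_world):
        full, null = self._fit_pair(small_world)
        with pytest.raises(DomainError):
            lrt(null, full)


class TestPercentEffect:
    def test_zero_coefficient_is_zero(self):
        assert percent_effect(0.0) == 0.0

    def test_log_log_reading(self):
        assert percent_effect(-0.184) == pytest.approx(100 * (math.exp(-0.184) - 1))

    def test_linear_log_passthrough(self):
        assert percent_effect(6.177, form="linear-log") == pytest.approx(6.177)

    def test_unknown_form_rejected(self):
        with pytest.raises(DomainError):
            percent_effect(1.0, form="sqrt")
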