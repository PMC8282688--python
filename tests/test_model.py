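import numpy as np
import pytest

from tracreg import (CountTable, alpha_to_beta, ancestry_matrix,
                     compute_weights, fit_sparse_log_contrast, fit_trac,
                     parse_lineages)
from tracreg.model import TracFit, selected_support, training_loss_beta
from tracreg.simulate import default_scenario
from tracreg.taxonomy import SEP, Lineage

from .conftest import random_counts


class TestWeights:
    def test_inverse_leaf_count_exponents(self, balanced_tree4):
        root = balanced_tree4.root
        a_node = f"{root}{SEP}A"
        assert compute_weights(balanced_tree4, 1.0).w[a_node] == 0.25 * 2
        # |L_A| = 2: a=1 -> 1/2; build a 4-leaf node via the root's children
        w_half = compute_weights(balanced_tree4, 0.5).w[a_node]
        assert w_half == pytest.approx(2 ** -0.5)

    def test_leaves_always_unit_weight(self, three_leaf_tree):
        for a in [1.0, 0.5, -3.0]:
            scheme = compute_weights(three_leaf_tree, a)
            for leaf in three_leaf_tree.leaves:
                assert scheme.w[leaf] == 1.0

    def test_four_leaf_subtree_values(self):
        rows = [Lineage(f"t{k}", (("F", "A"), ("OTU", f"t{k}")))
                for k in range(4)]
        tree = parse_lineages(rows)
        node = f"{tree.root}{SEP}A"
        assert compute_weights(tree, 1.0).w[node] == 0.25
        assert compute_weights(tree, 0.5).w[node] == 0.5


class TestAlphaToBeta:
    def test_star_tree_beta_equals_alpha(self, star_tree4, rng):
        anc = ancestry_matrix(star_tree4)
        alpha = rng.normal(size=4)
        alpha -= alpha.mean()
        beta = alpha_to_beta(alpha, anc, np.ones(4))
        assert np.allclose(beta, alpha)

    def test_internal_node_spreads_uniformly(self, balanced_tree4):
        anc = ancestry_matrix(balanced_tree4)
        sizes = np.asarray(anc.A.sum(axis=0)).ravel()
        alpha = np.zeros(len(anc.column_order))
        a_idx = anc.column_order.index(f"{balanced_tree4.root}{SEP}A")
        alpha[a_idx] = 1.0
        beta = alpha_to_beta(alpha, anc, sizes)
        by_leaf = dict(zip(balanced_tree4.leaf_ids, beta))
        assert by_leaf == {"a1": 0.5, "a2": 0.5, "b1": 0.0, "b2": 0.0}

    def test_zero_maps_to_zero(self, three_leaf_tree):
        anc = ancestry_matrix(three_leaf_tree)
        sizes = np.asarray(anc.A.sum(axis=0)).ravel()
        assert np.allclose(alpha_to_beta(np.zeros(6), anc, sizes), 0.0)


class TestFitTrac:
    def test_constant_response_gives_empty_model(self, three_leaf_tree, rng):
        counts = random_counts(rng, three_leaf_tree, n=8)
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_trac(counts, np.full(8, 3.25), three_leaf_tree)
        assert np.allclose(fit.path.alpha, 0.0, atol=1e-10)
        fit.select(index=0)
        assert fit.intercept_hat == pytest.approx(3.25)

    def test_scale_invariance_of_path(self, three_leaf_tree, rng):
        counts = random_counts(rng, three_leaf_tree, n=15)
        y = rng.normal(size=15)
        fit0 = fit_trac(counts, y, three_leaf_tree, pseudocount=0.0)
        D = rng.uniform(0.1, 10.0, size=15)
        scaled = CountTable(counts.X * D[:, None], counts.sample_ids,
                            counts.taxon_ids)
        fit1 = fit_trac(scaled, y, three_leaf_tree, pseudocount=0.0,
                        lambdas=fit0.path.lambdas)
        assert np.allclose(fit0.path.alpha, fit1.path.alpha, atol=1e-8)

    def test_beta_representation_matches_alpha_loss(self, rng):
        sc = default_scenario(seed=1, n_samples=40)
        fit = fit_trac(sc.counts, sc.response.y, sc.tree, n_lambda=10)
        fit.select(index=5)
        loss_a, loss_b = training_loss_beta(sc.counts, sc.response.y, fit)
        assert loss_a == pytest.approx(loss_b, abs=1e-10)
        assert abs(fit.beta_hat.sum()) <= 1e-8

    def test_beta_constant_on_selected_subtrees(self, balanced_tree4, rng):
        counts = random_counts(rng, balanced_tree4, n=30)
        z = np.log(counts.X + 1.0)
        y = (z[:, 0] + z[:, 1]) / 2 - (z[:, 2] + z[:, 3]) / 2
        fit = fit_trac(counts, y, balanced_tree4, n_lambda=20)
        fit.select(index=10)
        sel = fit.selected
        if set(sel["taxon"]) == {"A", "B"}:
            beta = dict(zip(balanced_tree4.leaf_ids, fit.beta_hat))
            assert beta["a1"] == pytest.approx(beta["a2"], abs=1e-10)
            assert beta["b1"] == pytest.approx(beta["b2"], abs=1e-10)


class TestPredict:
    def test_empty_model_predicts_intercept(self, three_leaf_tree, rng):
        counts = random_counts(rng, three_leaf_tree, n=10)
        y = rng.normal(size=10)
        fit = fit_trac(counts, y, three_leaf_tree).select(index=0)
        pred = fit.predict(counts)
        assert np.allclose(pred, y.mean(), atol=1e-10)

    def test_in_sample_prediction_matches_fit(self, three_leaf_tree, rng):
        counts = random_counts(rng, three_leaf_tree, n=12)
        y = rng.normal(size=12)
        fit = fit_trac(counts, y, three_leaf_tree, n_lambda=12).select(index=8)
        feats_pred = fit.predict(counts)
        loss_a, _ = training_loss_beta(counts, y, fit)
        assert np.mean((y - feats_pred) ** 2) == pytest.approx(loss_a, abs=1e-12)

    def test_rescaled_sample_same_prediction(self, three_leaf_tree, rng):
        counts = random_counts(rng, three_leaf_tree, n=12)
        y = rng.normal(size=12)
        fit = fit_trac(counts, y, three_leaf_tree, pseudocount=0.0,
                       n_lambda=12).select(index=6)
        scaled = CountTable(counts.X * 7.3, counts.sample_ids, counts.taxon_ids)
        assert np.allclose(fit.predict(counts), fit.predict(scaled), atol=1e-10)

    def test_taxon_mismatch_names_offenders(self, three_leaf_tree, rng):
        counts = random_counts(rng, three_leaf_tree, n=6)
        y = rng.normal(size=6)
        fit = fit_trac(counts, y, three_leaf_tree).select(index=0)
        bad = CountTable(counts.X[:, :2], counts.sample_ids, ["G1", "G2"])
        with pytest.raises(ValueError, match="G3"):
            fit.predict(bad)


class TestSparseLogContrast:
    def test_equals_trac_on_star_tree(self, star_tree4, rng):
        counts = random_counts(rng, star_tree4, n=20)
        y = rng.normal(size=20)
        slc = fit_sparse_log_contrast(counts, y)
        trac = fit_trac(counts, y, star_tree4, a=1.0,
                        lambdas=slc.path.lambdas)
        assert np.allclose(slc.path.alpha, trac.path.alpha, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_very_negative_a_recovers_leaf_only_model(self, seed,
                                                      three_leaf_tree):
        rng = np.random.default_rng(seed)
        counts = random_counts(rng, three_leaf_tree, n=25)
        z = np.log(counts.X + 1.0)
        y = z[:, 0] - z[:, 2] + 0.05 * rng.normal(size=25)
        slc = fit_sparse_log_contrast(counts, y)
        trac = fit_trac(counts, y, three_leaf_tree, a=-5.0,
                        lambdas=slc.path.lambdas)
        leaf_idx = [trac.column_order.index(u) for u in three_leaf_tree.leaves]
        assert np.allclose(trac.path.alpha[leaf_idx], slc.path.alpha,
                           atol=1e-6)
        internal = [k for k in range(len(trac.column_order))
                    if k not in leaf_idx]
        assert np.allclose(trac.path.alpha[internal], 0.0, atol=1e-6)

    def test_two_taxon_prediction_is_log_ratio(self, rng):
        rows = [Lineage("u", (("OTU", "u"),)), Lineage("v", (("OTU", "v"),))]
        tree = parse_lineages(rows)
        X = rng.uniform(1, 100, size=(20, 2))
        counts = CountTable(X, [f"s{i}" for i in range(20)], ["u", "v"])
        y = np.log(X[:, 0] / X[:, 1]) * 1.5 + 2.0
        fit = fit_trac(counts, y, tree, pseudocount=0.0, n_lambda=20)
        fit.select(index=19)
        pred = fit.predict(counts)
        ratio = np.log(X[:, 0] / X[:, 1])
        # prediction is affine in the log-ratio
        coef = np.polyfit(ratio, pred, 1)
        assert np.allclose(np.polyval(coef, ratio), pred, atol=1e-6)


class TestSelectionSemantics:
    def test_log_ratio_of_two_selected_nodes(self, rng):
        sc = default_scenario(seed=2, n_samples=60)
        fit = fit_trac(sc.counts, sc.response.y, sc.tree, n_lambda=25)
        # pick a path point with exactly two selected nodes
        for k in range(len(fit.path.lambdas)):
            if int(selected_support(fit.path.alpha[:, k]).sum()) == 2:
                fit.select(index=k)
                break
        else:
            pytest.skip("no two-node solution on this path")
        sel = fit.selected
        assert len(sel) == 2
        assert sel["alpha"].iloc[0] * sel["alpha"].iloc[1] < 0

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_smaller_a_does_not_aggregate_more(self, seed):
        sc = default_scenario(seed=seed, n_samples=80)
        counts_leaf_level = []
        for a in [1.0, 0.5]:
            fit = fit_trac(sc.counts, sc.response.y, sc.tree, a=a, n_lambda=15)
            fit.select(index=10)
            sel = fit.selected
            counts_leaf_level.append((sel["level"] == "OTU").sum())
        assert counts_leaf_level[1] >= counts_leaf_level[0]


class TestSerialization:
    def test_round_trip_bit_exact(self, three_leaf_tree, rng):
        counts = random_counts(rng, three_leaf_tree, n=10)
        y = rng.normal(size=10)
        fit = fit_trac(counts, y, three_leaf_tree, n_lambda=8).select(index=4)
        text = fit.to_json()
        back = TracFit.from_json(text)
        assert back.chosen_lambda == fit.chosen_lambda
        assert np.array_equal(back.alpha_hat, fit.alpha_hat)
        assert back.intercept_hat == fit.intercept_hat
        assert back.to_json() == text
        assert np.allclose(back.predict(counts), fit.predict(counts),
                           atol=0.0)
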