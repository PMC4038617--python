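import numpy as np
import pandas as pd
import pytest

from ricenest.grids import DEFAULT_SCHEME, Grid, NODATA_CODE
from ricenest.refine import (
    ProbabilityRuleTable,
    RuleStack,
    bayes_update,
    estimate_rule_table,
    evaluate_evidence,
    fit_base_classifier,
    predict_rule_stack,
    relabel_max_posterior,
)
from ricenest.synth import generate_band_stack, generate_sample_plots
from ricenest.terrain import EvidenceLayer


def make_stack(probs_per_cell, shape=(1, 1)):
    """Stack with the same probability vector at every cell."""
    p = np.asarray(probs_per_cell, dtype=float)
    cube = np.broadcast_to(p[:, None, None], (7,) + shape).copy()
    return RuleStack(cube, 30.0)


def make_layer(name, values, n_values):
    grid = Grid(np.asarray(values, dtype=np.uint8), 30.0, nodata=NODATA_CODE)
    return EvidenceLayer(name, grid, {v: str(v) for v in range(n_values)})


def table_from_likelihoods(layer_values: dict[str, dict[int, np.ndarray]]):
    """Build a rule table from per-(layer, value) likelihood vectors.

    Vectors are arbitrary in [0, 1]; rows are rescaled so that, per layer
    and class, probabilities over values sum to 1 (Bayes posteriors are
    invariant to that per-class rescaling).
    """
    rows = []
    for layer, byval in layer_values.items():
        mat = np.stack([byval[v] for v in sorted(byval)])  # value x class
        mat = mat / mat.sum(axis=0)
        for i, v in enumerate(sorted(byval)):
            for j, name in enumerate(DEFAULT_SCHEME.names):
                rows.append({"layer": layer, "value": v, "class": name, "probability": mat[i, j]})
    return ProbabilityRuleTable(pd.DataFrame(rows))


class TestBayesUpdate:
    def test_uniform_likelihood_is_identity(self):
        prior = np.array([0.5, 0.3, 0.2])
        assert np.allclose(bayes_update(prior, [0.4, 0.4, 0.4]), prior)

    def test_three_class_hand_example(self):
        post = bayes_update([0.5, 0.3, 0.2], [0.2, 0.5, 0.3])
        assert np.allclose(post, [0.3226, 0.4839, 0.1935], atol=1e-4)

    def test_two_step_hand_example(self):
        step1 = bayes_update([0.5, 0.5], [0.9, 0.1])
        post = bayes_update(step1, [0.8, 0.2])
        assert np.allclose(post, [0.972973, 0.027027], atol=1e-6)

    def test_zero_likelihood_annihilates(self):
        post = bayes_update([0.5, 0.3, 0.2], [0.0, 0.5, 0.3])
        assert post[0] == 0.0 and abs(post.sum() - 1.0) < 1e-12

    def test_zero_denominator_returns_prior(self):
        prior = np.array([0.5, 0.5])
        assert np.allclose(bayes_update(prior, [0.0, 0.0]), prior)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bayes_update([0.7, 0.7], [0.5, 0.5])
        with pytest.raises(ValueError):
            bayes_update([0.5, 0.5], [1.5, 0.5])


class TestEvaluateEvidence:
    def test_zero_evidence_layers_identity(self):
        stack = make_stack([0.2, 0.1, 0.1, 0.1, 0.3, 0.1, 0.1], (3, 3))
        table = table_from_likelihoods({"t": {0: np.full(7, 0.5)}})
        post = evaluate_evidence(stack, [], table)
        assert np.allclose(post.probs, stack.probs)

    def test_sequential_equals_single_product_update(self):
        rng = np.random.default_rng(21)
        prior = rng.dirichlet(np.ones(7), size=(4, 4)).transpose(2, 0, 1)
        stack = RuleStack(prior, 30.0)
        like_a = {v: rng.uniform(0.05, 1.0, 7) for v in range(3)}
        like_b = {v: rng.uniform(0.05, 1.0, 7) for v in range(2)}
        table = table_from_likelihoods({"a": like_a, "b": like_b})
        values_a = rng.integers(0, 3, (4, 4))
        values_b = rng.integers(0, 2, (4, 4))
        la = make_layer("a", values_a, 3)
        lb = make_layer("b", values_b, 2)
        seq = evaluate_evidence(stack, [la, lb], table)
        # oracle: one update with the elementwise product of likelihoods
        prod = np.empty_like(stack.probs)
        for i in range(4):
            for j in range(4):
                lk = table.likelihood("a", int(values_a[i, j])) * table.likelihood("b", int(values_b[i, j]))
                prod[:, i, j] = bayes_update(stack.probs[:, i, j], lk / lk.max())
        assert np.allclose(seq.probs, prod, atol=1e-12)

    def test_evidence_order_commutes(self):
        rng = np.random.default_rng(22)
        prior = rng.dirichlet(np.ones(7), size=(5, 5)).transpose(2, 0, 1)
        stack = RuleStack(prior, 30.0)
        table = table_from_likelihoods({
            "a": {v: rng.uniform(0.05, 1.0, 7) for v in range(3)},
            "b": {v: rng.uniform(0.05, 1.0, 7) for v in range(2)},
        })
        la = make_layer("a", rng.integers(0, 3, (5, 5)), 3)
        lb = make_layer("b", rng.integers(0, 2, (5, 5)), 2)
        ab = evaluate_evidence(stack, [la, lb], table)
        ba = evaluate_evidence(stack, [lb, la], table)
        assert np.allclose(ab.probs, ba.probs, atol=1e-12)

    def test_posterior_normalised_at_every_cell(self):
        rng = np.random.default_rng(23)
        prior = rng.dirichlet(np.ones(7), size=(6, 6)).transpose(2, 0, 1)
        stack = RuleStack(prior, 30.0)
        table = table_from_likelihoods({"a": {v: rng.uniform(0.05, 1.0, 7) for v in range(4)}})
        layer = make_layer("a", rng.integers(0, 4, (6, 6)), 4)
        post = evaluate_evidence(stack, [layer], table)
        assert np.allclose(post.probs.sum(axis=0), 1.0, atol=1e-9)

    def test_missing_evidence_value_names_layer_and_value(self):
        stack = make_stack(np.full(7, 1 / 7), (2, 2))
        table = table_from_likelihoods({"terrain": {0: np.full(7, 0.5)}})
        layer = make_layer("terrain", np.array([[0, 1], [0, 0]]), 2)
        with pytest.raises(KeyError, match="terrain") as err:
            evaluate_evidence(stack, [layer], table)
        assert "1" in str(err.value)

    def test_impossible_evidence_keeps_prior_and_is_flagged(self):
        prior = np.array([0.6, 0.4, 0, 0, 0, 0, 0.0])
        stack = make_stack(prior, (1, 1))
        # likelihood zero exactly for the classes carrying prior mass
        lk = {0: np.array([0, 0, 1, 1, 1, 1, 1.0]), 1: np.ones(7)}
        table = table_from_likelihoods({"a": lk})
        layer = make_layer("a", np.array([[0]]), 2)
        post = evaluate_evidence(stack, [layer], table)
        assert post.n_flagged == 1
        assert np.allclose(post.probs[:, 0, 0], prior)

    def test_uninformative_table_leaves_base_map_unchanged(self, small_landscape):
        bands = small_landscape["bands"]
        plots = small_landscape["plots"]
        model = fit_base_classifier(plots, bands, seed=0)
        rules = predict_rule_stack(model, bands)
        base = relabel_max_posterior(rules)
        flat = {v: np.full(7, 0.7) for v in range(5)}
        table = table_from_likelihoods({"terrain_position": flat})
        post = evaluate_evidence(rules, [small_landscape["terrain"]], table)
        refined = relabel_max_posterior(post)
        assert np.array_equal(base.values, refined.values)


class TestRelabel:
    def test_unique_max(self):
        stack = make_stack([0.1, 0.7, 0.2, 0, 0, 0, 0.0])
        assert relabel_max_posterior(stack).values[0, 0] == 1

    def test_exact_tie_breaks_to_lowest_index(self):
        stack = make_stack([0.5, 0.5, 0, 0, 0, 0, 0.0])
        assert relabel_max_posterior(stack).values[0, 0] == 0

    def test_nodata_cell_propagates(self):
        cube = np.full((7, 2, 2), 1 / 7)
        cube[:, 0, 0] = np.nan
        out = relabel_max_posterior(RuleStack(cube, 30.0))
        assert out.values[0, 0] == NODATA_CODE
        assert out.values[1, 1] == 0


class TestRuleTable:
    def test_rows_must_sum_to_one_per_layer_class(self):
        rows = [{"layer": "a", "value": 0, "class": n, "probability": 0.4}
                for n in DEFAULT_SCHEME.names]
        with pytest.raises(ValueError):
            ProbabilityRuleTable(pd.DataFrame(rows))

    def test_csv_round_trip(self, tmp_path):
        table = table_from_likelihoods({"a": {0: np.full(7, 0.3), 1: np.full(7, 0.9)}})
        path = tmp_path / "rules.csv"
        table.to_csv(path)
        back = ProbabilityRuleTable.from_csv(path)
        assert np.allclose(back.likelihood("a", 0), table.likelihood("a", 0))

    def test_estimated_table_is_valid_and_covers_declared_values(self, small_landscape):
        table = estimate_rule_table(
            [small_landscape["terrain"], small_landscape["elevation"]],
            small_landscape["truth"], small_landscape["plots"],
        )
        for v in range(5):
            lk = table.likelihood("terrain_position", v)
            assert lk.shape == (7,) and np.all(lk >= 0)


class TestBaseClassifier:
    def test_single_class_training_rejected(self):
        truth = Grid(np.zeros((10, 10), dtype=np.uint8), 100.0)
        bands = generate_band_stack(truth, noise_sd=0.01, seed=0)
        plots = generate_sample_plots(truth, 20, seed=0)
        with pytest.raises(ValueError):
            fit_base_classifier(plots, bands, seed=0)

    def test_refit_is_deterministic(self, small_landscape):
        bands, plots = small_landscape["bands"], small_landscape["plots"]
        a = predict_rule_stack(fit_base_classifier(plots, bands, seed=3), bands)
        b = predict_rule_stack(fit_base_classifier(plots, bands, seed=3), bands)
        assert np.array_equal(a.probs, b.probs)

    def test_rule_stack_normalised_and_nodata_propagates(self, small_landscape):
        bands, plots = small_landscape["bands"], small_landscape["plots"]
        model = fit_base_classifier(plots, bands, seed=0)
        poked = [b.like(b.values.copy(), nodata=np.nan) for b in bands]
        poked[0].values[0, 0] = np.nan
        stack = predict_rule_stack(model, poked)
        assert np.all(np.isnan(stack.probs[:, 0, 0]))
        valid = stack.valid_mask()
        assert np.allclose(stack.probs[:, valid].sum(axis=0), 1.0, atol=1e-6)
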