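import itertools

import numpy as np
import pandas as pd
import pytest

from microdbn import (DynamicBayesianNetwork, LongitudinalDataset,
                      baseline_structure, bic_score, bootstrap_edge_support,
                      build_transition_dataset, fit_gaussian_cpd, hill_climb,
                      infer_edge_signs, log_likelihood, normalize_predictions,
                      predict_next, simulate_transition_data)
from microdbn.dbn import (DBNModel, GaussianCPD, TransitionDataset, build_nodes,
                          fit_model, model_from_dict, model_to_dict)
from tests.conftest import make_sample

LOG2PI = np.log(2 * np.pi)


def transitions_from_arrays(prev: dict, curr: dict, variables=None, subjects=None):
    n = len(next(iter(prev.values())))
    taxa = sorted(k for k in prev if not (variables or {}).get(k))
    return TransitionDataset(pd.DataFrame(prev), pd.DataFrame(curr),
                             subjects if subjects is not None
                             else np.array([f"s{i % 3}" for i in range(n)]),
                             taxa, variables or {})


class TestBuildTransitionDataset:
    def test_row_count(self):
        samples = [make_sample(f"s{i}", times=np.linspace(0, 4, 5))
                   for i in range(3)]
        data = build_transition_dataset(LongitudinalDataset(samples), rate=1.0)
        assert data.n == 12  # 3 subjects x (5 - 1) transitions

    def test_short_subject_excluded_with_warning(self):
        good = make_sample("good", times=np.linspace(0, 4, 5))
        short = make_sample("short", times=np.linspace(0, 0.5, 5))
        with pytest.warns(UserWarning, match="short"):
            data = build_transition_dataset(
                LongitudinalDataset([good, short]), rate=1.0)
        assert set(data.subjects) == {"good"}

    def test_rows_match_resampled_values(self):
        sample = make_sample("s", times=np.linspace(0, 4, 5))
        data = build_transition_dataset(LongitudinalDataset([sample]), rate=1.0)
        np.testing.assert_allclose(data.prev["taxon_1"].to_numpy(),
                                   sample.profiles["taxon_1"].values[:-1])
        np.testing.assert_allclose(data.curr["taxon_1"].to_numpy(),
                                   sample.profiles["taxon_1"].values[1:])


class TestGaussianCPD:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        u = rng.uniform(0, 1, 50)
        data = transitions_from_arrays({"A": u, "B": rng.uniform(0, 1, 50)},
                                       {"A": 1.0 + 2.0 * u, "B": np.zeros(50)})
        cpd = fit_gaussian_cpd("A", [("A", "prev")], data)
        lam0, coefs, sigma2 = cpd.pooled
        assert lam0 == pytest.approx(1.0, abs=1e-8)
        assert coefs[0] == pytest.approx(2.0, abs=1e-8)
        assert sigma2 == pytest.approx(cpd.variance_floor)

    def test_intercept_only(self):
        y = np.array([0.1, 0.2, 0.3, 0.4])
        data = transitions_from_arrays({"A": np.zeros(4)}, {"A": y})
        cpd = fit_gaussian_cpd("A", [], data)
        lam0, coefs, sigma2 = cpd.pooled
        assert lam0 == pytest.approx(y.mean())
        assert len(coefs) == 0
        assert sigma2 == pytest.approx(np.mean((y - y.mean()) ** 2))

    def test_independent_parent_coefficient_vanishes(self):
        rng = np.random.default_rng(1)
        n = 10_000
        u = rng.normal(0, 1, n)
        y = 0.3 + rng.normal(0, 1, n)  # y independent of u
        data = transitions_from_arrays({"A": u}, {"A": y})
        cpd = fit_gaussian_cpd("A", [("A", "prev")], data)
        assert abs(cpd.pooled[1][0]) < 0.05

    def test_per_configuration_fits_and_sparse_fallback(self):
        rng = np.random.default_rng(2)
        n = 60
        u = rng.uniform(0, 1, n)
        g = np.array((["x"] * 30) + (["y"] * 28) + (["z"] * 2))
        y = np.where(g == "x", 1.0 + 2.0 * u, np.where(g == "y", -1.0 + 0.5 * u, 7.0))
        data = transitions_from_arrays({"A": u, "G": g}, {"A": y, "G": g},
                                       variables={"G": "discrete"})
        cpd = fit_gaussian_cpd("A", [("A", "prev"), ("G", "prev")], data)
        assert cpd.configs[("x",)][0] == pytest.approx(1.0, abs=1e-6)
        assert cpd.configs[("y",)][1][0] == pytest.approx(0.5, abs=1e-6)
        assert ("z",) not in cpd.configs  # 2 rows < k + 2: pooled fallback
        # parameter count: two fitted configs + pooled, (k + 2) each
        assert cpd.n_params == 3 * 3


class TestLikelihoodAndBIC:
    def test_gaussian_closed_form_per_row(self):
        y = np.full(10, 0.4)
        data = transitions_from_arrays({"A": y}, {"A": y})
        cpd = GaussianCPD("A", [], [], {(): (0.4, np.array([]), 1.0)},
                          (0.4, np.array([]), 1.0), {(): 10}, 1)
        structure = baseline_structure(build_nodes(["A"]), 1)
        model = DBNModel(structure, {"A": cpd}, 10, 0.0, 0.0)
        ll = log_likelihood(model, data)
        assert ll == pytest.approx(10 * (-0.5 * LOG2PI))

    def test_empty_data_gives_zero(self):
        data = transitions_from_arrays({"A": np.array([])}, {"A": np.array([])})
        structure = baseline_structure(build_nodes(["A"]), 1)
        model = DBNModel(structure, {}, 0, 0.0, 0.0)
        assert log_likelihood(model, data) == 0.0
        with pytest.raises(ValueError):
            bic_score(model, data)

    def test_helpful_parent_never_decreases_likelihood(self):
        rng = np.random.default_rng(3)
        n = 500
        a = rng.normal(0.5, 0.2, n)
        b = 0.2 + 0.8 * a + rng.normal(0, 0.05, n)
        data = transitions_from_arrays({"A": a, "B": rng.normal(0.5, 0.2, n)},
                                       {"A": a, "B": b})
        nodes = build_nodes(["A", "B"])
        without = fit_model(baseline_structure(nodes, 3), data)
        richer = baseline_structure(nodes, 3)
        richer.inter_edges.add(("A", "B"))
        with_parent = fit_model(richer, data)
        assert with_parent.log_likelihood >= without.log_likelihood

    def test_bic_formula(self):
        # two intercept-only nodes with MLE variance e/(2*pi) give LL = -100
        # at N = 100; with d = 4 the score is -100 - 2 ln 100
        n = 100
        s = np.sqrt(1.0 / (2 * np.pi))  # MLE variance making LL = -50 per node
        y = s * np.tile([1.0, -1.0], n // 2) + 10.0
        data = transitions_from_arrays({"A": y, "B": y}, {"A": y, "B": y})
        structure = baseline_structure(build_nodes(["A", "B"]), 1)
        structure.inter_edges.clear()
        model = fit_model(structure, data)
        assert model.n_params == 4
        assert model.log_likelihood == pytest.approx(-100.0, rel=1e-9)
        assert model.bic == pytest.approx(-100.0 - 2.0 * np.log(100.0), rel=1e-9)

    def test_penalty_monotonicity(self):
        rng = np.random.default_rng(4)
        n = 200
        a = rng.normal(0.5, 0.2, n)
        noise = rng.normal(0, 1e-3, n)
        data = transitions_from_arrays(
            {"A": a, "B": rng.normal(0.5, 0.2, n)}, {"A": a + noise, "B": a})
        nodes = build_nodes(["A", "B"])
        small = fit_model(baseline_structure(nodes, 3), data)
        bigger = baseline_structure(nodes, 3)
        bigger.inter_edges.add(("B", "A"))  # useless parent for A
        big = fit_model(bigger, data)
        assert big.n_params > small.n_params
        # adding a useless parent lowers BIC at this N
        assert big.bic < small.bic


class TestBaselineStructure:
    def test_self_edges_only(self):
        taxa = [f"T{i}" for i in range(14)]
        nodes = build_nodes(taxa, {"C1": "discrete", "C2": "continuous"})
        s = baseline_structure(nodes, 3)
        assert s.inter_edges == {(t, t) for t in taxa}
        assert s.intra_edges == set()
        assert all(s.n_parents(t) == 1 for t in taxa)
        assert s.parents("T0") == [("T0", "prev")]


class TestHillClimb:
    def _two_taxa_data(self, n=2000, seed=0):
        cpds = {"A": (0.05, {("A", "prev"): 0.9}, 0.02 ** 2),
                "B": (0.6, {("B", "prev"): 0.8, ("A", "prev"): -0.6}, 0.02 ** 2)}
        return simulate_transition_data(cpds, n, seed=seed)

    def test_recovers_cross_edge(self):
        model = hill_climb(self._two_taxa_data(), max_parents=3)
        edges = model.structure.inter_edges
        assert {("A", "A"), ("B", "B"), ("A", "B")} <= edges
        assert ("B", "A") not in model.structure.intra_edges
        assert ("A", "B") not in model.structure.intra_edges

    def test_no_spurious_edges_for_self_dynamics(self):
        cpds = {"A": (0.05, {("A", "prev"): 0.8}, 0.02 ** 2),
                "B": (0.1, {("B", "prev"): 0.7}, 0.02 ** 2)}
        data = simulate_transition_data(cpds, 4000, seed=1)
        model = hill_climb(data, max_parents=3)
        assert model.structure.inter_edges == {("A", "A"), ("B", "B")}
        assert model.structure.intra_edges == set()

    def test_max_parents_respected(self):
        model = hill_climb(self._two_taxa_data(), max_parents=1)
        for t in model.structure.taxa:
            assert model.structure.n_parents(t) == 1  # fixed self-edge only

    def test_hill_climb_bic_at_least_baseline(self):
        data = self._two_taxa_data(n=500, seed=2)
        learned = hill_climb(data, max_parents=3)
        base = fit_model(baseline_structure(build_nodes(data.taxa), 3), data)
        assert learned.bic >= base.bic
        assert learned.structure.intra_is_acyclic()

    def test_greedy_closes_most_of_enumeration_gap(self):
        """Exhaustive-enumeration oracle on 3-taxon systems, max_parents=2."""
        for seed in range(4):
            cpds = {"A": (0.05, {("A", "prev"): 0.7}, 0.03 ** 2),
                    "B": (0.1, {("B", "prev"): 0.5, ("A", "prev"): 0.4}, 0.03 ** 2),
                    "C": (0.2, {("C", "prev"): 0.6, ("B", "curr"): -0.5}, 0.03 ** 2)}
            data = simulate_transition_data(cpds, 80, seed=seed)
            nodes = build_nodes(data.taxa)
            base = fit_model(baseline_structure(nodes, 2), data)
            greedy = hill_climb(data, max_parents=2)
            best = base.bic
            taxa = data.taxa
            options = {c: [None] + [(p, "prev") for p in taxa if True]
                       + [(p, "curr") for p in taxa if p != c] for c in taxa}
            for combo in itertools.product(*(options[c] for c in taxa)):
                s = baseline_structure(nodes, 2)
                ok = True
                for child, extra in zip(taxa, combo):
                    if extra is None:
                        continue
                    p, slice_ = extra
                    if slice_ == "prev":
                        if (p, child) in s.inter_edges:
                            ok = False
                            break
                        s.inter_edges.add((p, child))
                    else:
                        s.intra_edges.add((p, child))
                if not ok or not s.intra_is_acyclic():
                    continue
                best = max(best, fit_model(s, data).bic)
            gap = best - base.bic
            closed = greedy.bic - base.bic
            assert closed >= 0.95 * gap - 1e-9


class TestPredict:
    def _identity_model(self):
        data = transitions_from_arrays({"A": np.linspace(0.1, 0.9, 30)},
                                       {"A": np.linspace(0.1, 0.9, 30)})
        return hill_climb(data, max_parents=1)

    def test_identity_dynamics(self):
        model = self._identity_model()
        pred = predict_next(model, {"A": 0.42})
        assert pred["A"] == pytest.approx(0.42, abs=1e-6)

    def test_linear_arithmetic_and_clipping(self):
        cpd = GaussianCPD("A", [("A", "prev")], [],
                          {(): (0.1, np.array([0.5]), 1.0)},
                          (0.1, np.array([0.5]), 1.0), {(): 1}, 1)
        structure = baseline_structure(build_nodes(["A"]), 1)
        model = DBNModel(structure, {"A": cpd}, 1, 0.0, 0.0)
        assert predict_next(model, {"A": 0.4})["A"] == pytest.approx(0.3)
        assert predict_next(model, {"A": -0.5})["A"] == 0.0  # mean -0.15 clipped

    def test_missing_parent_named_in_error(self):
        model = self._identity_model()
        with pytest.raises(ValueError, match="A"):
            predict_next(model, {})


class TestNormalizePredictions:
    def test_proportions(self):
        np.testing.assert_allclose(normalize_predictions([2.0, 3.0, 5.0]),
                                   [0.2, 0.3, 0.5])

    def test_idempotent(self):
        v = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(normalize_predictions(v), v)

    def test_zero_vector_uniform_with_warning(self):
        with pytest.warns(UserWarning):
            out = normalize_predictions([0.0, 0.0, 0.0, 0.0])
        np.testing.assert_allclose(out, 0.25)


class TestBootstrapAndSigns:
    def test_b1_support_binary_and_deterministic(self):
        data = simulate_transition_data(
            {"A": (0.05, {("A", "prev"): 0.8}, 0.02 ** 2),
             "B": (0.1, {("B", "prev"): 0.7}, 0.02 ** 2)}, 200, seed=5)
        s1 = bootstrap_edge_support(data, max_parents=2, B=1, seed=7)
        s2 = bootstrap_edge_support(data, max_parents=2, B=1, seed=7)
        assert s1 == s2
        assert set(s1.values()) <= {0.0, 1.0}

    def test_strong_edge_high_support(self):
        cpds = {"A": (0.05, {("A", "prev"): 0.9}, 0.02 ** 2),
                "B": (0.6, {("B", "prev"): 0.8, ("A", "prev"): -0.6}, 0.02 ** 2)}
        data = simulate_transition_data(cpds, 2000, seed=6)
        support = bootstrap_edge_support(data, max_parents=3, B=50, seed=0)
        assert support[("A", "prev", "B")] > 0.8

    def test_edge_signs(self):
        cpds = {"A": (0.05, {("A", "prev"): 0.9}, 0.02 ** 2),
                "B": (0.6, {("B", "prev"): 0.8, ("A", "prev"): -0.6}, 0.02 ** 2)}
        model = hill_climb(simulate_transition_data(cpds, 2000, seed=6),
                           max_parents=3)
        signs = infer_edge_signs(model)
        assert signs[("A", "prev", "B")] == "negative"
        assert signs[("B", "prev", "B")] == "positive"

    def test_exact_zero_coefficient_is_neutral(self):
        cpd = GaussianCPD("A", [("B", "prev")], [],
                          {(): (0.1, np.array([0.0]), 1.0)},
                          (0.1, np.array([0.0]), 1.0), {(): 5}, 1)
        structure = baseline_structure(build_nodes(["A", "B"]), 2)
        structure.inter_edges.add(("B", "A"))
        trivial = GaussianCPD("B", [], [], {(): (0.5, np.array([]), 1.0)},
                              (0.5, np.array([]), 1.0), {(): 5}, 1)
        model = DBNModel(structure, {"A": cpd, "B": trivial}, 5, 0.0, 0.0)
        assert infer_edge_signs(model)[("B", "prev", "A")] == "neutral"


class TestEstimatorAndSerialization:
    def test_estimator_fit_predict(self):
        cpds = {"A": (0.05, {("A", "prev"): 0.9}, 0.02 ** 2),
                "B": (0.6, {("B", "prev"): 0.8, ("A", "prev"): -0.6}, 0.02 ** 2)}
        data = simulate_transition_data(cpds, 1000, seed=8)
        est = DynamicBayesianNetwork(max_parents=3).fit(data)
        assert est.bic_ == est.model_.bic
        preds = est.predict(data.prev.head(5), data.curr.head(5))
        assert list(preds.columns) == ["A", "B"]
        assert (preds.to_numpy() >= 0).all()

    def test_model_json_round_trip(self):
        data = simulate_transition_data(
            {"A": (0.05, {("A", "prev"): 0.8}, 0.02 ** 2),
             "B": (0.1, {("B", "prev"): 0.7, ("A", "curr"): 0.3}, 0.02 ** 2)},
            500, seed=9)
        model = hill_climb(data, max_parents=3)
        clone = model_from_dict(model_to_dict(model))
        assert clone.structure.inter_edges == model.structure.inter_edges
        assert clone.structure.intra_edges == model.structure.intra_edges
        assert clone.bic == model.bic
        obs_p, obs_c = data.prev.iloc[0], data.curr.iloc[0]
        assert predict_next(clone, obs_p, obs_c) == predict_next(model, obs_p, obs_c)
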