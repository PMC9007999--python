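import json

import numpy as np
import pandas as pd
import pytest

from oncodag.gbn import (
    EmptyEvidenceError,
    FittedNetwork,
    LinearGaussianCPD,
    QuerySpec,
    annotate_network,
    annotated_from_json,
    annotated_to_json,
    conditional_query,
    fit_linear_gaussian,
    logic_sample,
    quantile_contrast,
)
from oncodag.graphs import Graph
from oncodag.structure import BootStrengthTable


@pytest.fixture
def cancer_x_net():
    """Two-node fixture: Cancer ~ Bernoulli(0.5), X = 0.2 + 0.5*Cancer + N(0, 0.1^2)."""
    dag = Graph(["Cancer", "X"], arcs=[("Cancer", "X")])
    cpds = {
        "Cancer": LinearGaussianCPD("Cancer", 0.5, {}, 0.5),
        "X": LinearGaussianCPD("X", 0.2, {"Cancer": 0.5}, 0.1),
    }
    return FittedNetwork(dag, cpds, {"Cancer": "bernoulli"}, {"Cancer": 0.5})


class TestFit:
    def test_noiseless_line_recovered(self):
        x = np.linspace(0, 1, 50)
        frame = pd.DataFrame({"x": x, "y": 0.5 + 2 * x})
        dag = Graph(["x", "y"], arcs=[("x", "y")])
        net = fit_linear_gaussian(dag, frame)
        cpd = net.cpds["y"]
        assert cpd.intercept == pytest.approx(0.5, abs=1e-9)
        assert cpd.coefficients["x"] == pytest.approx(2.0, abs=1e-9)
        assert cpd.sd <= 1e-6

    def test_root_gets_mean_and_population_sd(self, rng):
        v = rng.normal(3.0, 2.0, size=200)
        frame = pd.DataFrame({"r": v})
        net = fit_linear_gaussian(Graph(["r"]), frame)
        assert net.cpds["r"].intercept == pytest.approx(v.mean())
        assert net.cpds["r"].sd == pytest.approx(v.std())

    def test_binary_root_flagged_bernoulli(self):
        frame = pd.DataFrame({"Cancer": [0.0, 1.0, 1.0, 0.0], "x": [0.1, 0.9, 0.8, 0.2]})
        dag = Graph(["Cancer", "x"], arcs=[("Cancer", "x")])
        net = fit_linear_gaussian(dag, frame)
        assert net.root_kind["Cancer"] == "bernoulli"
        assert net.root_p1["Cancer"] == pytest.approx(0.5)

    def test_collinear_parents_named(self, rng):
        a = rng.normal(size=50)
        frame = pd.DataFrame({"a": a, "b": 2 * a, "y": rng.normal(size=50)})
        dag = Graph(["a", "b", "y"], arcs=[("a", "y"), ("b", "y")])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_linear_gaussian(dag, frame)

    def test_coefficients_recovered_within_3se(self, rng):
        """Parameter recovery on a simulated 4-node network (n=2000)."""
        n = 2000
        hits = total = 0
        for rep in range(5):
            r = np.random.default_rng(100 + rep)
            a = r.normal(size=n)
            b = 0.8 * a + 0.3 * r.normal(size=n)
            c = -0.6 * a + 0.5 * b + 0.3 * r.normal(size=n)
            frame = pd.DataFrame({"a": a, "b": b, "c": c})
            dag = Graph(["a", "b", "c"], arcs=[("a", "b"), ("a", "c"), ("b", "c")])
            net = fit_linear_gaussian(dag, frame)
            truth = {("a", "b"): 0.8, ("a", "c"): -0.6, ("b", "c"): 0.5}
            for (p, ch), beta in truth.items():
                est = net.cpds[ch].coefficients[p]
                se = 3 * 0.3 / np.sqrt(n)  # conservative SE bound
                total += 1
                hits += abs(est - beta) < 3 * se
        assert hits / total >= 0.95


class TestLogicSample:
    def test_marginal_mean_matches_analytic(self, cancer_x_net):
        n = 100_000
        samples = logic_sample(cancer_x_net, n, seed=5)
        # E[X] = 0.2 + 0.5 * 0.5 = 0.45; MC se ~ sd/sqrt(n)
        se = samples["X"].std() / np.sqrt(n)
        assert abs(samples["X"].mean() - 0.45) < 3 * se
        assert set(np.unique(samples["Cancer"])) <= {0.0, 1.0}

    def test_zero_noise_is_deterministic_propagation(self):
        dag = Graph(["a", "b"], arcs=[("a", "b")])
        cpds = {
            "a": LinearGaussianCPD("a", 1.0, {}, 0.0),
            "b": LinearGaussianCPD("b", 0.5, {"a": 2.0}, 0.0),
        }
        net = FittedNetwork(dag, cpds, {"a": "gaussian"})
        s = logic_sample(net, 10, seed=0)
        assert np.all(s["a"] == 1.0) and np.all(s["b"] == 2.5)

    def test_same_seed_identical(self, cancer_x_net):
        s1 = logic_sample(cancer_x_net, 500, seed=3)
        s2 = logic_sample(cancer_x_net, 500, seed=3)
        pd.testing.assert_frame_equal(s1, s2)

    def test_convergence_rate_scales_with_sqrt_n(self, cancer_x_net):
        errs = []
        for n in (10**3, 10**4, 10**5):
            reps = [
                abs(logic_sample(cancer_x_net, n, seed=s)["X"].mean() - 0.45)
                for s in range(5)
            ]
            errs.append(np.mean(reps))
        assert errs[2] < errs[0]  # error shrinks with n
        assert errs[2] < 0.3 / np.sqrt(10**5) * 5


class TestConditionalQuery:
    def test_high_cancer_evidence_shifts_mean(self, cancer_x_net):
        spec = QuerySpec((("Cancer", ">", 0.95),), ("X",), None, 100_000, 7)
        survivors, summary = conditional_query(cancer_x_net, spec)
        se = summary.loc["X", "sd"] / np.sqrt(summary.loc["X", "n"])
        assert abs(summary.loc["X", "mean"] - 0.7) < 3 * se

    def test_low_cancer_evidence(self, cancer_x_net):
        spec = QuerySpec((("Cancer", "<", 0.05),), ("X",), None, 100_000, 7)
        _, summary = conditional_query(cancer_x_net, spec)
        se = summary.loc["X", "sd"] / np.sqrt(summary.loc["X", "n"])
        assert abs(summary.loc["X", "mean"] - 0.2) < 3 * se

    def test_impossible_evidence_raises(self, cancer_x_net):
        spec = QuerySpec((("Cancer", ">", 2.0),), ("X",), None, 1000, 0)
        with pytest.raises(EmptyEvidenceError):
            conditional_query(cancer_x_net, spec)

    def test_evidence_free_query_equals_unconditional(self, cancer_x_net):
        spec = QuerySpec((), ("X",), None, 2000, 11)
        survivors, summary = conditional_query(cancer_x_net, spec)
        raw = logic_sample(cancer_x_net, 2000, seed=11)
        assert summary.loc["X", "mean"] == raw["X"].mean()
        assert len(survivors) == 2000

    def test_unknown_evidence_node_rejected(self, cancer_x_net):
        spec = QuerySpec((("Nope", "<", 1.0),), (), None, 100, 0)
        with pytest.raises(KeyError, match="unknown node"):
            conditional_query(cancer_x_net, spec)

    def test_predicate_parsing(self):
        assert QuerySpec.parse_predicate("Cancer<0.05") == ("Cancer", "<", 0.05)
        assert QuerySpec.parse_predicate("X >= 1.5") == ("X", ">=", 1.5)
        with pytest.raises(ValueError):
            QuerySpec.parse_predicate("Cancer~1")


class TestQuantileContrast:
    def test_key_feature_gap_is_positive(self, rng):
        frame = pd.DataFrame({"k": rng.normal(size=100)})
        out = quantile_contrast(frame, "k", 5)
        assert out.loc["k", "delta"] > 0
        assert out.loc["k", "delta"] == pytest.approx(
            out.loc["k", "mean_top"] - out.loc["k", "mean_bottom"]
        )

    def test_independent_feature_small_delta(self, rng):
        n = 2000
        frame = pd.DataFrame({"k": rng.normal(size=n), "y": rng.normal(size=n)})
        out = quantile_contrast(frame, "k", 5, ["y"])
        pooled_se = np.sqrt(2) * frame["y"].std() / np.sqrt(n / 5)
        assert abs(out.loc["y", "delta"]) < 3 * pooled_se

    def test_group_sizes_differ_by_at_most_one(self, rng):
        frame = pd.DataFrame({"k": rng.normal(size=10)})
        out = quantile_contrast(frame, "k", 5)
        assert out.loc["k", "n_bottom"] == 2 and out.loc["k", "n_top"] == 2

    def test_constant_key_rejected(self):
        frame = pd.DataFrame({"k": np.ones(10)})
        with pytest.raises(ValueError, match="identical"):
            quantile_contrast(frame, "k", 5)


class TestAnnotate:
    def make_strengths(self, rows):
        frame = pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])
        return BootStrengthTable(frame, 100, "mmhc", 0)

    def test_signs_and_inclusion_probabilities(self, cancer_x_net):
        strengths = self.make_strengths([("Cancer", "X", 1.0, 1.0)])
        doc = annotate_network(cancer_x_net, strengths)
        arc = doc["arcs"][0]
        assert arc["effect"] == "promote" and arc["inclusion_probability"] == 1.0

    def test_negative_coefficient_tagged_inhibitory(self):
        dag = Graph(["a", "b"], arcs=[("a", "b")])
        cpds = {
            "a": LinearGaussianCPD("a", 0.0, {}, 1.0),
            "b": LinearGaussianCPD("b", 0.0, {"a": -1.5}, 1.0),
        }
        net = FittedNetwork(dag, cpds)
        doc = annotate_network(net, self.make_strengths([("a", "b", 0.8, 1.0)]))
        assert doc["arcs"][0]["effect"] == "inhibit"

    def test_missing_strength_rejected(self, cancer_x_net):
        with pytest.raises(KeyError, match="no bootstrap strength"):
            annotate_network(cancer_x_net, self.make_strengths([]))

    def test_json_round_trip(self, cancer_x_net):
        doc = annotate_network(
            cancer_x_net, self.make_strengths([("Cancer", "X", 1.0, 1.0)])
        )
        assert annotated_from_json(annotated_to_json(doc)) == doc


class TestSelfConsistency:
    def test_fit_sample_fit_recovers_parameters(self, cancer_x_net):
        samples = logic_sample(cancer_x_net, 100_000, seed=13)
        refit = fit_linear_gaussian(cancer_x_net.dag, samples)
        beta = refit.cpds["X"].coefficients["Cancer"]
        se = 0.1 / np.sqrt(100_000 * 0.25)
        assert abs(beta - 0.5) < 3 * se
        assert abs(refit.cpds["X"].intercept - 0.2) < 3 * se
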