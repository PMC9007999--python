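import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oncodag.graphs import Graph
from oncodag.stats import (
    CITester,
    GaussianScorer,
    arc_significance,
    exact_t_pvalue,
    gaussian_score,
    node_l1_bic,
    partial_correlation,
)

from .conftest import random_dag


def residual_pcor_oracle(frame, x, y, Z):
    """Independent oracle: correlate the residuals of OLS projections on Z."""
    def residual(col):
        v = frame[col].to_numpy(dtype=float)
        if not Z:
            return v - v.mean()
        A = np.column_stack([np.ones(len(frame)), frame[list(Z)].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(A, v, rcond=None)
        return v - A @ beta

    rx, ry = residual(x), residual(y)
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


class TestPartialCorrelation:
    def test_exact_linear_dependence(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [2.0, 4, 6, 8]})
        assert partial_correlation(df, "x", "y") == pytest.approx(1.0)

    def test_orthogonal_centered_vectors(self):
        df = pd.DataFrame({"x": [1.0, 1, -1, -1], "y": [1.0, -1, 1, -1]})
        assert partial_correlation(df, "x", "y") == pytest.approx(0.0, abs=1e-12)

    def test_chain_conditioning_removes_dependence(self, chain_frame):
        assert abs(partial_correlation(chain_frame, "X", "Z", ["Y"])) < 0.1

    def test_matches_residual_regression_oracle(self, rng):
        frame = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        for Z in ([], ["c"], ["c", "d"], ["c", "d", "e"]):
            mine = partial_correlation(frame, "a", "b", Z)
            oracle = residual_pcor_oracle(frame, "a", "b", Z)
            assert mine == pytest.approx(oracle, abs=1e-10)

    def test_collinear_conditioning_named_in_error(self, rng):
        n = 30
        c = rng.normal(size=n)
        frame = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n), "c": c, "d": 2 * c}
        )
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            partial_correlation(frame, "a", "b", ["c", "d"])


class TestExactT:
    def test_zero_correlation_gives_p_one(self):
        assert exact_t_pvalue(0.0, 30) == 1.0

    def test_textbook_value(self):
        # r=0.5, n=27, |Z|=0: t = 0.5*5/sqrt(0.75) = 2.8868, df=25
        t = 0.5 * math.sqrt(25) / math.sqrt(1 - 0.25)
        assert t == pytest.approx(2.8868, abs=1e-4)
        expected = 2 * sps.t.sf(t, 25)
        assert exact_t_pvalue(0.5, 27) == pytest.approx(expected, abs=1e-12)

    def test_perfect_correlation_underflows_not_zero(self):
        p = exact_t_pvalue(1.0, 10)
        assert 0 < p < 1e-300

    def test_monotone_decreasing_in_abs_r(self):
        ps = [exact_t_pvalue(r, 50) for r in np.linspace(0.0, 0.99, 25)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValueError, match="df"):
            exact_t_pvalue(0.3, 4, cond_size=2)

    def test_matches_student_cdf_oracle_on_random_instances(self, rng):
        """|dp| < 1e-10 against an independent Student-CDF computation."""
        for _ in range(100):
            n = int(rng.integers(10, 51))
            cond = int(rng.integers(0, 4))
            r = float(rng.uniform(-0.95, 0.95))
            df = n - cond - 2
            t = abs(r) * math.sqrt(df) / math.sqrt(1 - r * r)
            oracle = 2 * (1 - sps.t.cdf(t, df))
            assert abs(exact_t_pvalue(r, n, cond) - oracle) < 1e-10


def brute_force_l1_bic(frame, node, parents):
    """Explicit normal-equations OLS + absolute residual sum + log10 penalty."""
    y = frame[node].to_numpy(float)
    if parents:
        A = np.column_stack([np.ones(len(y)), frame[list(parents)].to_numpy(float)])
        theta = np.linalg.inv(A.T @ A) @ A.T @ y
        yhat = A @ theta
    else:
        yhat = np.full_like(y, y.mean())
    return len(parents) * math.log10(len(y)) + float(np.abs(yhat - y).sum())


class TestNodeL1Bic:
    def test_constant_node_no_parents_is_zero(self):
        df = pd.DataFrame({"y": [0.0, 0, 0, 0]})
        assert node_l1_bic("y", [], df).bic == 0.0

    def test_perfect_fit_leaves_only_penalty(self):
        x = np.linspace(0, 1, 100)
        df = pd.DataFrame({"x": x, "y": x})
        rec = node_l1_bic("y", ["x"], df)
        assert rec.l1_loss == pytest.approx(0.0, abs=1e-9)
        assert rec.bic == pytest.approx(1 * math.log10(100), abs=1e-9)

    def test_noise_parent_costs_about_log10_n(self, rng):
        n = 400
        x = rng.normal(size=n)
        y = x + 0.3 * rng.normal(size=n)
        noise = rng.normal(size=n)
        df = pd.DataFrame({"x": x, "y": y, "noise": noise})
        base = node_l1_bic("y", ["x"], df).bic
        plus = node_l1_bic("y", ["x", "noise"], df).bic
        assert 0 < plus - base <= math.log10(n) + 1e-9

    def test_matches_brute_force_to_1e12(self, rng):
        frame = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("wxyz"))
        for parents in ([], ["w"], ["w", "x"], ["w", "x", "z"]):
            rec = node_l1_bic("y", parents, frame)
            assert rec.bic == pytest.approx(
                brute_force_l1_bic(frame, "y", parents), abs=1e-12
            )
            assert rec.bic == pytest.approx(
                rec.n_arcs * math.log10(rec.n_obs) + rec.l1_loss
            )


def brute_force_gaussian_bic(frame, node, parents):
    y = frame[node].to_numpy(float)
    n = len(y)
    if parents:
        A = np.column_stack([np.ones(n), frame[list(parents)].to_numpy(float)])
        theta = np.linalg.inv(A.T @ A) @ A.T @ y
        resid = y - A @ theta
    else:
        resid = y - y.mean()
    var = float(resid @ resid) / n
    loglik = -0.5 * n * (math.log(2 * math.pi * var) + 1)
    return loglik - 0.5 * (len(parents) + 2) * math.log(n)


class TestGaussianScore:
    def test_matches_closed_form_ols_oracle(self, rng):
        frame = pd.DataFrame(rng.normal(size=(80, 4)), columns=list("abcd"))
        for parents in ([], ["a"], ["a", "b"], ["a", "b", "d"]):
            assert gaussian_score("c", parents, frame) == pytest.approx(
                brute_force_gaussian_bic(frame, "c", parents), abs=1e-10
            )

    def test_noise_parent_usually_rejected(self, rng):
        wins = 0
        for _ in range(20):
            y = rng.normal(size=500)
            x = rng.normal(size=500)
            df = pd.DataFrame({"x": x, "y": y})
            if gaussian_score("y", [], df) > gaussian_score("y", ["x"], df):
                wins += 1
        assert wins >= 19

    def test_deterministic_parent_capped_by_variance_guard(self):
        x = np.linspace(0, 1, 50)
        df = pd.DataFrame({"x": x, "y": 2 * x})
        assert np.isfinite(gaussian_score("y", ["x"], df))

    def test_network_score_decomposes_over_nodes(self, rng):
        frame = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        scorer = GaussianScorer(frame)
        for _ in range(50):
            dag = random_dag(list("abcde"), 0.4, rng)
            total = scorer.network_score(dag)
            parts = sum(scorer.local_score(n, dag.parents(n)) for n in dag.nodes)
            assert total == pytest.approx(parts, abs=1e-10)


class TestArcSignificance:
    def test_conditions_on_other_parents_of_child(self, collider_frame):
        dag = Graph("ABC", arcs=[("A", "C"), ("B", "C")])
        rec = arc_significance(dag, ("A", "C"), collider_frame)
        assert rec.cond_size == 1
        oracle = residual_pcor_oracle(collider_frame, "A", "C", ["B"])
        assert rec.r == pytest.approx(oracle, abs=1e-10)

    def test_single_parent_reduces_to_plain_pearson(self, chain_frame):
        dag = Graph("XYZ", arcs=[("X", "Y"), ("Y", "Z")])
        rec = arc_significance(dag, ("X", "Y"), chain_frame)
        assert rec.cond_size == 0
        r, p = sps.pearsonr(chain_frame["X"], chain_frame["Y"])
        assert rec.r == pytest.approx(r, abs=1e-10)
        assert rec.p_value == pytest.approx(p, rel=1e-6)

    def test_arc_not_in_graph_rejected(self, chain_frame):
        dag = Graph("XYZ", arcs=[("X", "Y")])
        with pytest.raises(ValueError, match="not in graph"):
            arc_significance(dag, ("X", "Z"), chain_frame)


class TestCITester:
    def test_agrees_with_public_partial_correlation(self, rng):
        frame = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        tester = CITester(frame)
        for Z in ([], ["c"], ["d", "e"], ["c", "d", "e"]):
            r, p = tester.test("a", "b", Z)
            assert r == pytest.approx(partial_correlation(frame, "a", "b", Z), abs=1e-9)
            assert p == pytest.approx(
                exact_t_pvalue(partial_correlation(frame, "a", "b", Z), 60, len(Z)),
                rel=1e-9,
            )

    def test_symmetric_in_arguments(self, rng):
        frame = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        tester = CITester(frame)
        assert tester.test("a", "b", ["c"]) == tester.test("b", "a", ["c"])


class TestDiscreteCITester:
    def test_unconditional_g_matches_contingency_oracle(self, rng):
        from scipy.stats import chi2_contingency

        from oncodag.stats import DiscreteCITester

        x = rng.integers(0, 3, 500)
        y = (x + rng.integers(0, 2, 500)) % 3
        frame = pd.DataFrame({"x": x, "y": y})
        g, p = DiscreteCITester(frame).test("x", "y")
        g2, p2, _, _ = chi2_contingency(
            pd.crosstab(frame.x, frame.y).to_numpy(),
            correction=False,
            lambda_="log-likelihood",
        )
        assert g == pytest.approx(g2, abs=1e-8)
        assert p == pytest.approx(p2, rel=1e-8)

    def test_conditioning_separates_discretized_chain(self, rng):
        from oncodag.stats import DiscreteCITester

        a = rng.integers(0, 4, 1000)
        b = np.clip(a + rng.integers(-1, 2, 1000), 0, 3)
        c = np.clip(b + rng.integers(-1, 2, 1000), 0, 3)
        frame = pd.DataFrame({"a": a, "b": b, "c": c})
        tester = DiscreteCITester(frame)
        assert tester.pvalue("a", "c") < 0.01          # marginally dependent
        assert tester.pvalue("a", "c", ["b"]) > 0.01   # separated by b

    def test_non_integer_data_rejected(self, rng):
        from oncodag.stats import DiscreteCITester

        with pytest.raises(ValueError, match="integer-coded"):
            DiscreteCITester(pd.DataFrame({"x": rng.normal(size=10)}))
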