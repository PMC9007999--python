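import numpy as np
import pandas as pd
import pytest

from oncodag.graphs import ConstraintLists, Graph
from oncodag.stats import GaussianScorer
from oncodag.structure import (
    ALGORITHMS,
    BootStrengthTable,
    LearnConfig,
    averaged_network,
    bootstrap_arc_strengths,
    learn_structure,
    optimal_inclusion_threshold,
)

from .conftest import all_dags

CHAIN_CONSTRAINTS = ConstraintLists(
    blacklist=frozenset({("Y", "X"), ("Z", "Y"), ("Z", "X")})
)


class TestLearnStructure:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            LearnConfig(algorithm="ges")

    def test_independent_columns_give_empty_graph(self, independent_frame):
        g = learn_structure(independent_frame, LearnConfig("hc"))
        assert g.arcs == set() and g.undirected == set()

    @pytest.mark.parametrize("alg", ["hc", "tabu", "mmhc", "rsmax2"])
    def test_chain_with_roles_recovered_exactly(self, chain_frame, alg):
        g = learn_structure(chain_frame, LearnConfig(alg), CHAIN_CONSTRAINTS)
        assert g.arcs == {("X", "Y"), ("Y", "Z")}

    @pytest.mark.parametrize("alg", ["pc_stable", "gs", "iamb", "iamb_fdr"])
    def test_chain_skeleton_from_constraint_learners(self, chain_frame, alg):
        g = learn_structure(chain_frame, LearnConfig(alg), CHAIN_CONSTRAINTS)
        assert g.skeleton() == {frozenset(("X", "Y")), frozenset(("Y", "Z"))}
        assert g.arcs == {("X", "Y"), ("Y", "Z")}  # orientations forced by roles

    def test_pc_stable_finds_collider(self, collider_frame):
        g = learn_structure(collider_frame, LearnConfig("pc_stable"))
        assert ("A", "C") in g.arcs and ("B", "C") in g.arcs

    @pytest.mark.parametrize("alg", ["mmpc", "si_hiton_pc"])
    def test_local_discovery_returns_undirected_edges(self, chain_frame, alg):
        g = learn_structure(chain_frame, LearnConfig(alg))
        assert g.arcs == set()
        assert g.skeleton() == {frozenset(("X", "Y")), frozenset(("Y", "Z"))}

    def test_pc_stable_is_order_invariant(self, collider_frame, chain_frame):
        for frame in (collider_frame, chain_frame):
            g1 = learn_structure(frame, LearnConfig("pc_stable"))
            shuffled = frame[list(frame.columns)[::-1]]
            g2 = learn_structure(shuffled, LearnConfig("pc_stable"))
            assert g1.skeleton() == g2.skeleton()
            assert g1.arcs == g2.arcs

    def test_whitelist_always_present_blacklist_never(self, independent_frame):
        cons = ConstraintLists(
            blacklist=frozenset({("C", "D")}), whitelist=frozenset({("A", "B")})
        )
        for alg in ALGORITHMS:
            g = learn_structure(independent_frame, LearnConfig(alg), cons)
            assert ("A", "B") in g.arcs, alg
            assert ("C", "D") not in g.arcs, alg

    def test_hc_with_restarts_attains_bruteforce_optimum_on_3_nodes(self):
        """Exhaustive enumeration of all 25 DAGs over three nodes."""
        rng = np.random.default_rng(3)
        for trial in range(10):
            x = rng.normal(size=150)
            y = 0.9 * x + 0.5 * rng.normal(size=150)
            z = -0.8 * y + 0.5 * rng.normal(size=150)
            frame = pd.DataFrame({"A": x, "B": y, "C": z})
            scorer = GaussianScorer(frame)
            dags = list(all_dags(["A", "B", "C"]))
            assert len(dags) == 25
            best = max(scorer.network_score(d) for d in dags)
            g = learn_structure(frame, LearnConfig("hc", restarts=10, seed=trial))
            assert scorer.network_score(g) == pytest.approx(best, abs=1e-6)


class TestBootstrap:
    def test_strong_arc_has_high_strength(self, chain_frame):
        table = bootstrap_arc_strengths(
            chain_frame, LearnConfig("hc"), CHAIN_CONSTRAINTS, n_boot=100, seed=0
        )
        assert table.strength("X", "Y") >= 0.9
        assert table.strength("Y", "Z") >= 0.9

    def test_independent_pair_has_low_strength(self, independent_frame):
        table = bootstrap_arc_strengths(
            independent_frame, LearnConfig("hc"), n_boot=100, seed=0
        )
        for a in "ABCD":
            for b in "ABCD":
                if a < b:
                    assert table.strength(a, b) <= 0.2

    def test_whitelisted_arc_has_strength_one(self, independent_frame):
        cons = ConstraintLists(whitelist=frozenset({("A", "B")}))
        table = bootstrap_arc_strengths(
            independent_frame, LearnConfig("hc"), cons, n_boot=50, seed=1
        )
        assert table.strength("A", "B") == 1.0
        assert table.direction("A", "B") == 1.0

    def test_same_seed_byte_identical(self, chain_frame, tmp_path):
        out = []
        for run in range(2):
            t = bootstrap_arc_strengths(
                chain_frame, LearnConfig("tabu"), CHAIN_CONSTRAINTS, n_boot=40, seed=9
            )
            p = tmp_path / f"run{run}.csv"
            t.to_csv(p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_blacklist_respected_in_every_replicate(self, chain_frame):
        table = bootstrap_arc_strengths(
            chain_frame, LearnConfig("hc"), CHAIN_CONSTRAINTS, n_boot=60, seed=2
        )
        # a fully blacklisted direction can only appear via its reverse arc
        assert table.direction("Y", "X") == 0.0 or table.strength("X", "Y") == 0.0
        assert table.direction("X", "Y") == 1.0

    def test_invalid_n_boot(self, chain_frame):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_arc_strengths(chain_frame, n_boot=0)


def threshold_oracle(strengths):
    """Dense-grid numeric integration of the L1 CDF distance."""
    s = np.sort(np.asarray(strengths, float))
    grid = np.linspace(0, 1, 20001)[:-1]
    ecdf = np.searchsorted(s, grid, side="right") / s.size
    candidates = list(np.unique(s)) + [float(np.nextafter(s.max(), 2.0))]
    best_t, best_val = None, np.inf
    for t in candidates:
        f = (s < t).sum() / s.size
        val = np.abs(ecdf - f).mean()
        if val <= best_val + 1e-12:
            best_t, best_val = t, min(val, best_val)
    return best_t


class TestInclusionThreshold:
    def test_three_strong_two_weak(self):
        t = optimal_inclusion_threshold([1, 1, 1, 0.02, 0.01])
        assert 0.02 < t <= 1.0
        assert sum(s >= t for s in [1, 1, 1, 0.02, 0.01]) == 3

    def test_all_ones_retains_everything(self):
        assert optimal_inclusion_threshold([1.0, 1.0]) <= 1.0

    def test_all_zero_retains_nothing(self):
        t = optimal_inclusion_threshold([0.0, 0.0, 0.0])
        assert t > 0.0

    def test_matches_bruteforce_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            k = int(rng.integers(1, 40))
            s = rng.random(k)
            if rng.random() < 0.5:  # make some vectors bimodal
                s = np.where(rng.random(k) < 0.5, s * 0.1, 1 - s * 0.1)
            assert optimal_inclusion_threshold(s) == pytest.approx(
                threshold_oracle(s), abs=1e-12
            )

    def test_bimodal_vectors_separated(self, rng):
        for _ in range(50):
            lo = rng.uniform(0.0, 0.1, rng.integers(1, 10))
            hi = rng.uniform(0.9, 1.0, rng.integers(1, 10))
            s = np.concatenate([lo, hi])
            t = optimal_inclusion_threshold(s)
            assert np.all(lo < t) and np.all(hi >= t)


class TestAveragedNetwork:
    def make_table(self, rows):
        frame = pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])
        return BootStrengthTable(frame, n_boot=100, algorithm="hc", seed=0)

    def test_orientation_conventions(self):
        table = self.make_table(
            [
                ("A", "B", 0.95, 0.9),   # directed A->B
                ("A", "C", 0.95, 0.5),   # tie: undirected
                ("B", "C", 0.95, 0.1),   # directed C->B
                ("C", "D", 0.3, 1.0),    # below threshold: excluded
            ]
        )
        g = averaged_network(table, threshold=0.5)
        assert ("A", "B") in g.arcs
        assert frozenset(("A", "C")) in g.undirected
        assert ("C", "B") in g.arcs
        assert not g.adjacent("C", "D")

    def test_cycle_resolved_by_dropping_weakest_arc(self):
        table = self.make_table(
            [
                ("A", "B", 0.9, 1.0),
                ("B", "C", 0.8, 1.0),
                ("A", "C", 0.7, 0.0),  # C->A closes the cycle, weakest
            ]
        )
        with pytest.warns(UserWarning, match="cycle"):
            g = averaged_network(table, threshold=0.5)
        assert g.is_acyclic()
        assert ("C", "A") not in g.arcs
        assert ("A", "B") in g.arcs and ("B", "C") in g.arcs


class TestDiscreteVariant:
    def test_pc_stable_with_mi_test_on_discretized_chain(self):
        from oncodag.feature_table import FeatureTable, discretize

        rng = np.random.default_rng(1)
        a = rng.normal(size=800)
        b = a + 0.4 * rng.normal(size=800)
        c = b + 0.4 * rng.normal(size=800)
        raw = pd.DataFrame({"A": a, "B": b, "C": c})
        norm = (raw - raw.min()) / (raw.max() - raw.min())
        norm.index = [f"s{i}" for i in range(800)]
        disc = discretize(FeatureTable(norm, normalized=True), 6)
        g = learn_structure(disc.data, LearnConfig("pc_stable", ci_test="mi"))
        assert g.skeleton() == {frozenset(("A", "B")), frozenset(("B", "C"))}

    def test_invalid_ci_test_rejected(self):
        with pytest.raises(ValueError, match="ci_test"):
            LearnConfig(ci_test="fisher")
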