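"""Model/Results interface over the whole consensus workflow.

``ConsensusDAGModel`` wraps a feature table plus node roles; ``fit()`` runs
the four-step procedure — compile the role blacklist, bootstrap an ensemble
of structure-learning algorithms, build the consensus-seed whitelist from the
node-level L1-BIC sweep, and learn the final averaged network under both
constraint lists — then fits the linear-Gaussian parameters by maximum
likelihood.  The returned ``ConsensusDAGResults`` carries the intermediate
artifacts (strength tables, edge evidence, BIC sweep, seed whitelist) and the
fitted network; simulation, conditional queries, and quantile contrasts hang
off it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import consensus as _consensus
from .feature_table import FeatureTable, PreprocessConfig, preprocess
from .gbn import (
    FittedNetwork,
    QuerySpec,
    annotate_network,
    conditional_query,
    fit_linear_gaussian,
    logic_sample,
    quantile_contrast,
)
from .graphs import ConstraintLists, Graph, NodeRoleMap, build_blacklist, orient_pdag
from .structure import (
    ALGORITHMS,
    BootStrengthTable,
    LearnConfig,
    averaged_network,
    bootstrap_arc_strengths,
)

__all__ = ["ConsensusDAGModel", "ConsensusDAGResults", "DEFAULT_ENSEMBLE"]

DEFAULT_ENSEMBLE = ALGORITHMS  # all ten


class ConsensusDAGModel:
    """Consensus Bayesian-network model of a samples x features table.

    Parameters
    ----------
    table
        Feature table (or plain DataFrame) of continuous cell-level features
        and 0/1 sample attributes.  If not yet normalized it is preprocessed
        (log transform + min-max to [0, 1]) on construction.
    roles
        Node roles encoding prior causal knowledge (root / leaf / quasi-root);
        compiled into the structure-learning blacklist.
    """

    def __init__(
        self,
        table: FeatureTable | pd.DataFrame,
        roles: NodeRoleMap | Mapping | None = None,
        preprocess_cfg: PreprocessConfig | None = None,
    ) -> None:
        if isinstance(table, pd.DataFrame):
            table = FeatureTable.from_dataframe(table)
        if not table.normalized:
            table = preprocess(table, preprocess_cfg)
        self.table = table
        if roles is None:
            roles = NodeRoleMap()
        elif not isinstance(roles, NodeRoleMap):
            roles = NodeRoleMap.from_dict(roles)
        self.roles = roles
        self.blacklist = tuple(build_blacklist(table.feature_names, roles))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        roles: NodeRoleMap | Mapping | None = None,
        preprocess_cfg: PreprocessConfig | None = None,
    ) -> "ConsensusDAGModel":
        return cls(FeatureTable.from_dataframe(df), roles, preprocess_cfg)

    @classmethod
    def from_csv(cls, path, roles=None, preprocess_cfg=None) -> "ConsensusDAGModel":
        return cls(FeatureTable.from_csv(path), roles, preprocess_cfg)

    def fit(
        self,
        algorithms: Sequence[str] = DEFAULT_ENSEMBLE,
        n_boot: int = 10_000,
        alpha: float = 0.05,
        threshold_grid: Sequence[float] | None = None,
        p_selector: str = "min_p",
        final_algorithm: str = "mmhc",
        final_n_boot: int | None = None,
        seed: int | None = None,
    ) -> "ConsensusDAGResults":
        """Run the four-step consensus workflow and fit the Gaussian network.

        Every source of randomness derives from ``seed``: each ensemble
        algorithm gets an independent child seed, as does the final
        bootstrap.  Identical inputs and seed reproduce identical results.
        """
        unknown = set(algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithm(s): {sorted(unknown)}")
        frame = self.table.data
        constraints = ConstraintLists(blacklist=frozenset(self.blacklist))
        ss = np.random.SeedSequence(seed)
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(algorithms) + 1)]

        strength_tables: dict[str, BootStrengthTable] = {}
        averaged: dict[str, Graph] = {}
        for alg, alg_seed in zip(algorithms, child_seeds[:-1]):
            cfg = LearnConfig(algorithm=alg, alpha=alpha)
            st = bootstrap_arc_strengths(
                frame, cfg, constraints, n_boot=n_boot, seed=alg_seed
            )
            strength_tables[alg] = st
            averaged[alg] = averaged_network(st, nodes=list(frame.columns))

        evidence = _consensus.aggregate_ensemble(averaged, frame)
        sweep = _consensus.sweep_whitelist(
            evidence,
            frame,
            constraints,
            threshold_grid=threshold_grid,
            p_selector=p_selector,
            learn_cfg=LearnConfig(algorithm=final_algorithm, alpha=alpha),
        )
        whitelist = _consensus.select_consensus_seed(sweep)
        final_constraints = constraints.with_whitelist(whitelist)
        final_strengths, final_dag = _consensus.final_learning(
            frame,
            final_constraints,
            n_boot=final_n_boot if final_n_boot is not None else n_boot,
            seed=child_seeds[-1],
            learn_cfg=LearnConfig(algorithm=final_algorithm, alpha=alpha),
        )
        _consensus.classify_edges(evidence, whitelist)
        dag = orient_pdag(final_dag) if final_dag.undirected else final_dag
        network = fit_linear_gaussian(
            dag, frame, attribute_nodes=self.table.attribute_features()
        )
        network.arc_strengths = {
            arc: final_strengths.strength(*arc) for arc in dag.sorted_arcs()
        }
        return ConsensusDAGResults(
            model=self,
            constraints=final_constraints,
            strength_tables=strength_tables,
            averaged_networks=averaged,
            evidence=evidence,
            sweep=sweep,
            whitelist=tuple(whitelist),
            final_strengths=final_strengths,
            dag=dag,
            network=network,
            seed=seed,
            config={
                "algorithms": tuple(algorithms),
                "n_boot": n_boot,
                "alpha": alpha,
                "p_selector": p_selector,
                "final_algorithm": final_algorithm,
                "final_n_boot": final_n_boot if final_n_boot is not None else n_boot,
            },
        )


@dataclass
class ConsensusDAGResults:
    """Fitted consensus network with all intermediate evidence."""

    model: ConsensusDAGModel
    constraints: ConstraintLists
    strength_tables: dict[str, BootStrengthTable]
    averaged_networks: dict[str, Graph]
    evidence: _consensus.EdgeEvidenceTable
    sweep: _consensus.BicSweepTable
    whitelist: tuple
    final_strengths: BootStrengthTable
    dag: Graph
    network: FittedNetwork
    seed: int | None
    config: dict = field(default_factory=dict)

    # -- presentation -----------------------------------------------------
    def params_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in self.dag.sorted_arcs():
            cpd = self.network.cpds[b]
            rows.append(
                {
                    "from": a,
                    "to": b,
                    "coefficient": cpd.coefficients[a],
                    "effect": "promote" if cpd.coefficients[a] >= 0 else "inhibit",
                    "inclusion_probability": self.final_strengths.strength(a, b),
                    "whitelisted": (a, b) in set(self.whitelist),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "from", "to", "coefficient", "effect",
                "inclusion_probability", "whitelisted",
            ],
        )

    def summary(self) -> str:
        """Human-readable fit summary (arcs, coefficients, inclusion probs)."""
        lines = [
            "Consensus Bayesian network (linear-Gaussian)",
            "=" * 58,
            f"samples: {len(self.model.table)}    nodes: {len(self.dag.nodes)}    "
            f"arcs: {len(self.dag.arcs)}",
            f"ensemble: {', '.join(self.config.get('algorithms', ()))}",
            f"n_boot: {self.config.get('n_boot')}    seed: {self.seed}",
            f"blacklist: {len(self.constraints.blacklist)} arcs    "
            f"consensus whitelist: {len(self.whitelist)} arcs",
            "-" * 58,
            f"{'arc':<34}{'coef':>9}{'effect':>9}{'P(incl)':>8}",
        ]
        for _, row in self.params_frame().iterrows():
            arc = f"{row['from']} -> {row['to']}"
            lines.append(
                f"{arc:<34}{row['coefficient']:>9.3f}{row['effect']:>9}"
                f"{row['inclusion_probability']:>8.2f}"
            )
        lines.append("-" * 58)
        for node in self.dag.topological_order():
            cpd = self.network.cpds[node]
            if not cpd.coefficients:
                kind = self.network.root_kind.get(node, "gaussian")
                lines.append(
                    f"root {node}: mean={cpd.intercept:.3f} sd={cpd.sd:.3f} ({kind})"
                )
        return "\n".join(lines)

    # -- downstream use ---------------------------------------------------
    def simulate(self, n: int = 100_000, seed: int | None = None) -> pd.DataFrame:
        """Logic-sample n joint samples from the fitted network."""
        return logic_sample(self.network, n, seed)

    def query(
        self,
        evidence: Sequence = (),
        report: Sequence[str] = (),
        trend_feature: str | None = None,
        n_samples: int = 100_000,
        seed: int | None = None,
    ):
        """Conditional-probability query via logic sampling with rejection.

        ``evidence`` items may be (feature, op, bound) tuples or strings like
        ``"Cancer<0.05"``.
        """
        parsed = tuple(
            QuerySpec.parse_predicate(e) if isinstance(e, str) else tuple(e)
            for e in evidence
        )
        spec = QuerySpec(parsed, tuple(report), trend_feature, n_samples, seed)
        return conditional_query(self.network, spec, data=self.model.table)

    def quantile_contrast(
        self,
        key_feature: str,
        n_quantiles: int = 5,
        report_features: Sequence[str] | None = None,
    ) -> pd.DataFrame:
        """Top-vs-bottom quantile contrast on the observed data."""
        return quantile_contrast(
            self.model.table, key_feature, n_quantiles, report_features
        )

    def annotated_graph(self) -> dict:
        return annotate_network(self.network, self.final_strengths)
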