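"""Linear-Gaussian Bayesian network: fitting, sampling, and queries.

Given the final DAG, each node is modelled as normally distributed with mean
linear in its parents; parameters come from per-node maximum-likelihood
(ordinary least squares) fits.  The intercept is the average normalized value
of the node with all parents at zero; coefficient signs distinguish promoting
from inhibitory influences.  Binary 0/1 sample-attribute roots (e.g. a
"Cancer" indicator) are sampled from their empirical frequencies rather than
a Gaussian, so that conditional queries filtering on near-0/near-1 evidence
retain mass.

Conditional probability queries use logic sampling: forward ancestral
sampling followed by rejection filtering on the evidence predicates.
"""

from __future__ import annotations

import json
import math
import operator
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .graphs import Arc, Graph
from .stats import _SD_FLOOR, _as_frame, _check_design
from .structure import BootStrengthTable

__all__ = [
    "LinearGaussianCPD",
    "FittedNetwork",
    "QuerySpec",
    "fit_linear_gaussian",
    "logic_sample",
    "conditional_query",
    "quantile_contrast",
    "annotate_network",
]

_OPS = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
    "==": operator.eq,
}


@dataclass(frozen=True)
class LinearGaussianCPD:
    """Node conditional distribution: intercept + linear parent terms + noise."""

    node: str
    intercept: float
    coefficients: Mapping[str, float]
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    def mean(self, parent_values: Mapping[str, np.ndarray]) -> np.ndarray:
        mu = self.intercept
        for p, beta in self.coefficients.items():
            mu = mu + beta * np.asarray(parent_values[p])
        return np.asarray(mu, dtype=float)


@dataclass
class FittedNetwork:
    """DAG plus fitted per-node linear-Gaussian parameters.

    ``root_kind`` records which parentless nodes are 0/1 attributes (sampled
    from their empirical Bernoulli frequency, stored in ``root_p1``).
    """

    dag: Graph
    cpds: dict[str, LinearGaussianCPD]
    root_kind: dict[str, str] = field(default_factory=dict)  # "gaussian"|"bernoulli"
    root_p1: dict[str, float] = field(default_factory=dict)
    arc_strengths: dict[Arc, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.cpds:
                raise ValueError(f"missing CPD for node {node!r}")
            cpd = self.cpds[node]
            if set(cpd.coefficients) != self.dag.parents(node):
                raise ValueError(
                    f"CPD parents of {node!r} do not match the DAG"
                )

    def topological_order(self) -> list[str]:
        return self.dag.topological_order()


def fit_linear_gaussian(dag: Graph, data, attribute_nodes: Iterable[str] | None = None) -> FittedNetwork:
    """Maximum-likelihood fit of a linear-Gaussian model on ``dag``.

    Per node: OLS of the node on its parents with an intercept; the residual
    standard deviation is the MLE (sum of squares divided by n).  Root nodes
    get intercept = sample mean and sd = population sd.  Parentless 0/1
    attribute columns are flagged for empirical Bernoulli sampling.
    """
    if dag.undirected:
        raise ValueError("fit requires a fully directed DAG")
    if not dag.is_acyclic():
        raise ValueError("graph is cyclic")
    frame = _as_frame(data)
    missing = set(dag.nodes) - set(frame.columns)
    if missing:
        raise KeyError(f"DAG nodes absent from data: {sorted(missing)}")
    if attribute_nodes is None:
        attribute_nodes = [
            c
            for c in dag.nodes
            if set(np.unique(frame[c].to_numpy(dtype=float))) <= {0.0, 1.0}
        ]
    attribute_nodes = set(attribute_nodes)
    n = len(frame)
    cpds: dict[str, LinearGaussianCPD] = {}
    root_kind: dict[str, str] = {}
    root_p1: dict[str, float] = {}
    for node in dag.nodes:
        parents = sorted(dag.parents(node))
        y = frame[node].to_numpy(dtype=float)
        if not parents:
            sd = float(y.std())  # population (MLE) sd
            cpds[node] = LinearGaussianCPD(node, float(y.mean()), {}, max(sd, 0.0))
            if node in attribute_nodes:
                root_kind[node] = "bernoulli"
                root_p1[node] = float(y.mean())
            else:
                root_kind[node] = "gaussian"
            continue
        X = frame[parents].to_numpy(dtype=float)
        _check_design(X, parents)
        A = np.column_stack([np.ones(n), X])
        theta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ theta
        sd = math.sqrt(max(float(resid @ resid) / n, _SD_FLOOR**2))
        cpds[node] = LinearGaussianCPD(
            node, float(theta[0]), dict(zip(parents, theta[1:])), sd
        )
    return FittedNetwork(dag.copy(), cpds, root_kind, root_p1)


def logic_sample(net: FittedNetwork, n: int, seed: int | None = None) -> pd.DataFrame:
    """Forward ancestral sampling of ``n`` joint samples (deterministic per seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for node in net.topological_order():
        cpd = net.cpds[node]
        if not cpd.coefficients and net.root_kind.get(node) == "bernoulli":
            cols[node] = (rng.random(n) < net.root_p1[node]).astype(float)
            continue
        mu = cpd.mean(cols) if cpd.coefficients else np.full(n, cpd.intercept)
        noise = rng.normal(0.0, cpd.sd, n) if cpd.sd > 0 else 0.0
        cols[node] = mu + noise
    return pd.DataFrame({node: cols[node] for node in net.dag.nodes})


@dataclass(frozen=True)
class QuerySpec:
    """A conditional-probability query over the fitted network.

    ``evidence`` is a list of (feature, comparator, bound) predicates, e.g.
    ``("Cancer", "<", 0.05)``; samples failing any predicate are rejected.
    """

    evidence: tuple[tuple[str, str, float], ...] = ()
    report: tuple[str, ...] = ()
    trend_feature: str | None = None
    n_samples: int = 100_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        object.__setattr__(self, "evidence", tuple(tuple(e) for e in self.evidence))
        object.__setattr__(self, "report", tuple(self.report))
        for feat, op, bound in self.evidence:
            if op not in _OPS:
                raise ValueError(f"unknown comparator {op!r}; use {sorted(_OPS)}")
            float(bound)

    @staticmethod
    def parse_predicate(text: str) -> tuple[str, str, float]:
        """Parse ``"Cancer<0.05"``-style predicate strings."""
        for op in ("<=", ">=", "==", "<", ">"):
            if op in text:
                feat, bound = text.split(op, 1)
                return feat.strip(), op, float(bound)
        raise ValueError(f"cannot parse predicate {text!r}")


class EmptyEvidenceError(RuntimeError):
    """Raised when rejection filtering leaves no surviving samples."""


def conditional_query(
    net: FittedNetwork, spec: QuerySpec, data=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Logic-sampling conditional query: filtered samples + summary table.

    Samples are drawn forward, then rejected against all evidence predicates.
    The summary reports per feature the conditional mean, sd, survivor count
    and the least-squares trend slope against the trend feature (computed on
    the surviving samples; if ``data`` is given, the same slope on the
    observed data is reported alongside).
    """
    unknown = {f for f, _, _ in spec.evidence} - set(net.dag.nodes)
    if unknown:
        raise KeyError(f"evidence references unknown node(s): {sorted(unknown)}")
    samples = logic_sample(net, spec.n_samples, spec.seed)
    mask = np.ones(len(samples), dtype=bool)
    for feat, op, bound in spec.evidence:
        mask &= _OPS[op](samples[feat].to_numpy(), float(bound))
    survivors = samples.loc[mask].reset_index(drop=True)
    if len(survivors) == 0:
        raise EmptyEvidenceError(
            f"no samples satisfy evidence {spec.evidence}; query is empty"
        )
    if len(survivors) < 100:
        warnings.warn(
            f"only {len(survivors)} samples satisfy the evidence; "
            "summary statistics are unstable",
            stacklevel=2,
        )
    report = list(spec.report) or [c for c in samples.columns]
    rows = []
    trend = spec.trend_feature
    for feat in report:
        row = {
            "feature": feat,
            "mean": float(survivors[feat].mean()),
            "sd": float(survivors[feat].std(ddof=0)),
            "n": int(len(survivors)),
        }
        if trend and feat != trend:
            row["trend_slope"] = _slope(survivors[trend], survivors[feat])
            if data is not None:
                frame = _as_frame(data)
                row["trend_slope_data"] = _slope(frame[trend], frame[feat])
        rows.append(row)
    return survivors, pd.DataFrame(rows).set_index("feature")


def _slope(x: pd.Series, y: pd.Series) -> float:
    x = x.to_numpy(dtype=float)
    y = y.to_numpy(dtype=float)
    vx = x.var()
    if vx == 0:
        return float("nan")
    return float(np.cov(x, y, bias=True)[0, 1] / vx)


def quantile_contrast(
    data,
    key_feature: str,
    n_quantiles: int = 5,
    report_features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Top-vs-bottom quantile contrast of feature means.

    Samples are ranked by ``key_feature`` (stable order breaks ties) and split
    into ``n_quantiles`` groups whose sizes differ by at most one.  For each
    report feature the difference Delta = mean(top) - mean(bottom) is returned
    with the per-group means and sizes — emulating a knock-out (bottom
    quantile) versus wild-type (top quantile) comparison of expression.
    """
    frame = _as_frame(data)
    if n_quantiles < 2:
        raise ValueError("n_quantiles must be >= 2")
    key = frame[key_feature].to_numpy(dtype=float)
    if np.ptp(key) == 0:
        raise ValueError(f"all values of {key_feature!r} identical; no quantiles")
    if len(frame) < n_quantiles:
        raise ValueError("fewer samples than quantiles")
    order = np.argsort(key, kind="stable")
    groups = np.array_split(order, n_quantiles)
    bottom, top = groups[0], groups[-1]
    report = list(report_features or frame.columns)
    rows = []
    for feat in report:
        v = frame[feat].to_numpy(dtype=float)
        rows.append(
            {
                "feature": feat,
                "mean_bottom": float(v[bottom].mean()),
                "mean_top": float(v[top].mean()),
                "delta": float(v[top].mean() - v[bottom].mean()),
                "n_bottom": int(len(bottom)),
                "n_top": int(len(top)),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def annotate_network(net: FittedNetwork, strengths: BootStrengthTable) -> dict:
    """Annotated-graph document: per-arc coefficient, sign, inclusion probability.

    Every arc must be covered by the strength table; edge width in a drawing
    is proportional to the inclusion probability, the sign tags promoting
    versus inhibitory influence, and each node carries its intercept
    (its average value with all parents at zero).
    """
    arcs = []
    for a, b in net.dag.sorted_arcs():
        s = strengths.strength(a, b)
        if frozenset((a, b)) not in strengths._by_pair:
            raise KeyError(f"no bootstrap strength recorded for arc {a}->{b}")
        beta = net.cpds[b].coefficients[a]
        arcs.append(
            {
                "from": a,
                "to": b,
                "coefficient": float(beta),
                "effect": "promote" if beta >= 0 else "inhibit",
                "inclusion_probability": float(s),
            }
        )
    nodes = []
    for node in net.dag.nodes:
        cpd = net.cpds[node]
        nodes.append(
            {
                "node": node,
                "intercept": float(cpd.intercept),
                "residual_sd": float(cpd.sd),
                "kind": net.root_kind.get(node, "gaussian"),
            }
        )
    return {"nodes": nodes, "arcs": arcs}


def annotated_to_json(doc: dict) -> str:
    return json.dumps(doc, indent=2, sort_keys=True)


def annotated_from_json(text: str) -> dict:
    return json.loads(text)
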