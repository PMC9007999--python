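"""Statistical kernel for structure learning and arc assessment.

Two quantities drive everything:

* the *exact t-test* on a partial Pearson correlation — the conditional
  independence test used by the constraint-based learners and the "edge
  strength" p-value reported for arcs ("given the rest of the network" means
  conditioning on the child's other parents);
* Gaussian local scores — the standard Gaussian BIC used by the score-based
  search, and a node-level L1-BIC, ``BIC_j = n_arcs * log10(n_obs) +
  sum_i |Yhat_ij - Y_ij|``, used to pick the whitelist trade-off between
  regression accuracy and model complexity.

All computations run on an immutable snapshot of the data matrix; the
``CITester`` / ``GaussianScorer`` classes precompute the Gram matrix once so
that each local quantity is a small linear solve, which is what makes
bootstrap ensembles affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special as spsp

from .graphs import Arc, Graph

__all__ = [
    "ArcSignificanceRecord",
    "NodeBicRecord",
    "partial_correlation",
    "exact_t_pvalue",
    "gaussian_score",
    "node_l1_bic",
    "arc_significance",
    "CITester",
    "DiscreteCITester",
    "GaussianScorer",
]

_TINY_P = float(np.nextafter(0.0, 1.0))
_SD_FLOOR = 1e-12  # zero-variance guard for noiseless fixtures


@dataclass(frozen=True)
class ArcSignificanceRecord:
    """Edge-strength record: partial correlation and its exact-t p-value."""

    arc: Arc
    r: float
    cond_size: int
    n_obs: int
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")
        if abs(self.r) > 1.0 + 1e-9:
            raise ValueError(f"|r| > 1: {self.r}")
        if self.n_obs - self.cond_size - 2 < 1:
            raise ValueError("insufficient degrees of freedom")


@dataclass(frozen=True)
class NodeBicRecord:
    """Node-level L1-BIC: complexity penalty plus absolute regression loss."""

    node: str
    parents: tuple[str, ...]
    n_arcs: int
    n_obs: int
    l1_loss: float
    bic: float


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    # FeatureTable duck-typing
    frame = getattr(data, "data", None)
    if isinstance(frame, pd.DataFrame):
        return frame
    raise TypeError(f"expected DataFrame or FeatureTable, got {type(data)!r}")


def _check_design(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise on a singular conditioning design, naming the collinear columns."""
    if X.shape[1] == 0:
        return
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc, tol=1e-10 * max(1.0, float(np.abs(Xc).max())))
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular conditioning design; collinear/constant columns among {list(names)}"
        )


def partial_correlation(data, x: str, y: str, Z: Iterable[str] = ()) -> float:
    """Partial Pearson correlation of ``x`` and ``y`` given columns ``Z``.

    Equals the Pearson correlation of the residuals of ``x`` and ``y`` after
    least-squares projection onto ``Z`` plus an intercept.
    """
    frame = _as_frame(data)
    Z = list(Z)
    n = len(frame)
    if n <= len(Z) + 2:
        raise ValueError(f"need n_obs > |Z| + 2 (n={n}, |Z|={len(Z)})")
    cols = [x, y, *Z]
    M = frame[cols].to_numpy(dtype=float)
    for name, col in zip((x, y), M[:, :2].T):
        if np.ptp(col) == 0:
            raise np.linalg.LinAlgError(f"column {name!r} is constant")
    _check_design(M[:, 2:], Z)
    S = np.cov(M, rowvar=False, bias=True)
    S = np.atleast_2d(S)
    if Z:
        Szz = S[2:, 2:]
        Sxz = S[:2, 2:]
        beta = np.linalg.solve(Szz, Sxz.T)  # (|Z|, 2)
        cond = S[:2, :2] - Sxz @ beta
    else:
        cond = S[:2, :2]
    denom = math.sqrt(max(cond[0, 0], 0.0) * max(cond[1, 1], 0.0))
    if denom <= _SD_FLOOR**2:
        raise np.linalg.LinAlgError(
            f"residual variance of {x!r} or {y!r} vanishes given {Z}"
        )
    return float(np.clip(cond[0, 1] / denom, -1.0, 1.0))


def exact_t_pvalue(r: float, n_obs: int, cond_size: int = 0) -> float:
    """Two-sided p-value of the exact t-test for a (partial) correlation.

    ``t = r * sqrt(df) / sqrt(1 - r^2)`` with ``df = n_obs - cond_size - 2``.
    ``|r| = 1`` underflows to the smallest positive float rather than zero.
    """
    df = n_obs - cond_size - 2
    if df < 1:
        raise ValueError(f"df = n_obs - cond_size - 2 = {df} < 1")
    r = min(max(float(r), -1.0), 1.0)
    if abs(r) >= 1.0:
        return _TINY_P
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    p = 2.0 * float(spsp.stdtr(df, -abs(t)))  # Student-t survival, C fast path
    return min(max(p, _TINY_P), 1.0)


def gaussian_score(node: str, parents: Sequence[str], data, score_kind: str = "bic") -> float:
    """Decomposable Gaussian local score of ``node`` given ``parents``.

    Profiled Gaussian log-likelihood minus a BIC penalty ``(k/2) ln(n_obs)``
    with ``k = |parents| + 2`` (intercept and residual variance).  Higher is
    better; the network score is the sum of local scores.
    """
    if score_kind not in ("bic", "loglik"):
        raise ValueError(f"unknown score_kind {score_kind!r}")
    frame = _as_frame(data)
    scorer = GaussianScorer(frame)
    return scorer.local_score(node, tuple(parents), penalized=score_kind == "bic")


def _ols_fit(frame: pd.DataFrame, node: str, parents: Sequence[str]):
    """Least-squares fit of node on parents + intercept; returns (yhat, coef, icept)."""
    y = frame[node].to_numpy(dtype=float)
    if not parents:
        return np.full_like(y, y.mean()), np.zeros(0), float(y.mean())
    X = frame[list(parents)].to_numpy(dtype=float)
    _check_design(X, parents)
    A = np.column_stack([np.ones(len(y)), X])
    theta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return A @ theta, theta[1:], float(theta[0])


def node_l1_bic(node: str, parents: Sequence[str], data) -> NodeBicRecord:
    """Node-level L1-BIC of ``node`` given ``parents``.

    The loss is the summed absolute difference between the least-squares
    prediction and the observation; the penalty is ``n_arcs * log10(n_obs)``.
    With no parents the prediction is the sample mean.
    """
    frame = _as_frame(data)
    parents = tuple(parents)
    yhat, _, _ = _ols_fit(frame, node, parents)
    y = frame[node].to_numpy(dtype=float)
    l1 = float(np.abs(yhat - y).sum())
    n = len(frame)
    bic = len(parents) * math.log10(n) + l1
    return NodeBicRecord(node, parents, len(parents), n, l1, bic)


def arc_significance(dag: Graph, arc: Arc, data) -> ArcSignificanceRecord:
    """Edge strength of ``arc`` within ``dag``: partial correlation of the two
    endpoints given the child's other parents, with its exact-t p-value."""
    a, b = arc
    if (a, b) not in dag.arcs:
        raise ValueError(f"arc {a}->{b} not in graph")
    Z = sorted(dag.parents(b) - {a})
    frame = _as_frame(data)
    r = partial_correlation(frame, a, b, Z)
    p = exact_t_pvalue(r, len(frame), len(Z))
    return ArcSignificanceRecord((a, b), r, len(Z), len(frame), p)


# ---------------------------------------------------------------------------
# Gram-matrix backed fast paths


class _GramBase:
    def __init__(self, frame: pd.DataFrame) -> None:
        self.columns = list(frame.columns)
        self.index = {c: i for i, c in enumerate(self.columns)}
        M = frame.to_numpy(dtype=float)
        self.n = M.shape[0]
        self.S = np.cov(M, rowvar=False, bias=True)  # MLE covariance
        self.S = np.atleast_2d(self.S)


class CITester(_GramBase):
    """Cached partial-correlation exact-t tests on one dataset snapshot."""

    def __init__(self, frame: pd.DataFrame) -> None:
        super().__init__(frame)
        self._cache: dict[tuple, tuple[float, float]] = {}

    def test(self, x: str, y: str, Z: Iterable[str] = ()) -> tuple[float, float]:
        """Return (r, p) for x ⟂ y | Z."""
        Z = tuple(sorted(Z))
        key = (x, y, Z) if x < y else (y, x, Z)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        S = self.S
        ix, iy = self.index[x], self.index[y]
        nz = len(Z)
        if nz == 0:
            sxx, syy, sxy = S[ix, ix], S[iy, iy], S[ix, iy]
        elif nz == 1:
            # closed form: condition on a single variable
            iz = self.index[Z[0]]
            szz = S[iz, iz]
            if szz <= _SD_FLOOR**2:
                sxx, syy, sxy = S[ix, ix], S[iy, iy], S[ix, iy]
            else:
                sxz, syz = S[ix, iz], S[iy, iz]
                sxx = S[ix, ix] - sxz * sxz / szz
                syy = S[iy, iy] - syz * syz / szz
                sxy = S[ix, iy] - sxz * syz / szz
        else:
            iz = [self.index[z] for z in Z]
            Szz = S[iz][:, iz]
            Sxz = S[[ix, iy]][:, iz]
            try:
                beta = np.linalg.solve(Szz, Sxz.T)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(Szz, Sxz.T, rcond=None)[0]
            cond = S[[ix, iy]][:, [ix, iy]] - Sxz @ beta
            sxx, sxy, syy = cond[0, 0], cond[0, 1], cond[1, 1]
        denom = math.sqrt(max(sxx, 0.0) * max(syy, 0.0))
        if denom <= _SD_FLOOR**2:
            r = 0.0  # degenerate residuals carry no evidence of dependence
        else:
            r = min(max(float(sxy) / denom, -1.0), 1.0)
        df = self.n - nz - 2
        p = exact_t_pvalue(r, self.n, nz) if df >= 1 else 1.0
        self._cache[key] = (r, p)
        return r, p

    def pvalue(self, x: str, y: str, Z: Iterable[str] = ()) -> float:
        return self.test(x, y, Z)[1]

    def max_cond_size(self) -> int:
        return max(self.n - 3, 0)


class GaussianScorer(_GramBase):
    """Cached Gaussian-BIC local scores on one dataset snapshot."""

    def __init__(self, frame: pd.DataFrame) -> None:
        super().__init__(frame)
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}
        self._lodet = -0.5 * self.n * (math.log(2.0 * math.pi) + 1.0)

    def residual_variance(self, node: str, parents: tuple[str, ...]) -> float:
        j = self.index[node]
        if not parents:
            var = self.S[j, j]
        else:
            idx = [self.index[p] for p in parents]
            Spp = self.S[np.ix_(idx, idx)]
            Sjp = self.S[j, idx]
            try:
                var = self.S[j, j] - Sjp @ np.linalg.solve(Spp, Sjp)
            except np.linalg.LinAlgError:
                var = self.S[j, j] - Sjp @ np.linalg.lstsq(Spp, Sjp, rcond=None)[0]
        return max(float(var), _SD_FLOOR**2)

    def local_score(self, node: str, parents: Iterable[str], penalized: bool = True) -> float:
        parents = tuple(sorted(parents))
        key = (node, parents)
        hit = self._cache.get(key)
        if hit is None:
            var = self.residual_variance(node, parents)
            loglik = self._lodet - 0.5 * self.n * math.log(var)
            hit = loglik
            self._cache[key] = hit
        if penalized:
            k = len(parents) + 2
            return hit - 0.5 * k * math.log(self.n)
        return hit

    def network_score(self, dag: Graph) -> float:
        return sum(self.local_score(n, dag.parents(n)) for n in dag.nodes)


class DiscreteCITester:
    """Conditional-independence G-test for integer-coded (discretized) data.

    The statistic is twice the sample size times the conditional mutual
    information, ``G = 2 * sum n_xyz * ln(n_xyz * n_z / (n_xz * n_yz))``,
    referred to a chi-square law with ``(|X|-1) * (|Y|-1) * prod|Z|`` degrees
    of freedom.  Used by the constraint-based and local-discovery learners
    when the analysis runs on the discretized variant of the feature table.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        self.columns = list(frame.columns)
        self.index = {c: i for i, c in enumerate(self.columns)}
        M = frame.to_numpy()
        if not np.allclose(M, np.round(M)):
            raise ValueError("discrete test expects integer-coded data")
        self.codes = M.astype(int)
        self.n = self.codes.shape[0]
        self.card = [int(self.codes[:, j].max()) + 1 for j in range(self.codes.shape[1])]
        self._cache: dict[tuple, tuple[float, float]] = {}

    def test(self, x: str, y: str, Z: Iterable[str] = ()) -> tuple[float, float]:
        """Return (G statistic, p-value) for x independent of y given Z."""
        Z = tuple(sorted(Z))
        key = (x, y, Z) if x < y else (y, x, Z)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        ix, iy = self.index[x], self.index[y]
        iz = [self.index[z] for z in Z]
        cx, cy = self.card[ix], self.card[iy]
        # stratum id per sample from the conditioning codes
        if iz:
            strata = np.zeros(self.n, dtype=np.int64)
            for j in iz:
                strata = strata * self.card[j] + self.codes[:, j]
            n_strata = 1
            for j in iz:
                n_strata *= self.card[j]
        else:
            strata = np.zeros(self.n, dtype=np.int64)
            n_strata = 1
        flat = (strata * cx + self.codes[:, ix]) * cy + self.codes[:, iy]
        counts = np.bincount(flat, minlength=n_strata * cx * cy).reshape(
            n_strata, cx, cy
        )
        nz = counts.sum(axis=(1, 2), keepdims=True)
        nxz = counts.sum(axis=2, keepdims=True)
        nyz = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = counts * nz / (nxz * nyz)
            terms = np.where(counts > 0, counts * np.log(ratio), 0.0)
        g = 2.0 * float(terms.sum())
        df = (cx - 1) * (cy - 1) * n_strata
        p = float(spsp.chdtrc(df, max(g, 0.0))) if df > 0 else 1.0
        out = (g, min(max(p, _TINY_P), 1.0))
        self._cache[key] = out
        return out

    def pvalue(self, x: str, y: str, Z: Iterable[str] = ()) -> float:
        return self.test(x, y, Z)[1]

    def max_cond_size(self) -> int:
        return max(self.n - 3, 0)
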