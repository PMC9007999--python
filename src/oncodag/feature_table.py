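"""Sample x feature tables of digital-cytometry outputs and sample attributes.

Rows are tissue samples; columns are continuous cell-level features (cell
prevalence scores, state metrics, oncogene expression) plus 0/1-coded sample
attributes such as "Cancer".  Upstream deconvolution is out of scope — this
module consumes its output table, validates it, converts macrophage subset
scores into functional-orientation probabilities, applies the log /[0,1]
normalization used before network inference, and profiles zero inflation to
suggest leaf nodes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "MacrophageFractions",
    "PreprocessConfig",
    "macrophage_orientation",
    "preprocess",
    "discretize",
    "zero_profile",
]

CONTINUOUS = "continuous"
ATTRIBUTE01 = "attribute01"


@dataclass(frozen=True)
class PreprocessConfig:
    """Normalization settings applied before network inference.

    log_offset
        Added before the log so zero prevalence scores stay finite (and, with
        offset 1, stay at zero).
    log_base
        Base of the log transform (the min-max step makes the choice
        immaterial for downstream correlations; kept configurable).
    n_intervals
        Number of equal-width bins when ``discretize`` is set; the reference
        analyses used 15 (large cohort) or 6 (small cohorts).
    zero_leaf_fraction
        Features whose exact-zero fraction reaches this value are *suggested*
        as leaf nodes (roles remain user-confirmed).
    """

    log_offset: float = 1.0
    log_base: float = 10.0
    discretize: bool = False
    n_intervals: int | None = None
    zero_leaf_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.log_offset <= 0:
            raise ValueError("log_offset must be positive")
        if self.discretize and (self.n_intervals is None or self.n_intervals < 2):
            raise ValueError("discretize=True requires n_intervals >= 2")
        if not (0 < self.zero_leaf_fraction <= 1):
            raise ValueError("zero_leaf_fraction must lie in (0, 1]")


@dataclass
class FeatureTable:
    """Validated samples x features matrix with per-column kind metadata."""

    data: pd.DataFrame
    kinds: Mapping[str, str] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        na = df.isna()
        if na.to_numpy().any():
            row, col = next(zip(*np.nonzero(na.to_numpy())))
            raise ValueError(
                f"missing value at sample {df.index[row]!r}, feature {df.columns[col]!r}"
            )
        if not all(np.issubdtype(t, np.number) for t in df.dtypes):
            bad = [c for c, t in df.dtypes.items() if not np.issubdtype(t, np.number)]
            raise ValueError(f"non-numeric feature column(s): {bad}")
        kinds = dict(self.kinds)
        for col in df.columns:
            kinds.setdefault(
                col,
                ATTRIBUTE01
                if set(np.unique(df[col].to_numpy())) <= {0.0, 1.0}
                else CONTINUOUS,
            )
        unknown = set(kinds) - set(df.columns)
        if unknown:
            raise ValueError(f"kinds reference unknown feature(s): {sorted(unknown)}")
        for col, kind in kinds.items():
            if kind == ATTRIBUTE01:
                vals = set(np.unique(df[col].to_numpy()))
                if not vals <= {0.0, 1.0}:
                    raise ValueError(
                        f"attribute column {col!r} contains values outside {{0,1}}"
                    )
            elif kind != CONTINUOUS:
                raise ValueError(f"unknown column kind {kind!r} for {col!r}")
        self.kinds = kinds

    # -- convenience ------------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def continuous_features(self) -> list[str]:
        return [c for c in self.data.columns if self.kinds[c] == CONTINUOUS]

    def attribute_features(self) -> list[str]:
        return [c for c in self.data.columns if self.kinds[c] == ATTRIBUTE01]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, kinds: Mapping[str, str] | None = None, normalized: bool = False
    ) -> "FeatureTable":
        return cls(df.copy(), dict(kinds or {}), normalized)

    @classmethod
    def from_csv(
        cls, path: str | Path, kinds: Mapping[str, str] | None = None, sep: str | None = None
    ) -> "FeatureTable":
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except ValueError as exc:
            raise ValueError(f"malformed feature table {path}: {exc}") from exc
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = coerced.isna() & df[col].notna()
                if bad.any():
                    row = df.index[bad.to_numpy().nonzero()[0][0]]
                    raise ValueError(
                        f"non-numeric cell at sample {row!r}, feature {col!r} in {path}"
                    )
                df[col] = coerced
        return cls(df, dict(kinds or {}))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class MacrophageFractions:
    """Per-sample prevalence scores of the M0/M1/M2 macrophage subsets."""

    m0: np.ndarray
    m1: np.ndarray
    m2: np.ndarray

    def __post_init__(self) -> None:
        arrs = {}
        for name in ("m0", "m1", "m2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"negative {name} prevalence score")
            arrs[name] = arr
        if len({a.shape for a in arrs.values()}) != 1:
            raise ValueError("m0, m1, m2 must have identical length")
        for name, arr in arrs.items():
            object.__setattr__(self, name, arr)


def macrophage_orientation(
    fractions: MacrophageFractions,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Probability of the average macrophage functional orientation.

    ``p(MPhi_i) = MPhi_i / (MPhi_0 + MPhi_1 + MPhi_2)``; the three outputs sum
    to one per sample.  Samples with all three scores zero are degenerate:
    they yield NaN in all three outputs and a warning listing their positions.
    """
    total = fractions.m0 + fractions.m1 + fractions.m2
    degenerate = total == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} sample(s) with zero total macrophage signal "
            f"at positions {np.nonzero(degenerate)[0].tolist()}; "
            "orientation probabilities set to NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        safe_total = np.where(degenerate, np.nan, total)
        p0 = fractions.m0 / safe_total
        p1 = fractions.m1 / safe_total
        p2 = fractions.m2 / safe_total
    return p0, p1, p2


def preprocess(table: FeatureTable, cfg: PreprocessConfig | None = None) -> FeatureTable:
    """Log-transform and min-max normalize continuous columns to [0, 1].

    Each continuous column is mapped ``x -> log_base(x + log_offset)`` and then
    rescaled so its minimum is 0 and maximum 1.  Attribute columns pass through
    unchanged.  Constant columns map to all-zero with a warning.  The result
    carries a provenance flag so the pipeline cannot normalize twice.
    """
    cfg = cfg or PreprocessConfig()
    if table.normalized:
        raise ValueError("table is already normalized (provenance flag set)")
    df = table.data.copy()
    for col in table.continuous_features():
        x = df[col].to_numpy(dtype=float)
        if np.any(x < 0):
            raise ValueError(f"continuous feature {col!r} has negative values")
        x = np.log(x + cfg.log_offset) / math.log(cfg.log_base)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(f"constant feature {col!r} mapped to all-zero", stacklevel=2)
            df[col] = np.zeros_like(x)
        else:
            df[col] = (x - lo) / (hi - lo)
    out = FeatureTable(df, dict(table.kinds), normalized=True)
    return out


def discretize(table: FeatureTable, n_intervals: int) -> FeatureTable:
    """Code [0,1]-normalized continuous columns into equal-width intervals.

    Codes run 0 .. n_intervals-1; the value 1.0 falls in the top interval.
    """
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    if not table.normalized:
        raise ValueError("discretize expects a normalized table (run preprocess first)")
    df = table.data.copy()
    for col in table.continuous_features():
        x = df[col].to_numpy(dtype=float)
        if x.min() < 0 or x.max() > 1:
            raise ValueError(f"feature {col!r} outside [0,1]; normalize first")
        codes = np.minimum((x * n_intervals).astype(int), n_intervals - 1)
        df[col] = codes
    return replace(table, data=df)


def zero_profile(
    table: FeatureTable, zero_leaf_fraction: float = 0.5
) -> pd.DataFrame:
    """Exact-zero counts per feature and suggested leaf designations.

    Features whose zero fraction reaches ``zero_leaf_fraction`` (boundary
    inclusive) are suggested as leaves; 0/1 attribute columns are profiled but
    never suggested (their zeros encode a category, not absence).  The
    suggestion is advisory — node roles remain user-confirmed.
    """
    rows = []
    n = len(table)
    for col in table.feature_names:
        zeros = int((table.data[col].to_numpy() == 0).sum())
        frac = zeros / n if n else 0.0
        rows.append(
            {
                "feature": col,
                "zero_count": zeros,
                "zero_fraction": frac,
                "suggested_leaf": bool(
                    table.kinds[col] == CONTINUOUS and frac >= zero_leaf_fraction
                ),
            }
        )
    return pd.DataFrame(rows).set_index("feature")
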