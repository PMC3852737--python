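"""NODF nestedness of a binary incidence matrix, with null-model tests.

NODF (Nestedness metric based on Overlap and Decreasing Fill) scores, for
every pair of rows and every pair of columns whose marginal totals differ,
the percentage of the sparser line's presences that are shared with the
denser line; pairs with equal totals contribute zero.  The score is the
mean over all row pairs and column pairs, in [0, 100].  A perfectly nested
matrix — every sparser line a subset of every denser one, all fills
distinct — scores 100; a checkerboard scores 0.

Significance is assessed against two standard randomizations: an
equiprobable null (every cell 1 with probability fill/(R*C)) and a
degree-proportional null where cell (i, j) is 1 with probability
(k_i/C + k_j/R)/2, preserving expected marginals (the "Ce"-style null
commonly used for pollination networks).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .types import BipartiteNetwork

NULL_MODELS = ("equiprobable", "degree_proportional")


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary pollinator-by-plant incidence matrix with labelled margins."""

    rows: tuple[str, ...]  # pollinator ids
    cols: tuple[str, ...]  # plant ids
    values: np.ndarray  # shape (len(rows), len(cols)), 0/1

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.rows), len(self.cols)):
            raise DataError(
                f"matrix shape {v.shape} does not match labels "
                f"({len(self.rows)} rows, {len(self.cols)} cols)"
            )
        if v.size and not np.isin(v, (0, 1)).all():
            raise DataError("incidence matrix must be binary")
        object.__setattr__(self, "values", v.astype(np.int8))

    @property
    def fill(self) -> int:
        return int(self.values.sum())

    @classmethod
    def from_network(cls, net: BipartiteNetwork) -> "IncidenceMatrix":
        rows = tuple(sorted(net.pollinators))
        cols = tuple(sorted(net.plants))
        ridx = {r: i for i, r in enumerate(rows)}
        cidx = {c: j for j, c in enumerate(cols)}
        v = np.zeros((len(rows), len(cols)), dtype=np.int8)
        for p, a in net.links:
            v[ridx[a], cidx[p]] = 1
        return cls(rows, cols, v)

    @classmethod
    def from_csv(cls, source: Union[str, Path]) -> "IncidenceMatrix":
        df = pd.read_csv(source, index_col=0)
        try:
            vals = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ConfigurationError(f"matrix CSV is not numeric: {exc}") from None
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), vals.astype(int))

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(self.values, index=list(self.rows), columns=list(self.cols)).to_csv(path)


def sort_matrix(m: IncidenceMatrix) -> IncidenceMatrix:
    """Sort rows and columns into canonical nested display order.

    Lines are ordered by descending marginal total (linkage level L) from
    the upper-left corner; lines of equal total are ordered by increasing
    mean L of their interacting partners; remaining ties keep input order.
    """
    if m.values.size == 0:
        raise DataError("cannot sort an empty matrix")
    v = m.values.astype(float)
    row_fill, col_fill = v.sum(axis=1), v.sum(axis=0)

    def order(fills: np.ndarray, partner_fills: np.ndarray, lines: np.ndarray) -> list[int]:
        keys = []
        for i, line in enumerate(lines):
            k = fills[i]
            mean_partner = (line @ partner_fills) / k if k > 0 else np.inf
            keys.append((-k, mean_partner, i))
        return sorted(range(len(keys)), key=keys.__getitem__)

    r_order = order(row_fill, col_fill, v)
    c_order = order(col_fill, row_fill, v.T)
    return IncidenceMatrix(
        tuple(m.rows[i] for i in r_order),
        tuple(m.cols[j] for j in c_order),
        m.values[np.ix_(r_order, c_order)],
    )


def _axis_contribution(a: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap terms over all unordered line pairs of one axis."""
    n = a.shape[0]
    if n < 2:
        return 0.0, 0
    k = a.sum(axis=1)
    overlap = a @ a.T
    kmin = np.minimum.outer(k, k)
    valid = (k[:, None] != k[None, :]) & (kmin > 0)
    terms = np.where(valid, 100.0 * overlap / np.maximum(kmin, 1), 0.0)
    iu = np.triu_indices(n, 1)
    return float(terms[iu].sum()), n * (n - 1) // 2


def nodf(m: IncidenceMatrix, *, allow_degenerate: bool = False) -> float:
    """NODF score in [0, 100]; invariant to input row/column order.

    With ``allow_degenerate=False`` (the default) a matrix with fewer than
    two rows or columns, or with no presences, raises :class:`DataError`.
    Null-model replicates may legitimately contain empty lines; scoring
    them uses ``allow_degenerate=True``, under which empty or equal-fill
    lines simply contribute zero.
    """
    a = m.values.astype(np.float64)
    if not allow_degenerate:
        if a.shape[0] < 2 or a.shape[1] < 2:
            raise DataError(f"NODF needs >= 2 rows and columns, got shape {a.shape}")
        if a.sum() == 0:
            raise DataError("NODF undefined for an all-zero matrix")
    rsum, rpairs = _axis_contribution(a)
    csum, cpairs = _axis_contribution(a.T)
    npairs = rpairs + cpairs
    if npairs == 0:
        if allow_degenerate:
            return 0.0
        raise DataError("NODF undefined: no line pairs")
    return (rsum + csum) / npairs


# ---------------------------------------------------------------------------
# Null models and significance
# ---------------------------------------------------------------------------

def null_probabilities(m: IncidenceMatrix, model: str) -> np.ndarray:
    """Cell-presence probability matrix of a null model."""
    if model not in NULL_MODELS:
        raise ConfigurationError(f"unknown null model {model!r}; choose from {NULL_MODELS}")
    a = m.values.astype(float)
    r, c = a.shape
    if model == "equiprobable":
        return np.full((r, c), a.sum() / (r * c))
    k_row = a.sum(axis=1)  # pollinator degrees
    k_col = a.sum(axis=0)  # plant degrees
    return np.clip((k_row[:, None] / c + k_col[None, :] / r) / 2.0, 0.0, 1.0)


def null_matrix(
    m: IncidenceMatrix,
    model: str = "degree_proportional",
    rng: Optional[np.random.Generator] = None,
) -> IncidenceMatrix:
    """One random matrix from the chosen null model (same shape and labels)."""
    rng = np.random.default_rng() if rng is None else rng
    p = null_probabilities(m, model)
    return IncidenceMatrix(m.rows, m.cols, (rng.random(p.shape) < p).astype(np.int8))


@dataclass(frozen=True)
class NestednessResult:
    """Observed NODF against a Monte Carlo null distribution."""

    nodf: float
    null_model: str
    n_reps: int
    null_mean: float
    null_sd: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "nodf": self.nodf,
            "null_model": self.null_model,
            "n_reps": self.n_reps,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_value,
        }


def nodf_significance(
    m: IncidenceMatrix,
    model: str = "degree_proportional",
    n_reps: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> NestednessResult:
    """Monte Carlo significance of NODF against a null model.

    p = (1 + #{null NODF >= observed}) / (n_reps + 1), the add-one
    permutation-style correction, so p is never exactly zero.  Degenerate
    null replicates (empty lines) are retained and scored leniently;
    dropping them would bias the null.
    """
    if n_reps < 100:
        raise ConfigurationError(f"n_reps must be >= 100, got {n_reps}")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = nodf(m)
    p = null_probabilities(m, model)
    scores = np.empty(n_reps)
    for i in range(n_reps):
        null = IncidenceMatrix(m.rows, m.cols, (rng.random(p.shape) < p).astype(np.int8))
        scores[i] = nodf(null, allow_degenerate=True)
    p_value = (1 + int(np.sum(scores >= observed))) / (n_reps + 1)
    return NestednessResult(
        nodf=observed,
        null_model=model,
        n_reps=n_reps,
        null_mean=float(scores.mean()),
        null_sd=float(scores.std(ddof=1)),
        p_value=p_value,
    )
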