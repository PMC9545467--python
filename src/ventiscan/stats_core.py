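"""Spearman and partial Spearman rank correlation with significance tests.

The partial Spearman correlation between two variables ``x`` and ``y`` given a
covariate matrix ``Z`` is defined here as the Pearson correlation between the
residuals of the *ranks* of ``x`` and of ``y`` after ordinary least-squares
regression on an intercept plus the ranks of the covariate columns.  Ties are
handled with midranks throughout, so with no covariates the statistic reduces
exactly to the usual Spearman coefficient ("Pearson on ranks").

Significance uses the standard partial-correlation t test::

    t = rho * sqrt((n - 2 - k) / (1 - rho**2))     on  n - 2 - k  df

two-sided, where ``k`` is the number of covariates.  A perfectly monotone
relation (|rho| = 1) gets p = 0.  The test is two-sided because the detection
rule that consumes it supplies directionality separately through its positive
threshold on rho.

An independent precision-matrix route is also provided (invert the Spearman
correlation matrix of ``[x, y, Z]``; the partial coefficient is
``-Omega_12 / sqrt(Omega_11 * Omega_22)``).  The two routes agree to floating
precision on every non-degenerate instance, which the test suite exploits.

Rank invariance: because only ranks enter, the result is exactly invariant
under any strictly increasing transform of ``x``, ``y``, or any covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import IllConditionedError, UndefinedCorrelationError

__all__ = [
    "RankVector",
    "PartialCorrResult",
    "rank_transform",
    "spearman",
    "partial_spearman",
]

# Relative tolerance below which a residual sum of squares is treated as zero
# (e.g. y identical to a covariate): scaled to the centred rank variance.
_ZERO_RSS_RTOL = 1e-10


@dataclass(frozen=True)
class RankVector:
    """Midranks (1..n, average ties) of a numeric vector."""

    ranks: np.ndarray
    n: int


@dataclass(frozen=True)
class PartialCorrResult:
    """A (partial) Spearman coefficient with its two-sided p-value.

    ``k`` is the number of covariates actually used; ``method`` records which
    computational route produced the numbers.
    """

    rho: float
    p_value: float
    n: int
    k: int
    covariates_used: tuple[str, ...] = ()
    method: str = "residual"


def rank_transform(values) -> RankVector:
    """Midrank transform of a vector with no missing values.

    Raises ValueError on empty input or NaNs (missing-value deletion is the
    caller's job).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("rank_transform expects a 1-D vector")
    if v.size == 0:
        raise ValueError("rank_transform: empty vector")
    if np.isnan(v).any():
        raise ValueError("rank_transform: missing values are not allowed")
    return RankVector(_sps.rankdata(v, method="average"), v.size)


def _as_matrix(Z) -> np.ndarray:
    if Z is None:
        return np.empty((0, 0))
    Zm = np.asarray(Z, dtype=float)
    if Zm.ndim == 1:
        Zm = Zm[:, None]
    return Zm


def _rank_columns(Zm: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [rank_transform(Zm[:, j]).ranks for j in range(Zm.shape[1])]
    ) if Zm.shape[1] else np.empty((Zm.shape[0], 0))


def _p_from_t(rho: float, df: int) -> float:
    if 1.0 - rho * rho <= 1e-15:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    return float(min(1.0, 2.0 * _sps.t.sf(abs(t), df)))


def partial_spearman(
    x,
    y,
    Z=None,
    covariate_names=None,
    method: str = "residual",
) -> PartialCorrResult:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates ``Z``.

    Parameters
    ----------
    x, y : 1-D numeric vectors of equal length, no missing values.
    Z : optional (n, k) matrix of covariates (or a single vector).
    covariate_names : optional names, used in error messages and the result.
    method : ``"residual"`` (rank residualisation, the reference route) or
        ``"precision"`` (inverse Spearman correlation matrix).

    Raises
    ------
    UndefinedCorrelationError
        if ``x`` or ``y`` is constant, or a residual variance vanishes
        (e.g. ``y`` coincides with a covariate).
    IllConditionedError
        if the covariate rank columns are collinear; the offending column
        names are attached.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Zm = _as_matrix(Z)
    if Zm.size == 0:
        Zm = np.empty((x.size, 0))
    n = x.size
    k = Zm.shape[1]
    if y.size != n or Zm.shape[0] != n:
        raise ValueError("x, y and Z must have the same number of rows")
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    for name, v in (("x", x), ("y", y)):
        if np.isnan(v).any():
            raise ValueError(f"{name} contains missing values")
    if np.isnan(Zm).any():
        raise ValueError("Z contains missing values")
    names = (
        tuple(covariate_names)
        if covariate_names is not None
        else tuple(f"z{j}" for j in range(k))
    )
    if len(names) != k:
        raise ValueError("covariate_names length does not match Z")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("constant x or y: correlation undefined")

    rx = rank_transform(x).ranks
    ry = rank_transform(y).ranks
    RZ = _rank_columns(Zm)

    design = np.column_stack([np.ones(n), RZ])
    if k and np.linalg.matrix_rank(design) < k + 1:
        raise IllConditionedError(_offending_columns(RZ, names))

    if method == "precision":
        return _precision_route(rx, ry, RZ, n, k, names)
    if method != "residual":
        raise ValueError(f"unknown method: {method!r}")

    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    ssx = float(ex @ ex)
    ssy = float(ey @ ey)
    ss0x = float(np.sum((rx - rx.mean()) ** 2))
    ss0y = float(np.sum((ry - ry.mean()) ** 2))
    if ssx <= _ZERO_RSS_RTOL * ss0x or ssy <= _ZERO_RSS_RTOL * ss0y:
        raise UndefinedCorrelationError(
            "zero residual variance: x or y is explained by the covariates"
        )
    rho = float(np.clip((ex @ ey) / np.sqrt(ssx * ssy), -1.0, 1.0))
    return PartialCorrResult(
        rho=rho,
        p_value=_p_from_t(rho, n - 2 - k),
        n=n,
        k=k,
        covariates_used=names,
        method="residual",
    )


def spearman(x, y) -> PartialCorrResult:
    """Ordinary Spearman correlation (zero-covariate base case), n >= 4."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("spearman requires n >= 4")
    return partial_spearman(x, y, None)


def _precision_route(rx, ry, RZ, n, k, names) -> PartialCorrResult:
    M = np.column_stack([rx, ry, RZ])
    R = np.corrcoef(M, rowvar=False)
    try:
        omega = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise IllConditionedError(names) from exc
    denom = omega[0, 0] * omega[1, 1]
    if denom <= 0:
        raise UndefinedCorrelationError("singular precision matrix")
    rho = float(np.clip(-omega[0, 1] / np.sqrt(denom), -1.0, 1.0))
    return PartialCorrResult(
        rho=rho,
        p_value=_p_from_t(rho, n - 2 - k),
        n=n,
        k=k,
        covariates_used=names,
        method="precision-matrix",
    )


def _offending_columns(RZ: np.ndarray, names) -> list[str]:
    """Name covariate columns whose ranks add nothing to the design span."""
    n = RZ.shape[0]
    kept = np.ones((n, 1))
    offending = []
    for j in range(RZ.shape[1]):
        cand = np.column_stack([kept, RZ[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            offending.append(names[j])
        else:
            kept = cand
    return offending or list(names)
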