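"""Latent-correlation estimators for ordinal and dichotomised data.

Attitude networks are estimated from zero-order polychoric correlations:
each pair of ordinal items is assumed to discretise a latent bivariate
normal, whose correlation is recovered by two-step maximum likelihood
(thresholds from the margins, then a one-dimensional likelihood
maximisation in rho).  The tetrachoric correlation is the 2x2 special
case; the biserial correlation links a continuous score to an
artificially dichotomised variable under the same normality assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from ._bvn import bvn_cdf, bvn_upper

__all__ = [
    "UndefinedCorrelationError",
    "CorrelationNetwork",
    "contingency_table",
    "polychoric",
    "tetrachoric",
    "biserial",
    "point_biserial",
    "correlation_network",
]

RHO_BOUND = 0.999  # estimates are clamped to +/- this value


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (constant variable, empty group)."""


def contingency_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cross-tabulate two ordinal vectors into an r x c count matrix.

    Category labels are the sorted unique values of each vector; only
    observed categories form rows/columns.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    xcats, xi = np.unique(x, return_inverse=True)
    ycats, yi = np.unique(y, return_inverse=True)
    counts = np.zeros((len(xcats), len(ycats)), dtype=np.int64)
    np.add.at(counts, (xi, yi), 1)
    return counts


def _thresholds_from_margins(margin_counts: np.ndarray) -> np.ndarray:
    """Interior latent thresholds from cumulative marginal proportions."""
    cum = np.cumsum(margin_counts)[:-1] / margin_counts.sum()
    return ndtri(cum)


def _cell_probabilities(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of a bivariate normal on the threshold grid."""
    aa = np.concatenate(([-np.inf], a, [np.inf]))
    bb = np.concatenate(([-np.inf], b, [np.inf]))
    cdf = np.empty((len(aa), len(bb)))
    for i, h in enumerate(aa):
        for j, k in enumerate(bb):
            cdf[i, j] = bvn_cdf(h, k, rho)
    p = np.diff(np.diff(cdf, axis=0), axis=1)
    return np.clip(p, 1e-300, None)


def _tetrachoric_from_table(table: np.ndarray) -> float:
    """MLE for a 2x2 table via the score equation.

    With thresholds fixed from the margins, d(loglik)/d(rho) is a positive
    density times g(rho) = n11/p11 - n12/p12 - n21/p21 + n22/p22, which is
    strictly decreasing in rho; the MLE is the unique root (or a boundary).
    """
    n = table.astype(float)
    h = ndtri(n[0].sum() / n.sum())  # P(X in first row)
    k = ndtri(n[:, 0].sum() / n.sum())

    def score(rho: float) -> float:
        # p22 = P(X>h, Y>k) corresponds to the (2,2) cell
        p22 = bvn_upper(h, k, rho)
        ph, pk = ndtr(-h), ndtr(-k)
        p21 = max(ph - p22, 1e-300)
        p12 = max(pk - p22, 1e-300)
        p11 = max(1.0 - ph - pk + p22, 1e-300)
        p22 = max(p22, 1e-300)
        return n[0, 0] / p11 - n[0, 1] / p12 - n[1, 0] / p21 + n[1, 1] / p22

    lo, hi = -RHO_BOUND, RHO_BOUND
    s_lo, s_hi = score(lo), score(hi)
    if s_lo <= 0.0:
        return lo
    if s_hi >= 0.0:
        return hi
    return brentq(score, lo, hi, xtol=1e-7)


def _polychoric_from_table(table: np.ndarray) -> float:
    """MLE for an r x c table by bounded 1-D likelihood maximisation."""
    n = table.astype(float)
    a = _thresholds_from_margins(n.sum(axis=1))
    b = _thresholds_from_margins(n.sum(axis=0))

    def negloglik(rho: float) -> float:
        p = _cell_probabilities(a, b, rho)
        return -float(np.sum(n * np.log(p)))

    res = minimize_scalar(
        negloglik, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


def polychoric(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Polychoric correlation of two ordinal vectors.

    Returns ``(rho_hat, converged)``.  ``converged`` is False when the
    estimate hit the +/-0.999 clamp.  Tables containing an empty cell get a
    0.5 continuity correction in every cell, which keeps downstream
    inverse-weight distances finite.

    Raises
    ------
    UndefinedCorrelationError
        If either variable is constant.
    """
    table = contingency_table(x, y)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise UndefinedCorrelationError(
            "polychoric correlation undefined: a variable is constant"
        )
    work = table.astype(float)
    if np.any(work == 0):
        work = work + 0.5
    if work.shape == (2, 2):
        rho = _tetrachoric_from_table(work)
    else:
        rho = _polychoric_from_table(work)
    rho = float(np.clip(rho, -RHO_BOUND, RHO_BOUND))
    return rho, abs(rho) < RHO_BOUND


def tetrachoric(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Tetrachoric correlation: the 2x2 special case of :func:`polychoric`."""
    if len(np.unique(x)) > 2 or len(np.unique(y)) > 2:
        raise ValueError("tetrachoric requires binary variables")
    return polychoric(x, y)


def biserial(y: np.ndarray, d: np.ndarray) -> float:
    """Biserial correlation of a continuous score with a dichotomised variable.

    r_b = (mean(y|d=1) - mean(y|d=0)) * p * q / (s_y * phi(z)), with
    p = P(d=1), q = 1 - p, z the standard-normal quantile at p and phi the
    normal density.  Assumes d dichotomises a latent normal variable; the
    estimate is clamped to [-1, 1].
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(d)
    groups = np.unique(d)
    if len(groups) != 2:
        raise UndefinedCorrelationError("biserial: d must take exactly two values")
    d01 = (d == groups[1]).astype(float)
    s_y = y.std()  # population SD
    if s_y == 0:
        raise UndefinedCorrelationError("biserial: y is constant")
    p = d01.mean()
    q = 1.0 - p
    z = ndtri(p)
    rb = (y[d01 == 1].mean() - y[d01 == 0].mean()) * p * q / (s_y * norm.pdf(z))
    return float(np.clip(rb, -1.0, 1.0))


def point_biserial(y: np.ndarray, d: np.ndarray) -> float:
    """Point-biserial (plain Pearson) correlation; non-default alternative."""
    y = np.asarray(y, dtype=float)
    d = np.asarray(d)
    groups = np.unique(d)
    if len(groups) != 2:
        raise UndefinedCorrelationError("point_biserial: d must take exactly two values")
    d01 = (d == groups[1]).astype(float)
    if y.std() == 0:
        raise UndefinedCorrelationError("point_biserial: y is constant")
    p = d01.mean()
    rpb = (y[d01 == 1].mean() - y[d01 == 0].mean()) * np.sqrt(p * (1 - p)) / y.std()
    return float(np.clip(rpb, -1.0, 1.0))


@dataclass
class CorrelationNetwork:
    """Fully connected weighted network of pairwise latent correlations.

    ``weight_matrix`` is k x k, symmetric with zero diagonal, indexed in the
    order of ``element_ids``; weights lie in [-1, 1].
    """

    element_ids: list[int]
    weight_matrix: np.ndarray
    converged: np.ndarray = field(default=None)  # per-pair boolean matrix

    @property
    def k_nodes(self) -> int:
        return len(self.element_ids)


def correlation_network(
    responses: np.ndarray, element_ids: list[int] | np.ndarray
) -> CorrelationNetwork:
    """Estimate the zero-order polychoric correlation network among elements.

    ``responses`` is an n x k matrix of binary or ordinal codes; columns in
    ``element_ids`` are the attitude elements (the decision column, if any,
    is simply not listed).  Every pair gets a polychoric (tetrachoric for
    binary pairs) estimate, so the network is fully connected.
    """
    responses = np.asarray(responses)
    element_ids = list(element_ids)
    k = len(element_ids)
    if k < 2:
        raise ValueError("need at least two element columns")
    w = np.zeros((k, k))
    conv = np.ones((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                rho, ok = polychoric(responses[:, element_ids[i]],
                                     responses[:, element_ids[j]])
            except UndefinedCorrelationError as exc:
                raise UndefinedCorrelationError(
                    f"pair (column {element_ids[i]}, column {element_ids[j]}): {exc}"
                ) from exc
            w[i, j] = w[j, i] = rho
            conv[i, j] = conv[j, i] = ok
    return CorrelationNetwork(element_ids=element_ids, weight_matrix=w, converged=conv)
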