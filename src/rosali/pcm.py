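"""Partial credit model primitives.

The partial credit model (PCM) gives the probability that a person with
latent level :math:`\\theta` answers category :math:`x` of an ordered
polytomous item with thresholds :math:`\\delta_1, \\dots, \\delta_M`:

.. math::

    P(X = x \\mid \\theta) =
        \\frac{\\exp\\bigl(x\\theta - \\sum_{p \\le x} \\delta_p\\bigr)}
             {\\sum_{l=0}^{M} \\exp\\bigl(l\\theta - \\sum_{p \\le l} \\delta_p\\bigr)}

Threshold :math:`\\delta_p` is the latent level at which categories
:math:`p-1` and :math:`p` are equally likely.  This module provides the
closed-form category probabilities, expected-response (item characteristic)
and category characteristic curves, and the marginal log-likelihood of a
dataset with the latent trait integrated out under a normal law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._engine import LikelihoodEngine
from .data import ResponseData

__all__ = [
    "ItemParameters",
    "LatentDistribution",
    "category_probabilities",
    "expected_response",
    "response_variance",
    "curve_table",
    "marginal_loglik",
]

DEFAULT_THETA_GRID = np.round(np.arange(-4.0, 4.0 + 1e-9, 0.05), 10)


@dataclass
class ItemParameters:
    """Thresholds of one polytomous item.

    ``thresholds`` is either a flat sequence of ``M_j`` reals (shared by
    every (group, time) cell) or a mapping ``(group, time) -> sequence``
    for items whose thresholds differ across groups (DIF) or over time
    (recalibration response shift).
    """

    item_id: str
    n_categories: int
    thresholds: Sequence[float] | Mapping[tuple[str, str], Sequence[float]]

    def __post_init__(self):
        self.n_categories = int(self.n_categories)
        if self.n_categories < 2:
            raise ValueError("an item needs at least two categories")
        if isinstance(self.thresholds, Mapping):
            self.thresholds = {
                tuple(k): np.asarray(v, dtype=float) for k, v in self.thresholds.items()
            }
            for k, v in self.thresholds.items():
                self._check(v, cell=k)
        else:
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            self._check(self.thresholds)

    def _check(self, v: np.ndarray, cell=None) -> None:
        where = f" in cell {cell}" if cell else ""
        if v.shape != (self.n_categories - 1,):
            raise ValueError(
                f"item {self.item_id!r}{where}: expected "
                f"{self.n_categories - 1} thresholds, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(f"item {self.item_id!r}{where}: non-finite thresholds")

    def resolve(self, cell: tuple[str, str] | None = None) -> np.ndarray:
        """Threshold vector for a (group, time) cell; shared sets apply to all."""
        if isinstance(self.thresholds, dict):
            if cell is None or tuple(cell) not in self.thresholds:
                raise KeyError(
                    f"item {self.item_id!r}: no thresholds for cell {cell!r}"
                )
            return self.thresholds[tuple(cell)]
        return self.thresholds


@dataclass
class LatentDistribution:
    """Normal latent distribution over (group, time) cells.

    Means are per (group, time); variances are shared across groups within a
    time point and the T1-T2 covariance is shared across groups, matching
    the identifying assumptions of the two-group longitudinal PCM.  The mean
    of the reference cell is fixed at 0.
    """

    mu: Mapping[tuple[str, str], float]
    var: Mapping[str, float]
    cov_t1t2: float = 0.0
    reference_cell: tuple[str, str] = ("G0", "T1")

    def __post_init__(self):
        self.mu = {tuple(k): float(v) for k, v in self.mu.items()}
        self.var = {k: float(v) for k, v in self.var.items()}
        ref = tuple(self.reference_cell)
        if self.mu.get(ref, 0.0) != 0.0:
            raise ValueError(f"mean of reference cell {ref} must be 0")
        self.mu.setdefault(ref, 0.0)
        for t, v in self.var.items():
            if v <= 0:
                raise ValueError(f"variance at {t} must be positive")
        if len(self.var) == 2:
            v1, v2 = self.var.values()
            if self.cov_t1t2**2 >= v1 * v2:
                raise ValueError("latent covariance matrix is not positive definite")

    def correlation(self) -> float:
        if len(self.var) != 2:
            return 0.0
        v1, v2 = self.var.values()
        return self.cov_t1t2 / np.sqrt(v1 * v2)


# ---------------------------------------------------------------------- #
# closed-form curves
# ---------------------------------------------------------------------- #
def _thresholds_of(item) -> np.ndarray:
    if isinstance(item, ItemParameters):
        return item.resolve() if not isinstance(item.thresholds, dict) else None
    return np.asarray(item, dtype=float)


def category_probabilities(theta: float, item) -> np.ndarray:
    """PCM category probabilities at latent level ``theta``.

    ``item`` is an :class:`ItemParameters` with a shared threshold set, or a
    plain threshold sequence.  The normalization subtracts the largest
    exponent, so extreme ``theta`` cannot overflow; probabilities are
    nonnegative and sum to one to machine precision.
    """
    theta = float(theta)
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    thr = _thresholds_of(item)
    if thr is None:
        raise ValueError("cell-specific item: resolve a cell first")
    if not np.all(np.isfinite(thr)):
        raise ValueError("thresholds must be finite")
    cum = np.concatenate([[0.0], np.cumsum(thr)])
    logits = theta * np.arange(len(cum)) - cum
    logits -= logits.max()
    e = np.exp(logits)
    return e / e.sum()


def expected_response(theta: float, item) -> float:
    """Expected item response E[X | theta]; strictly increasing in theta."""
    p = category_probabilities(theta, item)
    return float(p @ np.arange(len(p)))


def response_variance(theta: float, item) -> float:
    """Var[X | theta] under the PCM."""
    p = category_probabilities(theta, item)
    x = np.arange(len(p), dtype=float)
    m = p @ x
    return float(p @ x**2 - m**2)


def curve_table(
    item: ItemParameters,
    cells: Sequence[tuple[str, str]] | None = None,
    theta_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Tabulated category characteristic curves (CCC) and item characteristic
    curve (ICC) for one item, per (group, time) cell.

    Cells with identical thresholds produce pointwise identical curves; a
    uniform threshold offset between cells translates the ICC horizontally,
    non-uniform differences change its shape.  Output has one row per
    (cell, theta) with columns ``p0..pM`` and ``icc``, ready for CSV export.
    """
    grid = DEFAULT_THETA_GRID if theta_grid is None else np.asarray(theta_grid, float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("theta grid must be finite")
    if np.any(np.diff(grid) < 0):
        raise ValueError("theta grid must be sorted")
    if cells is None:
        cells = (
            list(item.thresholds)
            if isinstance(item.thresholds, dict)
            else [("all", "all")]
        )
    rows = []
    for cell in cells:
        thr = (
            item.resolve(cell)
            if isinstance(item.thresholds, dict)
            else item.resolve()
        )
        for th in grid:
            p = category_probabilities(th, thr)
            rows.append(
                {
                    "item": item.item_id,
                    "group": cell[0],
                    "time": cell[1],
                    "theta": th,
                    **{f"p{c}": p[c] for c in range(item.n_categories)},
                    "icc": float(p @ np.arange(item.n_categories)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# marginal likelihood
# ---------------------------------------------------------------------- #
def marginal_loglik(
    data: ResponseData,
    items: Sequence[ItemParameters],
    latent: LatentDistribution,
    quadrature: int = 30,
) -> float:
    """Observed-data marginal log-likelihood of a PCM.

    The within-person product of conditional category probabilities (missing
    responses skipped) is integrated over the latent normal — univariate for
    one time point, bivariate for two — with fixed-order Gauss-Hermite
    quadrature, and summed over persons.  Always <= 0.
    """
    if len(items) != data.n_items:
        raise ValueError("one ItemParameters per data item required")
    engine = LikelihoodEngine(data, quadrature=quadrature)
    T = data.n_times
    delta = {}
    for g, glab in enumerate(data.group_labels):
        for t, tlab in enumerate(data.time_labels):
            per_item = []
            for j, it in enumerate(items):
                if isinstance(it.thresholds, dict):
                    thr = it.resolve((glab, tlab))
                else:
                    thr = it.resolve()
                if len(thr) != data.n_categories[j] - 1:
                    raise ValueError(
                        f"item {it.item_id!r}: thresholds inconsistent with data"
                    )
                per_item.append(thr)
            delta[(g, t)] = per_item
    mu = np.zeros((2, T))
    var = np.zeros(T)
    for t, tlab in enumerate(data.time_labels):
        var[t] = latent.var[tlab]
        for g, glab in enumerate(data.group_labels):
            mu[g, t] = latent.mu.get((glab, tlab), 0.0)
    rho = latent.correlation() if T == 2 else 0.0
    return engine.compute(delta, mu, var, rho).loglik
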