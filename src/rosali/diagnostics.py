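"""Pre-analysis screening of item fit and response-category behaviour.

Before any invariance testing, the partial credit model should describe the
data adequately.  This module provides:

- INFIT/OUTFIT mean-square residual statistics (information-weighted and
  unweighted) against a fitted cross-sectional model,
- detection of disordered thresholds,
- a zero-frequency check of the item-category x group contingency table at
  each time point,
- collapsing of adjacent response categories, applied identically in every
  (group, time) cell.

All functions are pure: inputs are never mutated; collapsing returns a new
dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MISSING, ResponseData

__all__ = [
    "item_fit",
    "disordered_thresholds",
    "sparse_cell_check",
    "collapse_categories",
    "suggest_collapsings",
    "DEFAULT_MISFIT_BAND",
]

DEFAULT_MISFIT_BAND = (0.7, 1.3)


def item_fit(
    results,
    band: tuple[float, float] = DEFAULT_MISFIT_BAND,
) -> pd.DataFrame:
    """INFIT and OUTFIT per item against a fitted cross-sectional PCM.

    Residuals are standardized with the item's leave-one-out posterior
    predictive moments: for item j, each person's posterior over the latent
    level is formed from their *other* responses under the fitted marginal
    model (a point estimate computed from all items would deflate both
    statistics well below 1 on short scales), giving ``E_ij`` and ``V_ij``
    with ``E[(x - E)^2] = V`` exactly under the model.  With
    ``z_ij = (x_ij - E_ij) / sqrt(V_ij)``,

    - ``OUTFIT_j`` is the plain mean of ``z^2`` (outlier-sensitive),
    - ``INFIT_j``  is ``sum (x - E)^2 / sum V`` (information-weighted,
      inlier-sensitive),

    both 1 in expectation for model-consistent responses.  Items outside
    ``band`` on either statistic are flagged ``misfit``; items without any
    usable response are excluded with a warning.
    """
    from ._engine import LikelihoodEngine

    model = results.model
    data = model.data
    if data.n_times != 1:
        raise ValueError("item fit screening uses a single-time fit")
    par = model._par
    delta, mu, var, rho = par.unpack(results.params.to_numpy())

    rows = []
    for j, item in enumerate(data.item_ids):
        x_all = data.responses[:, j, 0]
        obs_all = x_all != MISSING
        if not obs_all.any():
            warnings.warn(f"item {item!r}: no usable responses, excluded")
            continue
        # posterior given every response except item j
        resp_loo = data.responses.copy()
        resp_loo[:, j, :] = MISSING
        loo = ResponseData(
            resp_loo, data.groups, data.item_ids, data.n_categories,
            data.group_labels, data.time_labels, data.person_ids,
        )
        eng = LikelihoodEngine(loo, quadrature=model.quadrature)
        out = eng.compute(delta, mu, var, rho, want_node_posteriors=True)

        cats = np.arange(data.n_categories[j], dtype=float)
        sq_resid = np.array([])
        pred_var = np.array([])
        for rows_g, Q, theta in out.node_posteriors:
            g = data.groups[rows_g[0]]
            x = x_all[rows_g]
            obs = x != MISSING
            if not obs.any():
                continue
            cum = np.concatenate([[0.0], np.cumsum(delta[(g, 0)][j])])
            logits = np.outer(theta[:, 0], cats) - cum
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            e_nodes = p @ cats
            e2_nodes = p @ cats**2
            E = Q[obs] @ e_nodes
            V = Q[obs] @ e2_nodes - E**2
            sq_resid = np.append(sq_resid, (x[obs] - E) ** 2)
            pred_var = np.append(pred_var, V)
        z2 = sq_resid / pred_var
        outfit = float(z2.mean())
        infit = float(sq_resid.sum() / pred_var.sum())
        flag = (
            "ok"
            if band[0] <= infit <= band[1] and band[0] <= outfit <= band[1]
            else "misfit"
        )
        rows.append(
            {
                "item": item,
                "infit": infit,
                "outfit": outfit,
                "n_used": int(obs_all.sum()),
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def disordered_thresholds(thresholds) -> list[int]:
    """Indices ``p`` (1-based) where threshold p exceeds threshold p+1.

    An empty list means the thresholds are ordered along the latent scale.
    """
    thr = np.asarray(
        thresholds.thresholds if hasattr(thresholds, "thresholds") else thresholds,
        dtype=float,
    )
    return [int(p) + 1 for p in np.flatnonzero(np.diff(thr) < 0)]


def sparse_cell_check(data: ResponseData) -> pd.DataFrame:
    """Zero cells of the item-response x group table at each time point.

    Returns one row per (item, time, group, category) combination with zero
    observed frequency; an empty frame means every response category was
    used in both groups at every time point.
    """
    rows = []
    for j, item in enumerate(data.item_ids):
        for t, tlab in enumerate(data.time_labels):
            for g, glab in enumerate(data.group_labels):
                x = data.responses[data.groups == g, j, t]
                x = x[x != MISSING]
                counts = np.bincount(x, minlength=data.n_categories[j])
                for c in np.flatnonzero(counts == 0):
                    rows.append(
                        {
                            "item": item,
                            "time": tlab,
                            "group": glab,
                            "category": int(c),
                            "count": 0,
                        }
                    )
    return pd.DataFrame(rows, columns=["item", "time", "group", "category", "count"])


def collapse_categories(
    data: ResponseData, item: str, merge: tuple[int, int]
) -> ResponseData:
    """Merge two adjacent response categories of one item.

    Responses in the upper merged category are recoded into the lower one
    and all higher categories shift down by one, identically in both groups
    and at both time points; the item loses one category.  The total count
    of non-missing responses is conserved.
    """
    lo, hi = merge
    if hi != lo + 1:
        raise ValueError(f"categories to merge must be adjacent, got {merge}")
    j = data.item_ids.index(item)
    m = data.n_categories[j]
    if not (0 <= lo and hi < m):
        raise ValueError(f"merge {merge} outside categories 0..{m - 1}")
    resp = data.responses.copy()
    xj = resp[:, j, :]
    shift = (xj != MISSING) & (xj > lo)
    xj[shift] -= 1
    n_cat = list(data.n_categories)
    n_cat[j] = m - 1
    return ResponseData(
        resp,
        data.groups,
        data.item_ids,
        n_cat,
        data.group_labels,
        data.time_labels,
        data.person_ids,
        data.n_excluded,
    )


def suggest_collapsings(data: ResponseData) -> list[tuple[str, tuple[int, int]]]:
    """Adjacent-category merges that would resolve zero cells.

    For each item with an empty (category x group x time) cell, the sparse
    category is merged into its neighbour nearer the scale midpoint.  The
    returned list can be applied in order with :func:`collapse_categories`;
    explicit analyst-chosen merges always take precedence.
    """
    merges: list[tuple[str, tuple[int, int]]] = []
    work = data
    while True:
        report = sparse_cell_check(work)
        if report.empty:
            return merges
        row = report.iloc[0]
        j = work.item_ids.index(row["item"])
        m = work.n_categories[j]
        if m <= 2:
            # dichotomous items cannot be collapsed further
            report = report[report["item"] != row["item"]]
            if report.empty:
                return merges
            row = report.iloc[0]
            j = work.item_ids.index(row["item"])
            m = work.n_categories[j]
        c = int(row["category"])
        mid = (m - 1) / 2.0
        merge = (c, c + 1) if c < mid else (c - 1, c)
        merges.append((row["item"], merge))
        work = collapse_categories(work, row["item"], merge)
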