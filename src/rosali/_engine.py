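"""Marginal likelihood of partial credit models by Gauss-Hermite quadrature.

The latent trait is integrated out under a normal (cross-sectional) or
bivariate normal (two time points) distribution on a fixed tensor-product
Gauss-Hermite grid.  The engine evaluates the observed-data log-likelihood
and its exact gradient with respect to the natural parameters (thresholds
per (group, time) cell, latent means, log-variances, correlation); missing
responses simply drop out of the within-person product.

All heavy arrays are laid out person x node so that every step is a dense
numpy operation; with J items, n persons and K nodes the cost per evaluation
is O(n J K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import MISSING, ResponseData

__all__ = ["LikelihoodEngine", "ScorePieces"]

_SQRT2 = np.sqrt(2.0)


def gauss_hermite(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/log-weights for E[f(Z)], Z ~ N(0,1): nodes sqrt(2)*x, w/sqrt(pi)."""
    if order < 5:
        raise ValueError("quadrature order must be at least 5")
    x, w = np.polynomial.hermite.hermgauss(order)
    return _SQRT2 * x, np.log(w) - 0.5 * np.log(np.pi)


def _logp_grid(theta: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """log P(X = x | theta) on a node grid; (K, M+1), log-sum-exp stabilized."""
    cum = np.concatenate([[0.0], np.cumsum(thresholds)])
    x = np.arange(len(cum), dtype=float)
    logits = np.outer(theta, x) - cum  # (K, M+1)
    logits -= logsumexp(logits, axis=1, keepdims=True)
    return logits


@dataclass
class ScorePieces:
    """Gradient of the marginal log-likelihood in natural parameters."""

    d_delta: dict  # (g, t, j) -> ndarray (M_j,)
    d_mu: np.ndarray  # (2, T)
    d_logvar: np.ndarray  # (T,)
    d_rho: float = 0.0


@dataclass
class EngineOutput:
    loglik: float
    score: ScorePieces | None = None
    posterior_theta: np.ndarray | None = None  # (n, T) EAP per person
    # per group: (person row indices, posterior node weights, node thetas)
    node_posteriors: list | None = None


class LikelihoodEngine:
    """Evaluates the marginal log-likelihood for a fixed dataset.

    Parameters are supplied in natural form on each call:

    - ``delta[(g, t)]`` : list of J threshold arrays (length M_j each)
    - ``mu`` : array (2, T) of latent means per (group, time)
    - ``var`` : array (T,) latent variances (shared across groups per time)
    - ``rho`` : latent T1-T2 correlation (longitudinal only, shared across
      groups; the covariance is ``rho * sqrt(var_1 * var_2)``)
    """

    def __init__(self, data: ResponseData, quadrature: int = 30):
        self.data = data
        self.quadrature = int(quadrature)
        u, logw = gauss_hermite(self.quadrature)
        self.n_times = data.n_times
        if self.n_times == 1:
            self.U = u[:, None]  # (K, 1)
            self.logw = logw
        elif self.n_times == 2:
            u1, u2 = np.meshgrid(u, u, indexing="ij")
            self.U = np.column_stack([u1.ravel(), u2.ravel()])  # (K, 2)
            self.logw = (logw[:, None] + logw[None, :]).ravel()
        else:
            raise ValueError("at most two time points are supported")
        self.K = self.U.shape[0]

        # per-group observation index structures
        self.group_index = [np.flatnonzero(data.groups == g) for g in (0, 1)]
        self._obs = {}  # (g, t, j) -> (person-row indices within group, responses)
        self._xsum = {}  # (g, t) -> per-person sum of observed responses
        self._nobs_t = {}
        for g in (0, 1):
            rows = self.group_index[g]
            X = data.responses[rows]  # (n_g, J, T)
            for t in range(self.n_times):
                self._xsum[(g, t)] = np.where(X[:, :, t] != MISSING, X[:, :, t], 0).sum(
                    axis=1
                ).astype(float)
                for j in range(data.n_items):
                    m = X[:, j, t] != MISSING
                    self._obs[(g, t, j)] = (np.flatnonzero(m), X[m, j, t])

    # ------------------------------------------------------------------ #
    def _node_thetas(self, g: int, mu: np.ndarray, sig: np.ndarray, rho: float):
        """Latent values at the quadrature nodes for group g; (K, T)."""
        theta = np.empty((self.K, self.n_times))
        theta[:, 0] = mu[g, 0] + sig[0] * self.U[:, 0]
        if self.n_times == 2:
            c = np.sqrt(max(1.0 - rho * rho, 1e-12))
            theta[:, 1] = mu[g, 1] + sig[1] * (rho * self.U[:, 0] + c * self.U[:, 1])
        return theta

    def compute(
        self,
        delta: dict,
        mu: np.ndarray,
        var: np.ndarray,
        rho: float = 0.0,
        want_score: bool = False,
        want_posterior: bool = False,
        want_node_posteriors: bool = False,
    ) -> EngineOutput:
        data = self.data
        J, T = data.n_items, self.n_times
        mu = np.asarray(mu, dtype=float)
        var = np.asarray(var, dtype=float)
        if np.any(var <= 0):
            raise ValueError("latent variances must be positive")
        if T == 2:
            cov = np.array(
                [
                    [var[0], rho * np.sqrt(var[0] * var[1])],
                    [rho * np.sqrt(var[0] * var[1]), var[1]],
                ]
            )
            if np.linalg.eigvalsh(cov)[0] <= 0:
                raise ValueError("longitudinal latent covariance is not positive definite")
        sig = np.sqrt(var)

        total = 0.0
        score = (
            ScorePieces(d_delta={}, d_mu=np.zeros((2, T)), d_logvar=np.zeros(T))
            if want_score
            else None
        )
        post = np.full((data.n_persons, T), np.nan) if want_posterior else None
        node_post = [] if want_node_posteriors else None

        for g in (0, 1):
            rows = self.group_index[g]
            n_g = len(rows)
            if n_g == 0:
                if want_score:
                    for t in range(T):
                        for j in range(J):
                            score.d_delta[(g, t, j)] = np.zeros(
                                data.n_categories[j] - 1
                            )
                continue
            theta = self._node_thetas(g, mu, sig, rho)

            logp = {}
            moments = {}  # (t, j) -> (E, Pge)
            Lmat = np.zeros((n_g, self.K))
            for t in range(T):
                for j in range(J):
                    lp = _logp_grid(theta[:, t], delta[(g, t)][j])
                    logp[(t, j)] = lp
                    idx, resp = self._obs[(g, t, j)]
                    if len(idx):
                        Lmat[idx] += lp[:, resp].T
                    if want_score or want_posterior or want_node_posteriors:
                        p = np.exp(lp)
                        cats = np.arange(p.shape[1], dtype=float)
                        E = p @ cats
                        # P(X >= p) for p = 1..M
                        Pge = np.cumsum(p[:, ::-1], axis=1)[:, ::-1][:, 1:]
                        moments[(t, j)] = (E, Pge)

            a = Lmat + self.logw[None, :]
            ll_i = logsumexp(a, axis=1)
            total += ll_i.sum()

            if not (want_score or want_posterior or want_node_posteriors):
                continue
            Q = np.exp(a - ll_i[:, None])  # posterior node weights, rows sum to 1

            if want_posterior:
                post[rows] = Q @ theta
            if want_node_posteriors:
                node_post.append((rows, Q, theta))

            if not want_score:
                continue

            for t in range(T):
                for j in range(J):
                    idx, resp = self._obs[(g, t, j)]
                    Mj = data.n_categories[j] - 1
                    dj = np.zeros(Mj)
                    if len(idx):
                        _, Pge = moments[(t, j)]
                        Gm = Q[idx] @ Pge  # (n_obs, Mj)
                        for p in range(1, Mj + 1):
                            dj[p - 1] = Gm[:, p - 1].sum() - float((resp >= p).sum())
                    score.d_delta[(g, t, j)] = dj

                # residual pieces for latent parameters
                S = np.zeros((n_g, self.K))
                for j in range(J):
                    idx, _ = self._obs[(g, t, j)]
                    if len(idx):
                        E, _ = moments[(t, j)]
                        S[idx] += E[None, :]
                R = self._xsum[(g, t)][:, None] - S
                QR = Q * R
                score.d_mu[g, t] += QR.sum()
                colsum = QR.sum(axis=0)  # (K,)
                score.d_logvar[t] += colsum @ (0.5 * (theta[:, t] - mu[g, t]))
                if T == 2 and t == 1:
                    c = np.sqrt(max(1.0 - rho * rho, 1e-12))
                    dtheta2_drho = sig[1] * (self.U[:, 0] - (rho / c) * self.U[:, 1])
                    score.d_rho += float(colsum @ dtheta2_drho)

        return EngineOutput(
            loglik=float(total),
            score=score,
            posterior_theta=post,
            node_posteriors=node_post,
        )
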