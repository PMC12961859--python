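"""Marginal maximum likelihood fitting of cross-sectional and longitudinal
partial credit models.

The models follow the statsmodels convention: a model object is built from a
:class:`~rosali.data.ResponseData` and a :class:`~rosali.design.ModelSpec`,
``fit()`` maximizes the Gauss-Hermite marginal likelihood with a
quasi-Newton optimizer on an unconstrained reparameterization (log
variances, atanh correlation) and returns a :class:`PCMResults` carrying
estimates, standard errors and the bookkeeping needed for nested
likelihood-ratio tests.

Identifying constraints (reference-cell mean 0, variances shared across
groups, covariance shared across groups) hold exactly by construction: the
constrained quantities are simply not free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._engine import LikelihoodEngine
from .data import MISSING, ResponseData
from .design import ModelSpec

__all__ = [
    "CrossSectionalPCM",
    "LongitudinalPCM",
    "PCMResults",
    "TestResult",
    "likelihood_ratio_test",
    "fit_cross_sectional",
    "fit_longitudinal",
]


class _BasePCM:
    """Shared machinery of the two PCM variants."""

    def __init__(self, data: ResponseData, spec: ModelSpec | None = None,
                 quadrature: int = 30):
        if spec is None:
            spec = ModelSpec.for_data(data)
        if spec.item_ids != data.item_ids:
            raise ValueError("spec items do not match data items")
        self.data = data
        self.spec = spec
        self._par = spec.parameterization()
        self._engine = LikelihoodEngine(data, quadrature=quadrature)
        self.quadrature = quadrature
        self._check_observed_categories()

    def _check_observed_categories(self) -> None:
        for j, it in enumerate(self.data.item_ids):
            xj = self.data.responses[:, j, :]
            xj = xj[xj != MISSING]
            counts = np.bincount(xj, minlength=self.data.n_categories[j])
            empty = np.flatnonzero(counts == 0)
            if len(empty):
                raise ValueError(
                    f"item {it!r}: categories {empty.tolist()} unobserved in the "
                    "analysis sample; collapse adjacent categories first "
                    "(rosali.diagnostics.collapse_categories)"
                )

    @property
    def param_names(self) -> list[str]:
        return list(self._par.names)

    def loglike(self, params: np.ndarray) -> float:
        delta, mu, var, rho = self._par.unpack(params)
        return self._engine.compute(delta, mu, var, rho).loglik

    def loglike_and_score(self, params: np.ndarray) -> tuple[float, np.ndarray]:
        delta, mu, var, rho = self._par.unpack(params)
        out = self._engine.compute(delta, mu, var, rho, want_score=True)
        return out.loglik, self._par.chain(out.score, params)

    def score(self, params: np.ndarray) -> np.ndarray:
        return self.loglike_and_score(params)[1]

    def start_params(self) -> np.ndarray:
        return self._par.start_values(self.data)

    def eap_theta(self, params: np.ndarray) -> np.ndarray:
        """Expected a-posteriori latent level per person (n, T)."""
        delta, mu, var, rho = self._par.unpack(params)
        return self._engine.compute(
            delta, mu, var, rho, want_posterior=True
        ).posterior_theta

    def fit(
        self,
        start_params: np.ndarray | None = None,
        maxiter: int = 1000,
        gtol: float = 5e-5,
        compute_se: bool = False,
    ) -> "PCMResults":
        x0 = self.start_params() if start_params is None else np.asarray(start_params, float)
        if x0.shape != (self._par.n_params,):
            raise ValueError("start_params has wrong length")

        def negll(x):
            ll, g = self.loglike_and_score(x)
            return -ll, -g

        res = optimize.minimize(
            negll,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol, "maxcor": 25},
        )
        grad = self.score(res.x)
        converged = bool(res.success) or float(np.max(np.abs(grad))) < 1e-3
        if not converged:
            warnings.warn(
                f"PCM fit did not converge after {res.nit} iterations "
                f"(max |score| = {np.max(np.abs(grad)):.2e})",
                RuntimeWarning,
            )
        out = PCMResults(
            model=self,
            params=pd.Series(res.x, index=self.param_names),
            llf=float(-res.fun),
            converged=converged,
            n_iter=int(res.nit),
        )
        if compute_se:
            out.bse  # noqa: B018 - trigger lazy Hessian
        return out


class CrossSectionalPCM(_BasePCM):
    """Two-group PCM at a single time point (DIF structure optional).

    The group effect on the latent trait is the mean of the non-reference
    group, ``mu_G1``; it is a free parameter unless every item carries DIF,
    in which case it is fixed at 0 for identifiability.  The latent variance
    is shared across groups.
    """

    def __init__(self, data, spec=None, quadrature=30):
        if data.n_times != 1:
            raise ValueError(
                "cross-sectional model needs exactly one time point; "
                "use data.at_time(...) to restrict"
            )
        if spec is None:
            spec = ModelSpec.for_data(data, longitudinal=False)
        if spec.longitudinal or spec.rs:
            raise ValueError("cross-sectional spec cannot carry RS terms")
        super().__init__(data, spec, quadrature)


class LongitudinalPCM(_BasePCM):
    """Two-group, two-time-point PCM with bivariate-normal latent trait.

    Latent means are free per (group, time) except for the identifying
    constraints; variances may differ over time but are shared across
    groups, and the T1-T2 covariance is shared across groups.  DIF
    structure applies at both time points; RS terms shift thresholds at T2.
    """

    def __init__(self, data, spec=None, quadrature=30):
        if data.n_times != 2:
            raise ValueError("longitudinal model needs two time points")
        if spec is None:
            spec = ModelSpec.for_data(data, longitudinal=True)
        if not spec.longitudinal:
            raise ValueError("spec is not longitudinal")
        super().__init__(data, spec, quadrature)


@dataclass
class PCMResults:
    """Fitted PCM: estimates, uncertainty, and model-comparison bookkeeping."""

    model: _BasePCM
    params: pd.Series
    llf: float
    converged: bool
    n_iter: int = 0
    _cov: pd.DataFrame | None = field(default=None, repr=False)
    hessian_singular: bool = field(default=False, repr=False)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def df_model(self) -> int:
        return len(self.params)

    @property
    def nobs(self) -> int:
        return self.model.data.n_persons

    # ------------------------------------------------------------------ #
    # uncertainty
    # ------------------------------------------------------------------ #
    def _hessian(self) -> np.ndarray:
        """Hessian of the log-likelihood by central differences of the
        analytic score (relative step 1e-5 per parameter)."""
        x = self.params.to_numpy()
        n = len(x)
        H = np.empty((n, n))
        for i in range(n):
            h = 1e-5 * max(1.0, abs(x[i]))
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            H[i] = (self.model.score(xp) - self.model.score(xm)) / (2 * h)
        return 0.5 * (H + H.T)

    def cov_params(self) -> pd.DataFrame:
        if self._cov is None:
            if not self.converged:
                raise ValueError("standard errors require a converged fit")
            info = -self._hessian()
            try:
                cov = np.linalg.inv(info)
                if np.any(np.diag(cov) <= 0):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                self.hessian_singular = True
                warnings.warn(
                    "observed information is singular; using pseudo-inverse, "
                    "affected parameters get NaN standard errors",
                    RuntimeWarning,
                )
                cov = np.linalg.pinv(info)
            self._cov = pd.DataFrame(
                cov, index=self.params.index, columns=self.params.index
            )
        return self._cov

    @property
    def bse(self) -> pd.Series:
        d = np.diag(self.cov_params().to_numpy()).copy()
        d[d <= 0] = np.nan
        return pd.Series(np.sqrt(d), index=self.params.index)

    # ------------------------------------------------------------------ #
    # natural-scale latent quantities
    # ------------------------------------------------------------------ #
    def latent_distribution(self) -> pd.DataFrame:
        """Latent means, variances and correlation on the natural scale,
        with delta-method standard errors."""
        rows = []
        bse = None
        try:
            bse = self.bse
        except ValueError:
            pass
        for name in self.params.index:
            if name.startswith(("mu_", "log_var", "atanh_corr")):
                est, se = self.params[name], (np.nan if bse is None else bse[name])
                if name.startswith("log_var"):
                    rows.append(
                        ("var" + name[7:], np.exp(est), np.exp(est) * se)
                    )
                elif name == "atanh_corr":
                    rho = np.tanh(est)
                    rows.append(("corr_T1T2", rho, (1 - rho**2) * se))
                else:
                    rows.append((name, est, se))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"])

    def _mu_combo(self, cells: list[tuple[int, int, float]]):
        """Estimate/SE/p of a linear combination of latent means given as
        (group index, time index, coefficient) triples.  Returns
        (estimate, se, p); fixed means contribute 0, and a combination with
        no free parameter is the structural zero (se and p are None)."""
        par = self.model._par
        coef = pd.Series(0.0, index=self.params.index)
        free = False
        for g, t, c in cells:
            k = par.mu_ix.get((g, t))
            if k is not None:
                coef.iloc[k] += c
                free = True
        if not free or np.all(coef == 0):
            return 0.0, None, None
        est = float(coef @ self.params)
        var = float(coef @ self.cov_params() @ coef)
        se = np.sqrt(var) if var > 0 else np.nan
        p = 2 * stats.norm.sf(abs(est) / se) if se and np.isfinite(se) else np.nan
        return est, float(se), float(p)

    def group_effect(self, time_index: int = 0):
        """Latent-mean difference G1 - G0 at a time point: (est, se, p)."""
        return self._mu_combo([(1, time_index, 1.0), (0, time_index, -1.0)])

    def time_effect(self, group_index: int):
        """Latent-mean change T2 - T1 within a group: (est, se, p)."""
        if not self.spec.longitudinal:
            raise ValueError("time effects need a longitudinal fit")
        return self._mu_combo([(group_index, 1, 1.0), (group_index, 0, -1.0)])

    # ------------------------------------------------------------------ #
    def summary(self) -> str:
        spec = self.spec
        kind = "Longitudinal" if spec.longitudinal else "Cross-sectional"
        lines = [
            f"{kind} partial credit model (marginal ML, "
            f"{self.model.quadrature}-point Gauss-Hermite)",
            f"persons: {self.nobs}  items: {len(spec.item_ids)}  "
            f"free parameters: {self.df_model}",
            f"log-likelihood: {self.llf:.4f}   converged: {self.converged}",
            f"structure: {spec.describe()}",
            "",
            f"{'parameter':<22}{'estimate':>12}{'std err':>12}",
        ]
        try:
            bse = self.bse
        except ValueError:
            bse = pd.Series(np.nan, index=self.params.index)
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>12.4f}{bse[name]:>12.4f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "structure": self.spec.describe(),
            "loglik": self.llf,
            "n_free_parameters": self.df_model,
            "converged": self.converged,
            "estimates": {k: float(v) for k, v in self.params.items()},
        }


@dataclass(frozen=True)
class TestResult:
    """A likelihood-ratio test between two nested fits."""

    statistic: float
    df: int
    p_value: float
    p_adjusted: float
    comparison: tuple[str, str]

    def significant(self, alpha: float) -> bool:
        return self.p_adjusted < alpha

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "comparison": list(self.comparison),
        }


def likelihood_ratio_test(restricted: PCMResults, full: PCMResults) -> TestResult:
    """LRT of a restricted against a full PCM fit on the same data.

    Nesting is checked structurally on the model specs; the statistic
    ``2 (llf_full - llf_restricted)`` is clamped at zero (optimizer slack)
    and referred to the chi-squared upper tail with df equal to the
    difference in free-parameter counts.
    """
    if restricted.model.data is not full.model.data and (
        restricted.nobs != full.nobs
    ):
        raise ValueError("fits compare different datasets")
    if not restricted.spec.is_nested_in(full.spec):
        raise ValueError(
            f"specs are not nested: [{restricted.spec.describe()}] vs "
            f"[{full.spec.describe()}]"
        )
    if not (restricted.converged and full.converged):
        raise ValueError("both fits must have converged")
    df = full.df_model - restricted.df_model
    stat = max(0.0, 2.0 * (full.llf - restricted.llf))
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult(
        statistic=stat,
        df=df,
        p_value=p,
        p_adjusted=p,
        comparison=(restricted.spec.describe(), full.spec.describe()),
    )


def fit_cross_sectional(data: ResponseData, spec: ModelSpec | None = None,
                        quadrature: int = 30, **fit_kw) -> PCMResults:
    """Fit the two-group cross-sectional PCM (data restricted to one time)."""
    return CrossSectionalPCM(data, spec, quadrature).fit(**fit_kw)


def fit_longitudinal(data: ResponseData, spec: ModelSpec | None = None,
                     quadrature: int = 30, **fit_kw) -> PCMResults:
    """Fit the two-group, two-time-point longitudinal PCM."""
    return LongitudinalPCM(data, spec, quadrature).fit(**fit_kw)
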