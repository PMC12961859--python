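"""Cohort baseline description: per-group summaries with two-sample tests.

Categorical covariates are summarized as frequencies and percentages over
non-missing values (one decimal, round-half-up) and compared with the
Pearson chi-squared test; continuous covariates as mean (SD), compared with
the unequal-variance (Welch) t-test.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["summarize_baseline", "round_half_up"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (0.05 -> 0.1)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _is_continuous(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s) and s.nunique(dropna=True) > 10


def summarize_baseline(
    df: pd.DataFrame,
    group_col: str = "group",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group baseline table from a one-row-per-person frame.

    Returns one row per covariate level (categorical) or per covariate
    (continuous) with counts/percentages or mean (SD) per group, the number
    missing per group, and the two-sample comparison p-value.  Percentages
    use non-missing denominators.  Covariates that are entirely missing are
    omitted with a warning.
    """
    groups = df[group_col].astype(str)
    glabels = sorted(groups.unique())
    if len(glabels) != 2:
        raise ValueError(f"expected two groups, found {glabels}")
    if covariates is None:
        covariates = [c for c in df.columns if c != group_col]

    rows = []
    for cov in covariates:
        s = df[cov]
        if s.isna().all():
            warnings.warn(f"covariate {cov!r} is entirely missing; omitted")
            continue
        n_miss = {g: int(s[groups == g].isna().sum()) for g in glabels}
        if _is_continuous(s):
            a = s[groups == glabels[0]].dropna().astype(float)
            b = s[groups == glabels[1]].dropna().astype(float)
            _, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "covariate": cov,
                    "level": "mean (SD)",
                    glabels[0]: f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                    glabels[1]: f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                    f"{glabels[0]}_missing": n_miss[glabels[0]],
                    f"{glabels[1]}_missing": n_miss[glabels[1]],
                    "test": "Welch t",
                    "p_value": float(p),
                }
            )
        else:
            tab = pd.crosstab(s.astype("string"), groups)
            levels = list(tab.index)
            if tab.shape[0] < 2:
                p = np.nan
            else:
                chi2, p, _, _ = stats.chi2_contingency(
                    tab.to_numpy(), correction=False
                )
            denom = {g: int(tab[g].sum()) for g in glabels}
            for lev in levels:
                rec = {"covariate": cov, "level": str(lev)}
                for g in glabels:
                    cnt = int(tab.loc[lev, g])
                    pct = round_half_up(100.0 * cnt / denom[g]) if denom[g] else np.nan
                    rec[g] = f"{cnt} ({pct}%)"
                    rec[f"{g}_pct"] = pct
                rec[f"{glabels[0]}_missing"] = n_miss[glabels[0]]
                rec[f"{glabels[1]}_missing"] = n_miss[glabels[1]]
                rec["test"] = "chi-squared"
                rec["p_value"] = float(p) if np.isfinite(p) else np.nan
                rows.append(rec)
    return pd.DataFrame(rows)
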