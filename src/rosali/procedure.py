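"""The two-stage item-level invariance detection procedure (ROSALI).

Algorithm 1 (cross-sectional, first time point) tests for differential item
functioning between the two groups; algorithm 2 (longitudinal, carrying the
DIF structure forward) tests for recalibration response shift between the
two time points.  Each algorithm starts with an overall likelihood-ratio
test of the fully non-invariant against the fully invariant model and, if
the overall test rejects, iteratively frees the thresholds of the item with
the most significant Bonferroni-adjusted test, re-fitting after every flag
so that each iteration conditions on the effects found before it.  A scan
stops when no adjusted test is significant, or once all but one item have
been flagged (freeing the last item would only re-express the group or
time effect).

Flagged items are characterized by nested restrictions tested at the same
alpha: for RS, whether the shift is shared by both groups or group-specific
(and whether a group shifts at all); in either algorithm, whether the shift
is uniform (one common offset for all thresholds, a horizontal translation
of the item characteristic curve) or non-uniform.  The accepted form enters
the working model for subsequent iterations.

The final step fits the adjusted longitudinal model (all flagged effects
freed) and the naive fully invariant model, reporting group effects at each
time point and time effects per group side by side under both assumptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ResponseData
from .design import ModelSpec, RsTerm
from .model import (
    CrossSectionalPCM,
    LongitudinalPCM,
    PCMResults,
    TestResult,
    likelihood_ratio_test,
)

__all__ = ["RosaliAnalysis", "DetectionReport", "FlaggedItem"]


def _adjust(tr: TestResult, k: int) -> TestResult:
    return TestResult(
        statistic=tr.statistic,
        df=tr.df,
        p_value=tr.p_value,
        p_adjusted=min(1.0, tr.p_value * k),
        comparison=tr.comparison,
    )


@dataclass
class FlaggedItem:
    """One item flagged by a scan, with its characterization."""

    item: str
    test: TestResult  # Bonferroni-adjusted flagging test (free thresholds)
    shift_type: str  # "uniform" | "non_uniform"
    group_scope: str | None = None  # RS only: "similar_in_both" | "group_specific"
    estimates: dict = field(default_factory=dict)  # param -> {estimate, se}
    characterization: list = field(default_factory=list)  # TestResults

    def to_dict(self) -> dict:
        return {
            "item": self.item,
            "test": self.test.to_dict(),
            "shift_type": self.shift_type,
            "group_scope": self.group_scope,
            "estimates": self.estimates,
            "characterization": [t.to_dict() for t in self.characterization],
        }


@dataclass
class DetectionReport:
    """Ordered log of every test and the resulting effect estimates."""

    alpha: float
    quadrature: int
    overall_dif: TestResult | None = None
    dif_items: list[FlaggedItem] = field(default_factory=list)
    overall_rs: TestResult | None = None
    rs_items: list[FlaggedItem] = field(default_factory=list)
    effects: pd.DataFrame | None = None  # adjusted & invariant side by side
    final_structure: str = ""
    iteration_log: list[dict] = field(default_factory=list)
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "quadrature": self.quadrature,
            "overall_dif": self.overall_dif.to_dict() if self.overall_dif else None,
            "dif_items": [f.to_dict() for f in self.dif_items],
            "overall_rs": self.overall_rs.to_dict() if self.overall_rs else None,
            "rs_items": [f.to_dict() for f in self.rs_items],
            "effects": (
                None
                if self.effects is None
                else {
                    str(k): {
                        c: (None if pd.isna(v) else float(v))
                        for c, v in row.items()
                    }
                    for k, row in self.effects.to_dict("index").items()
                }
            ),
            "final_structure": self.final_structure,
            "iteration_log": self.iteration_log,
            "n_excluded": self.n_excluded,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_markdown(self) -> str:
        lines = ["# Item-level invariance (DIF / response shift) report", ""]
        lines.append(f"alpha = {self.alpha}, Gauss-Hermite order = {self.quadrature}")
        if self.n_excluded:
            lines.append(f"persons excluded for all-missing responses: {self.n_excluded}")
        lines.append("")
        lines.append("## Algorithm 1 - differential item functioning at T1")
        if self.overall_dif is None:
            lines.append("not run")
        else:
            t = self.overall_dif
            lines.append(
                f"overall test: chi2({t.df}) = {t.statistic:.3f}, p = {t.p_value:.4g}"
            )
            if not self.dif_items:
                lines.append("no item-level DIF retained.")
            for f in self.dif_items:
                lines.append(
                    f"- **{f.item}**: {f.shift_type} DIF "
                    f"(adjusted p = {f.test.p_adjusted:.4g}); offsets: "
                    + ", ".join(
                        f"{k} = {v['estimate']:+.3f}"
                        + (f" (SE {v['se']:.3f})" if v.get("se") else "")
                        for k, v in f.estimates.items()
                    )
                )
        lines.append("")
        lines.append("## Algorithm 2 - recalibration response shift T1 -> T2")
        if self.overall_rs is None:
            lines.append("not run")
        else:
            t = self.overall_rs
            lines.append(
                f"overall test: chi2({t.df}) = {t.statistic:.3f}, p = {t.p_value:.4g}"
            )
            if not self.rs_items:
                lines.append("no item-level recalibration retained.")
            for f in self.rs_items:
                lines.append(
                    f"- **{f.item}**: {f.shift_type} shift, scope {f.group_scope} "
                    f"(adjusted p = {f.test.p_adjusted:.4g}); shifts: "
                    + ", ".join(
                        f"{k} = {v['estimate']:+.3f}"
                        + (f" (SE {v['se']:.3f})" if v.get("se") else "")
                        for k, v in f.estimates.items()
                    )
                )
        lines.append("")
        lines.append("## Group and time effects on the latent construct")
        if self.effects is not None:
            lines.append("")
            lines.append("```")
            lines.append(self.effects.round(3).to_string())
            lines.append("```")
        lines.append("")
        lines.append(f"final model structure: {self.final_structure}")
        return "\n".join(lines)


class RosaliAnalysis:
    """Runs the full two-algorithm detection on a two-time-point dataset.

    Parameters
    ----------
    data : ResponseData with two time points
    alpha : familywise level for every test (overall gates, scans with
        per-iteration Bonferroni adjustment, characterizations)
    quadrature : Gauss-Hermite order per latent dimension
    require_overall_test : if True (default) a scan only runs when the
        overall non-invariance test is significant; set False to scan
        unconditionally.
    """

    def __init__(
        self,
        data: ResponseData,
        alpha: float = 0.05,
        quadrature: int = 30,
        require_overall_test: bool = True,
    ):
        if data.n_times != 2:
            raise ValueError("the full procedure needs two time points")
        if data.n_items < 2:
            raise ValueError(
                "invariance testing needs at least two items: with a single "
                "item, the fully non-invariant model is indistinguishable "
                "from a group/time effect"
            )
        self.data = data
        self.alpha = float(alpha)
        self.quadrature = int(quadrature)
        self.require_overall_test = bool(require_overall_test)
        self.iteration_log: list[dict] = []

    # ------------------------------------------------------------------ #
    # fitting helpers (warm starts + audit log)
    # ------------------------------------------------------------------ #
    def _fit(self, step: str, data, spec: ModelSpec,
             warm: PCMResults | None = None) -> PCMResults:
        cls = LongitudinalPCM if spec.longitudinal else CrossSectionalPCM
        model = cls(data, spec, quadrature=self.quadrature)
        x0 = model.start_params()
        if warm is not None:
            prev = warm.params
            for k, name in enumerate(model.param_names):
                if name in prev.index:
                    x0[k] = prev[name]
        res = model.fit(start_params=x0)
        self.iteration_log.append(
            {
                "step": step,
                "model": spec.describe(),
                "loglik": res.llf,
                "n_free_parameters": res.df_model,
                "converged": bool(res.converged),
            }
        )
        return res

    # ------------------------------------------------------------------ #
    # algorithm 1: DIF at T1
    # ------------------------------------------------------------------ #
    def detect_dif(self):
        """Overall DIF test and iterative item scan at the first time point.

        Returns (overall TestResult, flagged items, final DIF dict,
        final cross-sectional fit).
        """
        d1 = self.data.at_time(self.data.time_labels[0])
        spec_inv = ModelSpec.for_data(d1, longitudinal=False)
        fit_inv = self._fit("dif_overall:invariant", d1, spec_inv)
        spec_all = spec_inv.all_dif("free")
        fit_all = self._fit("dif_overall:all_free", d1, spec_all, warm=fit_inv)
        overall = likelihood_ratio_test(fit_inv, fit_all)

        flagged: list[FlaggedItem] = []
        current_spec, current_fit = spec_inv, fit_inv
        run_scan = overall.significant(self.alpha) or not self.require_overall_test
        J = self.data.n_items
        while run_scan and len(flagged) < J - 1:
            done = {f.item for f in flagged}
            candidates = [it for it in self.data.item_ids if it not in done]
            k = len(candidates)
            best = None
            for item in candidates:
                cand_spec = current_spec.with_dif(item, "free")
                cand_fit = self._fit(
                    f"dif_scan:{item}", d1, cand_spec, warm=current_fit
                )
                tr = _adjust(likelihood_ratio_test(current_fit, cand_fit), k)
                if best is None or (tr.p_adjusted, tr.p_value) < (
                    best[1].p_adjusted,
                    best[1].p_value,
                ):
                    best = (item, tr, cand_spec, cand_fit)
            item, tr, cand_spec, cand_fit = best
            if not tr.significant(self.alpha):
                break
            # uniform-vs-non-uniform characterization at the same alpha
            uni_spec = current_spec.with_dif(item, "uniform")
            uni_fit = self._fit(f"dif_char:{item}:uniform", d1, uni_spec, warm=cand_fit)
            char = likelihood_ratio_test(uni_fit, cand_fit)
            if char.p_value >= self.alpha:
                shift_type, current_spec, current_fit = "uniform", uni_spec, uni_fit
            else:
                shift_type, current_spec, current_fit = "non_uniform", cand_spec, cand_fit
            flagged.append(
                FlaggedItem(item=item, test=tr, shift_type=shift_type,
                            characterization=[char])
            )

        if flagged:
            self._attach_estimates(flagged, current_fit, prefix="dif_")
        return overall, flagged, dict(current_spec.dif), current_fit

    # ------------------------------------------------------------------ #
    # algorithm 2: recalibration RS
    # ------------------------------------------------------------------ #
    def detect_rs(self, dif: dict, warm: PCMResults | None = None):
        """Overall RS test and iterative scan, conditioning on the DIF
        structure found at T1 (carried unchanged to T2)."""
        data = self.data
        g0, g1 = data.group_labels
        spec_inv = ModelSpec.for_data(data, longitudinal=True, dif=dif)
        fit_inv = self._fit("rs_overall:invariant", data, spec_inv, warm=warm)
        spec_all = spec_inv.all_rs("free")
        fit_all = self._fit("rs_overall:all_free", data, spec_all, warm=fit_inv)
        overall = likelihood_ratio_test(fit_inv, fit_all)

        flagged: list[FlaggedItem] = []
        current_spec, current_fit = spec_inv, fit_inv
        run_scan = overall.significant(self.alpha) or not self.require_overall_test
        J = data.n_items
        free_both = RsTerm("by_group", group_forms=((g0, "free"), (g1, "free")))
        while run_scan and len(flagged) < J - 1:
            done = {f.item for f in flagged}
            candidates = [it for it in data.item_ids if it not in done]
            k = len(candidates)
            best = None
            for item in candidates:
                cand_spec = current_spec.with_rs(item, free_both)
                cand_fit = self._fit(
                    f"rs_scan:{item}", data, cand_spec, warm=current_fit
                )
                tr = _adjust(likelihood_ratio_test(current_fit, cand_fit), k)
                if best is None or (tr.p_adjusted, tr.p_value) < (
                    best[1].p_adjusted,
                    best[1].p_value,
                ):
                    best = (item, tr, cand_spec, cand_fit)
            item, tr, cand_spec, cand_fit = best
            if not tr.significant(self.alpha):
                break
            flag, current_spec, current_fit = self._characterize_rs(
                item, tr, current_spec, cand_spec, cand_fit
            )
            flagged.append(flag)

        if flagged:
            self._attach_estimates(flagged, current_fit, prefix="rs_")
        return overall, flagged, current_spec, current_fit

    def _characterize_rs(self, item, tr, base_spec, cand_spec, cand_fit):
        """Scope (shared vs group-specific, including one-group-only) and
        form (uniform vs non-uniform) of a flagged time shift."""
        data = self.data
        g0, g1 = data.group_labels
        char: list[TestResult] = []

        # scope: one shift vector shared by both groups?
        shared_spec = base_spec.with_rs(item, RsTerm("shared", "free"))
        shared_fit = self._fit(f"rs_char:{item}:shared", data, shared_spec, warm=cand_fit)
        scope_test = likelihood_ratio_test(shared_fit, cand_fit)
        char.append(scope_test)

        if scope_test.p_value >= self.alpha:
            scope = "similar_in_both"
            uni_spec = base_spec.with_rs(item, RsTerm("shared", "uniform"))
            uni_fit = self._fit(
                f"rs_char:{item}:shared_uniform", data, uni_spec, warm=shared_fit
            )
            form_test = likelihood_ratio_test(uni_fit, shared_fit)
            char.append(form_test)
            if form_test.p_value >= self.alpha:
                spec, fit, shift_type = uni_spec, uni_fit, "uniform"
            else:
                spec, fit, shift_type = shared_spec, shared_fit, "non_uniform"
        else:
            scope = "group_specific"
            # per group: does the group shift at all, and if so, uniformly?
            forms: dict[str, str | None] = {g0: "free", g1: "free"}
            spec, fit = cand_spec, cand_fit
            for g in (g0, g1):
                others = [
                    (gg, ff) for gg, ff in forms.items() if ff is not None and gg != g
                ]
                if others:  # dropping g entirely
                    drop_term = RsTerm("by_group", group_forms=tuple(others))
                    drop_spec = base_spec.with_rs(item, drop_term)
                    drop_fit = self._fit(
                        f"rs_char:{item}:no_{g}", data, drop_spec, warm=fit
                    )
                    drop_test = likelihood_ratio_test(drop_fit, fit)
                    char.append(drop_test)
                    if drop_test.p_value >= self.alpha:
                        forms[g] = None
                        spec, fit = drop_spec, drop_fit
                        continue
                uni_forms = tuple(
                    (gg, "uniform" if gg == g else ff)
                    for gg, ff in forms.items()
                    if ff is not None
                )
                uni_spec = base_spec.with_rs(item, RsTerm("by_group", group_forms=uni_forms))
                uni_fit = self._fit(f"rs_char:{item}:{g}_uniform", data, uni_spec, warm=fit)
                uni_test = likelihood_ratio_test(uni_fit, fit)
                char.append(uni_test)
                if uni_test.p_value >= self.alpha:
                    forms[g] = "uniform"
                    spec, fit = uni_spec, uni_fit
            active = [f for f in forms.values() if f is not None]
            shift_type = "uniform" if all(f == "uniform" for f in active) else "non_uniform"

        flag = FlaggedItem(
            item=item, test=tr, shift_type=shift_type, group_scope=scope,
            characterization=char,
        )
        return flag, spec, fit

    # ------------------------------------------------------------------ #
    @staticmethod
    def _attach_estimates(flagged, final_fit: PCMResults, prefix: str):
        """Offset/shift estimates (with SE from the final model of the
        algorithm) for every flagged item."""
        try:
            bse = final_fit.bse
        except Exception:  # non-invertible information: report estimates only
            bse = pd.Series(np.nan, index=final_fit.params.index)
        for f in flagged:
            names = [
                n
                for n in final_fit.params.index
                if n == f"{prefix}{f.item}" or n.startswith(f"{prefix}{f.item}_")
            ]
            f.estimates = {
                n: {
                    "estimate": float(final_fit.params[n]),
                    "se": None if pd.isna(bse[n]) else float(bse[n]),
                }
                for n in names
            }

    def estimate_effects(self, final_spec: ModelSpec,
                         adjusted_fit: PCMResults | None = None) -> pd.DataFrame:
        """Group effects at T1/T2 and time effects per group, estimated under
        the detected structure ("adjusted") and under full invariance
        ("invariant"), side by side."""
        data = self.data
        if adjusted_fit is None or adjusted_fit.spec is not final_spec:
            adjusted_fit = self._fit("effects:adjusted", data, final_spec)
        else:
            self.iteration_log.append(
                {
                    "step": "effects:adjusted",
                    "model": final_spec.describe(),
                    "loglik": adjusted_fit.llf,
                    "n_free_parameters": adjusted_fit.df_model,
                    "converged": bool(adjusted_fit.converged),
                }
            )
        inv_spec = ModelSpec.for_data(data, longitudinal=True)
        invariant_fit = self._fit("effects:invariant", data, inv_spec)

        g0, g1 = data.group_labels
        t1, t2 = data.time_labels
        rows = {}
        for label, getter in [
            (f"group_effect_{t1}", lambda r: r.group_effect(0)),
            (f"group_effect_{t2}", lambda r: r.group_effect(1)),
            (f"time_effect_{g0}", lambda r: r.time_effect(0)),
            (f"time_effect_{g1}", lambda r: r.time_effect(1)),
        ]:
            ea, sa, pa = getter(adjusted_fit)
            ei, si, pi = getter(invariant_fit)
            rows[label] = {
                "adjusted_estimate": ea,
                "adjusted_se": np.nan if sa is None else sa,
                "adjusted_p": np.nan if pa is None else pa,
                "invariant_estimate": ei,
                "invariant_se": np.nan if si is None else si,
                "invariant_p": np.nan if pi is None else pi,
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    # ------------------------------------------------------------------ #
    def run(self) -> DetectionReport:
        """Execute both algorithms and the final effect estimation."""
        self.iteration_log = []
        overall_dif, dif_items, dif, cs_fit = self.detect_dif()
        overall_rs, rs_items, final_spec, final_fit = self.detect_rs(dif, warm=cs_fit)
        effects = self.estimate_effects(final_spec, adjusted_fit=final_fit)
        # keep the adjusted fit around for curve export / inspection
        self.final_spec_ = final_spec
        self.final_fit_ = final_fit
        return DetectionReport(
            alpha=self.alpha,
            quadrature=self.quadrature,
            overall_dif=overall_dif,
            dif_items=dif_items,
            overall_rs=overall_rs,
            rs_items=rs_items,
            effects=effects,
            final_structure=final_spec.describe(),
            iteration_log=self.iteration_log,
            n_excluded=self.data.n_excluded,
        )
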