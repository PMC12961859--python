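"""Model specifications: which items are invariant, and what is estimable.

A :class:`ModelSpec` declares, per item, whether its thresholds differ
between groups (DIF) and/or move between the two time points (recalibration
response shift), and in what form:

- DIF form ``"free"`` adds one offset per threshold in the non-reference
  group; ``"uniform"`` adds a single common offset (a horizontal shift of
  the whole item).  DIF applies at both time points.
- An RS term has a scope — ``"shared"`` (both groups shift identically) or
  ``"by_group"`` (per-group shifts, possibly in only one group) — and a form
  (``"free"`` or ``"uniform"``) per affected group.

Identifiability constraints follow from the declarations: the reference-cell
mean is always 0; if every item carries DIF the group effect at T1 is not
estimable and is fixed at 0; if every item shifts over time within a group,
that group's time effect is fixed at 0.  The free-parameter count is fully
determined by the spec, which is what nested likelihood-ratio tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import MISSING, ResponseData

__all__ = ["RsTerm", "ModelSpec", "Parameterization"]

_FORM_RANK = {"uniform": 1, "free": 2}


@dataclass(frozen=True)
class RsTerm:
    """Time-shift declaration for one item.

    scope:
        ``"shared"`` — one shift (vector or scalar) applied in both groups;
        ``"by_group"`` — separate shifts per affected group.
    form:
        for shared scope: ``"free"`` (one shift per threshold) or
        ``"uniform"`` (a single scalar offset).
    group_forms:
        for by_group scope: ``((group_label, form), ...)`` for each affected
        group, in group order.
    """

    scope: str
    form: str = "free"
    group_forms: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.scope not in ("shared", "by_group"):
            raise ValueError(f"unknown RS scope {self.scope!r}")
        if self.scope == "shared":
            if self.form not in _FORM_RANK:
                raise ValueError(f"unknown RS form {self.form!r}")
        else:
            if not self.group_forms:
                raise ValueError("by_group RS term needs group_forms")
            for _, f in self.group_forms:
                if f not in _FORM_RANK:
                    raise ValueError(f"unknown RS form {f!r}")

    def affects(self, group_label: str) -> bool:
        if self.scope == "shared":
            return True
        return any(g == group_label for g, _ in self.group_forms)

    def form_for(self, group_label: str) -> str | None:
        if self.scope == "shared":
            return self.form
        for g, f in self.group_forms:
            if g == group_label:
                return f
        return None


def _rs_nested(r: RsTerm | None, f: RsTerm | None, groups) -> bool:
    """Is the RS shift set of ``r`` contained in that of ``f``?"""
    if r is None:
        return True
    if f is None:
        return False
    if f.scope == "shared":
        if r.scope != "shared":
            return False
        return _FORM_RANK[r.form] <= _FORM_RANK[f.form]
    # f is by_group: containment groupwise; a shared r is the tied diagonal,
    # contained iff every group is affected in f with at least r's form rank.
    for g in groups:
        rf = r.form_for(g)
        ff = f.form_for(g)
        if rf is None:
            continue
        if ff is None or _FORM_RANK[rf] > _FORM_RANK[ff]:
            return False
    return True


@dataclass
class ModelSpec:
    """Declarative structure of a cross-sectional or longitudinal PCM."""

    item_ids: tuple[str, ...]
    n_categories: tuple[int, ...]
    longitudinal: bool
    group_labels: tuple[str, str] = ("G0", "G1")
    time_labels: tuple[str, ...] = ("T1", "T2")
    dif: dict = field(default_factory=dict)  # item -> "free" | "uniform"
    rs: dict = field(default_factory=dict)  # item -> RsTerm

    def __post_init__(self):
        self.item_ids = tuple(self.item_ids)
        self.n_categories = tuple(int(m) for m in self.n_categories)
        for it, form in self.dif.items():
            if it not in self.item_ids:
                raise ValueError(f"DIF declared for unknown item {it!r}")
            if form not in _FORM_RANK:
                raise ValueError(f"unknown DIF form {form!r}")
        for it, term in self.rs.items():
            if it not in self.item_ids:
                raise ValueError(f"RS declared for unknown item {it!r}")
            if not isinstance(term, RsTerm):
                raise TypeError("rs values must be RsTerm")
        if self.rs and not self.longitudinal:
            raise ValueError("RS terms require a longitudinal spec")
        if self.longitudinal and len(self.time_labels) != 2:
            raise ValueError("longitudinal spec needs two time labels")

    # ------------------------------------------------------------------ #
    @classmethod
    def for_data(
        cls,
        data: ResponseData,
        longitudinal: bool | None = None,
        dif: dict | None = None,
        rs: dict | None = None,
    ) -> "ModelSpec":
        if longitudinal is None:
            longitudinal = data.n_times == 2
        return cls(
            item_ids=data.item_ids,
            n_categories=data.n_categories,
            longitudinal=longitudinal,
            group_labels=data.group_labels,
            time_labels=data.time_labels if longitudinal else data.time_labels[:1],
            dif=dict(dif or {}),
            rs=dict(rs or {}),
        )

    def with_dif(self, item: str, form: str = "free") -> "ModelSpec":
        new = dict(self.dif)
        new[item] = form
        return replace(self, dif=new, rs=dict(self.rs))

    def with_rs(self, item: str, term: RsTerm) -> "ModelSpec":
        new = dict(self.rs)
        new[item] = term
        return replace(self, dif=dict(self.dif), rs=new)

    def all_dif(self, form: str = "free") -> "ModelSpec":
        return replace(
            self, dif={it: form for it in self.item_ids}, rs=dict(self.rs)
        )

    def all_rs(self, form: str = "free") -> "ModelSpec":
        """Every item shifting over time, separately per group (fully
        non-invariant longitudinal model)."""
        term = RsTerm(
            "by_group", group_forms=tuple((g, form) for g in self.group_labels)
        )
        return replace(
            self, dif=dict(self.dif), rs={it: term for it in self.item_ids}
        )

    # ------------------------------------------------------------------ #
    @property
    def all_items_dif(self) -> bool:
        return set(self.dif) == set(self.item_ids)

    def rs_on_all_items(self, group_label: str) -> bool:
        return all(
            it in self.rs and self.rs[it].affects(group_label)
            for it in self.item_ids
        )

    def parameterization(self) -> "Parameterization":
        return Parameterization(self)

    @property
    def n_free_parameters(self) -> int:
        return len(self.parameterization().names)

    def is_nested_in(self, other: "ModelSpec") -> bool:
        """Structural nesting: every model in this spec's family is also in
        ``other``'s.  Identifiability swaps (a freed mean absorbed by common
        threshold offsets) are handled by construction since latent-mean
        constraints are derived from the item declarations."""
        if (
            self.item_ids != other.item_ids
            or self.longitudinal != other.longitudinal
            or self.group_labels != other.group_labels
        ):
            return False
        for it in self.item_ids:
            r, f = self.dif.get(it), other.dif.get(it)
            if r is not None and (
                f is None or _FORM_RANK[r] > _FORM_RANK[f]
            ):
                return False
            if not _rs_nested(self.rs.get(it), other.rs.get(it), self.group_labels):
                return False
        return True

    def describe(self) -> str:
        kind = "longitudinal" if self.longitudinal else "cross-sectional"
        bits = [kind]
        if self.dif:
            bits.append(
                "dif={"
                + ", ".join(f"{it}:{f}" for it, f in sorted(self.dif.items()))
                + "}"
            )
        if self.rs:
            parts = []
            for it, term in sorted(self.rs.items()):
                if term.scope == "shared":
                    parts.append(f"{it}:shared/{term.form}")
                else:
                    gf = ",".join(f"{g}/{f}" for g, f in term.group_forms)
                    parts.append(f"{it}:by_group[{gf}]")
            bits.append("rs={" + ", ".join(parts) + "}")
        if len(bits) == 1:
            bits.append("invariant")
        return " ".join(bits)


class Parameterization:
    """Maps the flat free-parameter vector to natural model parameters.

    Threshold cells resolve to sums of free parameters (base thresholds plus
    any DIF offset and/or RS shift), latent means resolve to a parameter
    index or a fixed 0, variances are parameterized as logs and the T1-T2
    correlation as its inverse hyperbolic tangent so the optimizer works on
    an unconstrained space.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.names: list[str] = []
        self.n_times = 2 if spec.longitudinal else 1
        J = len(spec.item_ids)
        g1 = spec.group_labels[1]

        def add(name: str) -> int:
            self.names.append(name)
            return len(self.names) - 1

        base_ix = {}  # (j, p) -> index
        for j, it in enumerate(spec.item_ids):
            for p in range(1, spec.n_categories[j]):
                base_ix[(j, p)] = add(f"delta_{it}_{p}")

        dif_ix = {}  # (j, p) -> index (uniform: same index for all p)
        for j, it in enumerate(spec.item_ids):
            form = spec.dif.get(it)
            if form is None:
                continue
            if form == "uniform":
                k = add(f"dif_{it}")
                for p in range(1, spec.n_categories[j]):
                    dif_ix[(j, p)] = k
            else:
                for p in range(1, spec.n_categories[j]):
                    dif_ix[(j, p)] = add(f"dif_{it}_{p}")

        rs_ix = {}  # (j, g, p) -> index
        for j, it in enumerate(spec.item_ids):
            term = spec.rs.get(it)
            if term is None:
                continue
            if term.scope == "shared":
                if term.form == "uniform":
                    k = add(f"rs_{it}")
                    for g in (0, 1):
                        for p in range(1, spec.n_categories[j]):
                            rs_ix[(j, g, p)] = k
                else:
                    for p in range(1, spec.n_categories[j]):
                        k = add(f"rs_{it}_{p}")
                        rs_ix[(j, 0, p)] = k
                        rs_ix[(j, 1, p)] = k
            else:
                for glab, form in term.group_forms:
                    g = spec.group_labels.index(glab)
                    if form == "uniform":
                        k = add(f"rs_{it}_{glab}")
                        for p in range(1, spec.n_categories[j]):
                            rs_ix[(j, g, p)] = k
                    else:
                        for p in range(1, spec.n_categories[j]):
                            rs_ix[(j, g, p)] = add(f"rs_{it}_{glab}_{p}")

        # latent means
        t1, = spec.time_labels[:1]
        self.mu_ix: dict[tuple[int, int], int | None] = {(0, 0): None}
        if spec.all_items_dif:
            self.mu_ix[(1, 0)] = None
        else:
            self.mu_ix[(1, 0)] = add(f"mu_{g1}_{t1}")
        if spec.longitudinal:
            t2 = spec.time_labels[1]
            if spec.rs_on_all_items(spec.group_labels[0]):
                self.mu_ix[(0, 1)] = None  # time effect in G0 fixed at 0
            else:
                self.mu_ix[(0, 1)] = add(f"mu_{spec.group_labels[0]}_{t2}")
            if spec.rs_on_all_items(g1):
                # time effect in G1 fixed at 0: tie the T2 mean to the T1 mean
                self.mu_ix[(1, 1)] = self.mu_ix[(1, 0)]
            else:
                self.mu_ix[(1, 1)] = add(f"mu_{g1}_{t2}")

        # latent (co)variance
        if spec.longitudinal:
            self.var_ix = [add("log_var_T1"), add("log_var_T2")]
            self.rho_ix = add("atanh_corr")
        else:
            self.var_ix = [add("log_var")]
            self.rho_ix = None

        # threshold index lists per (g, t, j): list over p of tuple of indices
        self.delta_ix: dict[tuple[int, int, int], list[tuple[int, ...]]] = {}
        for g in (0, 1):
            for t in range(self.n_times):
                for j in range(J):
                    per_p = []
                    for p in range(1, spec.n_categories[j]):
                        ix = [base_ix[(j, p)]]
                        if g == 1 and (j, p) in dif_ix:
                            ix.append(dif_ix[(j, p)])
                        if t == 1 and (j, g, p) in rs_ix:
                            ix.append(rs_ix[(j, g, p)])
                        per_p.append(tuple(ix))
                    self.delta_ix[(g, t, j)] = per_p

    @property
    def n_params(self) -> int:
        return len(self.names)

    # ------------------------------------------------------------------ #
    def unpack(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        spec = self.spec
        J = len(spec.item_ids)
        delta = {}
        for g in (0, 1):
            for t in range(self.n_times):
                delta[(g, t)] = [
                    np.array([x[list(ix)].sum() for ix in self.delta_ix[(g, t, j)]])
                    for j in range(J)
                ]
        mu = np.zeros((2, self.n_times))
        for (g, t), k in self.mu_ix.items():
            if k is not None:
                mu[g, t] = x[k]
        var = np.exp(np.array([x[k] for k in self.var_ix]))
        rho = np.tanh(x[self.rho_ix]) if self.rho_ix is not None else 0.0
        return delta, mu, var, rho

    def chain(self, score, x: np.ndarray) -> np.ndarray:
        """Pull the natural-parameter gradient back to the free vector."""
        grad = np.zeros(len(self.names))
        for (g, t, j), per_p in self.delta_ix.items():
            dj = score.d_delta[(g, t, j)]
            for p0, ix in enumerate(per_p):
                for k in ix:
                    grad[k] += dj[p0]
        for (g, t), k in self.mu_ix.items():
            if k is not None:
                grad[k] += score.d_mu[g, t]
        for t, k in enumerate(self.var_ix):
            grad[k] += score.d_logvar[t]
        if self.rho_ix is not None:
            rho = np.tanh(x[self.rho_ix])
            grad[self.rho_ix] += score.d_rho * (1.0 - rho**2)
        return grad

    # ------------------------------------------------------------------ #
    def start_values(self, data: ResponseData) -> np.ndarray:
        """Cheap starting point: pooled adjacent-category logits for the
        base thresholds, zero offsets and means, unit variances, and a
        moderate positive retest correlation."""
        spec = self.spec
        x0 = np.zeros(len(self.names))
        for j, it in enumerate(spec.item_ids):
            xj = data.responses[:, j, :]
            xj = xj[xj != MISSING]
            counts = np.bincount(xj, minlength=spec.n_categories[j]).astype(float)
            for p in range(1, spec.n_categories[j]):
                k = self.names.index(f"delta_{it}_{p}")
                x0[k] = np.log(counts[p - 1] + 0.5) - np.log(counts[p] + 0.5)
        if self.rho_ix is not None:
            x0[self.rho_ix] = np.arctanh(0.5)
        return x0
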