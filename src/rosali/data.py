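"""Polytomous item-response data for two groups and up to two time points.

The in-memory container is a dense integer array (person x item x time) with
``-1`` encoding a missing response, plus per-person group labels.  This layout
keeps the marginal-likelihood engine simple and fast while the public
constructors (:meth:`ResponseData.from_dataframe`, :meth:`ResponseData.read_csv`)
speak the tabular dialect questionnaire data are usually exported in: one row
per person x time point, one column per item.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ResponseData"]

MISSING = -1


class ResponseData:
    """Person x item x time polytomous responses with group labels.

    Parameters
    ----------
    responses : ndarray of int, shape (n_persons, n_items, n_times)
        Category codes ``0..M_j``; ``-1`` marks a missing response.
    groups : ndarray of int, shape (n_persons,)
        ``0`` for the reference group, ``1`` for the other group.
    item_ids : sequence of str
    n_categories : sequence of int
        Number of response categories ``M_j + 1`` per item (>= 2).
    group_labels : (str, str)
        Labels, reference group first.
    time_labels : sequence of str
        One label (cross-sectional) or two (longitudinal, T1 first).
    person_ids : sequence, optional
    n_excluded : int
        Count of persons dropped at ingestion because they had no
        non-missing response at any time point.
    """

    def __init__(
        self,
        responses: np.ndarray,
        groups: np.ndarray,
        item_ids: Sequence[str],
        n_categories: Sequence[int],
        group_labels: tuple[str, str] = ("G0", "G1"),
        time_labels: Sequence[str] = ("T1", "T2"),
        person_ids: Sequence | None = None,
        n_excluded: int = 0,
    ):
        responses = np.asarray(responses, dtype=np.int64)
        if responses.ndim != 3:
            raise ValueError("responses must be (n_persons, n_items, n_times)")
        self.responses = responses
        self.groups = np.asarray(groups, dtype=np.int64)
        if self.groups.shape != (responses.shape[0],):
            raise ValueError("groups must have one entry per person")
        if not np.isin(self.groups, [0, 1]).all():
            raise ValueError("group codes must be 0 (reference) or 1")
        self.item_ids = tuple(str(i) for i in item_ids)
        self.n_categories = tuple(int(m) for m in n_categories)
        if len(self.item_ids) != responses.shape[1]:
            raise ValueError("item_ids length does not match responses")
        if len(self.n_categories) != responses.shape[1]:
            raise ValueError("n_categories length does not match responses")
        if any(m < 2 for m in self.n_categories):
            raise ValueError("each item needs at least 2 categories")
        self.group_labels = tuple(group_labels)
        if len(self.group_labels) != 2:
            raise ValueError("exactly two group labels required")
        self.time_labels = tuple(time_labels)
        if len(self.time_labels) != responses.shape[2]:
            raise ValueError("time_labels length does not match responses")
        if person_ids is None:
            person_ids = np.arange(responses.shape[0])
        self.person_ids = np.asarray(person_ids)
        self.n_excluded = int(n_excluded)
        self._validate_codes()

    def _validate_codes(self) -> None:
        for j, m in enumerate(self.n_categories):
            xj = self.responses[:, j, :]
            bad = (xj != MISSING) & ((xj < 0) | (xj >= m))
            if bad.any():
                i, t = np.argwhere(bad)[0]
                raise ValueError(
                    f"response {xj[i, t]} out of range 0..{m - 1} for item "
                    f"'{self.item_ids[j]}' (person {self.person_ids[i]!r}, "
                    f"time {self.time_labels[t]})"
                )

    # ------------------------------------------------------------------ #
    # basic properties
    # ------------------------------------------------------------------ #
    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_times(self) -> int:
        return self.responses.shape[2]

    @property
    def group_sizes(self) -> tuple[int, int]:
        return int((self.groups == 0).sum()), int((self.groups == 1).sum())

    def observed_mask(self) -> np.ndarray:
        return self.responses != MISSING

    def __repr__(self) -> str:  # pragma: no cover
        g0, g1 = self.group_sizes
        return (
            f"<ResponseData {self.n_persons} persons "
            f"({self.group_labels[0]}={g0}, {self.group_labels[1]}={g1}), "
            f"{self.n_items} items, times={self.time_labels}>"
        )

    # ------------------------------------------------------------------ #
    # views / derived datasets
    # ------------------------------------------------------------------ #
    def at_time(self, label: str) -> "ResponseData":
        """Cross-sectional view restricted to one time point."""
        if label not in self.time_labels:
            raise KeyError(f"unknown time label {label!r}")
        t = self.time_labels.index(label)
        return ResponseData(
            self.responses[:, :, t : t + 1],
            self.groups,
            self.item_ids,
            self.n_categories,
            self.group_labels,
            (label,),
            self.person_ids,
            self.n_excluded,
        )

    def drop_items(self, items: Sequence[str]) -> "ResponseData":
        keep = [j for j, it in enumerate(self.item_ids) if it not in set(items)]
        if not keep:
            raise ValueError("cannot drop every item")
        return ResponseData(
            self.responses[:, keep, :],
            self.groups,
            [self.item_ids[j] for j in keep],
            [self.n_categories[j] for j in keep],
            self.group_labels,
            self.time_labels,
            self.person_ids,
            self.n_excluded,
        )

    def category_counts(self, item: str) -> pd.DataFrame:
        """Counts of each category per (group, time) cell for one item."""
        j = self.item_ids.index(item)
        rows = []
        for g, glab in enumerate(self.group_labels):
            for t, tlab in enumerate(self.time_labels):
                x = self.responses[self.groups == g, j, t]
                x = x[x != MISSING]
                counts = np.bincount(x, minlength=self.n_categories[j])
                rows.append([glab, tlab, *counts])
        cols = ["group", "time"] + [f"cat{c}" for c in range(self.n_categories[j])]
        return pd.DataFrame(rows, columns=cols)

    # ------------------------------------------------------------------ #
    # tabular I/O
    # ------------------------------------------------------------------ #
    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        items: Sequence[str] | Mapping[str, int],
        person_col: str = "person_id",
        group_col: str = "group",
        time_col: str = "time",
        reference_group: str | None = None,
        time_order: Sequence[str] | None = None,
    ) -> "ResponseData":
        """Build a dataset from a long-by-time, wide-by-item table.

        ``items`` is either a list of item column names (category counts
        inferred from the observed maximum) or a mapping ``column -> number
        of categories``.  Persons with no non-missing response at any time
        point are excluded; the count is kept in ``n_excluded``.
        """
        if isinstance(items, Mapping):
            item_ids = list(items)
            n_cat = [int(items[c]) for c in item_ids]
        else:
            item_ids = list(items)
            n_cat = None

        for col in [person_col, group_col, time_col, *item_ids]:
            if col not in df.columns:
                raise ValueError(f"column {col!r} missing from input")

        dup = df.duplicated([person_col, time_col], keep=False)
        if dup.any():
            rows = df.loc[dup, [person_col, time_col]].to_dict("records")
            raise ValueError(f"duplicated (person, time) rows: {rows[:10]}")

        glabels = sorted(df[group_col].astype(str).unique())
        if len(glabels) != 2:
            raise ValueError(f"expected exactly two groups, found {glabels}")
        if reference_group is not None:
            reference_group = str(reference_group)
            if reference_group not in glabels:
                raise ValueError(f"reference group {reference_group!r} not in data")
            glabels = [reference_group] + [g for g in glabels if g != reference_group]

        tlabels = list(time_order) if time_order is not None else sorted(
            df[time_col].astype(str).unique()
        )
        unknown = set(df[time_col].astype(str)) - set(tlabels)
        if unknown:
            raise ValueError(f"unexpected time labels {sorted(unknown)}")

        bad_grp = df.groupby(person_col)[group_col].nunique()
        bad_grp = bad_grp[bad_grp > 1]
        if len(bad_grp):
            raise ValueError(
                f"inconsistent group labels for persons {list(bad_grp.index)[:10]}"
            )

        pids = pd.unique(df[person_col])
        pidx = {p: i for i, p in enumerate(pids)}
        n, J, T = len(pids), len(item_ids), len(tlabels)
        resp = np.full((n, J, T), MISSING, dtype=np.int64)
        groups = np.zeros(n, dtype=np.int64)

        gmap = {lab: k for k, lab in enumerate(glabels)}
        tmap = {lab: k for k, lab in enumerate(tlabels)}
        for _, row in df.iterrows():
            i = pidx[row[person_col]]
            groups[i] = gmap[str(row[group_col])]
            t = tmap[str(row[time_col])]
            for j, col in enumerate(item_ids):
                v = row[col]
                if pd.isna(v):
                    continue
                fv = float(v)
                if fv != int(fv):
                    raise ValueError(
                        f"non-integer response {v!r} for item {col!r} "
                        f"(person {row[person_col]!r}, time {row[time_col]!r})"
                    )
                resp[i, j, t] = int(fv)

        if n_cat is None:
            n_cat = [int(resp[:, j, :].max()) + 1 for j in range(J)]

        # range check with informative cell naming before construction
        for j, m in enumerate(n_cat):
            bad = (resp[:, j, :] != MISSING) & (resp[:, j, :] >= m)
            if bad.any():
                i, t = np.argwhere(bad)[0]
                raise ValueError(
                    f"category code {resp[i, j, t]} exceeds 0..{m - 1} for item "
                    f"{item_ids[j]!r} (person {pids[i]!r}, time {tlabels[t]})"
                )

        keep = (resp != MISSING).any(axis=(1, 2))
        n_excluded = int((~keep).sum())
        return cls(
            resp[keep],
            groups[keep],
            item_ids,
            n_cat,
            tuple(glabels),
            tuple(tlabels),
            np.asarray(pids)[keep],
            n_excluded,
        )

    def to_dataframe(
        self,
        person_col: str = "person_id",
        group_col: str = "group",
        time_col: str = "time",
    ) -> pd.DataFrame:
        rows = []
        for i in range(self.n_persons):
            for t, tlab in enumerate(self.time_labels):
                rec = {
                    person_col: self.person_ids[i],
                    group_col: self.group_labels[self.groups[i]],
                    time_col: tlab,
                }
                for j, it in enumerate(self.item_ids):
                    v = self.responses[i, j, t]
                    rec[it] = np.nan if v == MISSING else int(v)
                rows.append(rec)
        return pd.DataFrame(rows)

    def to_csv(self, path, **kwargs) -> None:
        self.to_dataframe(**kwargs).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, items, **kwargs) -> "ResponseData":
        """Read a response CSV (see :meth:`from_dataframe` for the layout)."""
        return cls.from_dataframe(pd.read_csv(path), items, **kwargs)

    @classmethod
    def from_long_dataframe(
        cls,
        df: pd.DataFrame,
        item_col: str = "item",
        response_col: str = "response",
        person_col: str = "person_id",
        group_col: str = "group",
        time_col: str = "time",
        **kwargs,
    ) -> "ResponseData":
        """Convert fully long input (one row per person x time x item) to
        the native layout and build the dataset."""
        dup = df.duplicated([person_col, time_col, item_col], keep=False)
        if dup.any():
            rows = df.loc[dup, [person_col, time_col, item_col]].to_dict("records")
            raise ValueError(f"duplicated (person, time, item) rows: {rows[:10]}")
        wide = df.pivot_table(
            index=[person_col, group_col, time_col],
            columns=item_col,
            values=response_col,
            aggfunc="first",
        ).reset_index()
        wide.columns.name = None
        items = kwargs.pop("items", None)
        if items is None:
            items = [c for c in wide.columns if c not in (person_col, group_col, time_col)]
        return cls.from_dataframe(
            wide, items, person_col=person_col, group_col=group_col,
            time_col=time_col, **kwargs,
        )
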