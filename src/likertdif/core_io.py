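"""Ordinal response data model and pre-analysis filters.

Responses are respondent-by-item matrices of integer Likert codes
``1..K`` (``K = 4`` for the 32-item HIV Stigma Scale bundled with this
package).  Missing cells are carried as NaN; persons are dropped
listwise per analysis, never imputed.  Sparse response categories can
be merged inward so that every group x category cell reaches a minimum
count before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


class DataError(ValueError):
    """Raised for malformed or inconsistent response data."""


@dataclass
class ResponseMatrix:
    """Persons x items matrix of ordinal codes.

    ``responses`` is a float array with codes in ``1..K`` and NaN for
    missing.  ``item_categories`` tracks the number of categories per
    item; it starts at ``K`` for every item and only differs after
    category collapsing.
    """

    responses: np.ndarray
    person_ids: list[str]
    item_ids: list[str]
    K: int
    item_categories: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise DataError("responses must be 2-D (persons x items)")
        n, j = self.responses.shape
        if len(self.person_ids) != n or len(self.item_ids) != j:
            raise DataError("id lists must match the responses shape")
        if self.K < 2:
            raise DataError("K must be >= 2")
        if self.item_categories is None:
            self.item_categories = np.full(j, self.K, dtype=int)
        else:
            self.item_categories = np.asarray(self.item_categories, dtype=int)
        obs = self.responses[~np.isnan(self.responses)]
        if obs.size and (obs < 1).any():
            raise DataError("response codes must be >= 1")
        if obs.size and (self.responses > self.item_categories).any():
            raise DataError("response codes exceed the item category count")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def item_index(self, item_id: str) -> int:
        try:
            return self.item_ids.index(item_id)
        except ValueError:
            raise DataError(f"unknown item id: {item_id!r}") from None

    def subset_items(self, items: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_index(i) for i in items]
        return ResponseMatrix(
            self.responses[:, idx].copy(),
            list(self.person_ids),
            list(items),
            self.K,
            self.item_categories[idx].copy(),
        )

    def subset_persons(self, mask: np.ndarray) -> "ResponseMatrix":
        mask = np.asarray(mask, dtype=bool)
        return ResponseMatrix(
            self.responses[mask].copy(),
            [p for p, m in zip(self.person_ids, mask) if m],
            list(self.item_ids),
            self.K,
            self.item_categories.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.responses, index=self.person_ids, columns=self.item_ids)


@dataclass
class GroupAssignment:
    """Group labels aligned with a ResponseMatrix's persons.

    Labels are strings; ``None`` marks a missing group (such persons are
    excluded from every DIF fit at :func:`listwise_subset`).
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=object)
        arr = np.array([None if (x is None or (isinstance(x, float) and np.isnan(x))) else str(x) for x in arr], dtype=object)
        self.labels = arr

    @property
    def n_persons(self) -> int:
        return self.labels.shape[0]

    @property
    def levels(self) -> list[str]:
        return sorted({x for x in self.labels if x is not None})

    @property
    def missing_mask(self) -> np.ndarray:
        return np.array([x is None for x in self.labels], dtype=bool)

    def validate(self) -> None:
        if len(self.levels) < 2:
            raise DataError("group assignment needs >= 2 non-empty levels")

    def subset(self, mask: np.ndarray) -> "GroupAssignment":
        return GroupAssignment(self.labels[np.asarray(mask, dtype=bool)])

    def indices_by_level(self) -> dict[str, np.ndarray]:
        return {g: np.flatnonzero(self.labels == g) for g in self.levels}


@dataclass
class ScaleDefinition:
    """Item-to-subscale map with reverse-scored item flags.

    Subscale item lists are disjoint and ordered; ``reverse_items``
    holds ids whose codes run against the trait (recode ``c -> K+1-c``).
    """

    subscales: dict[str, list[str]]
    reverse_items: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, items in self.subscales.items():
            if not items:
                raise DataError(f"subscale {name!r} has no items")
            dup = seen.intersection(items)
            if dup:
                raise DataError(f"items assigned to more than one subscale: {sorted(dup)}")
            seen.update(items)
        unknown = set(self.reverse_items) - seen
        if unknown:
            raise DataError(f"reverse items not in any subscale: {sorted(unknown)}")

    @property
    def all_items(self) -> list[str]:
        out: list[str] = []
        for items in self.subscales.values():
            out.extend(items)
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScaleDefinition":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            subscales={name: [str(i) for i in items] for name, items in raw["subscales"].items()},
            reverse_items={str(i) for i in raw.get("reverse_items", [])},
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "subscales": {k: list(v) for k, v in self.subscales.items()},
            "reverse_items": sorted(self.reverse_items),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def bundled_scale(name: str = "hiv_stigma_scale_32") -> ScaleDefinition:
    """Load a scale definition shipped with the package.

    ``hiv_stigma_scale_32`` encodes the revised 32-item HIV Stigma Scale:
    four subscales (Personalized stigma 11, Disclosure concerns 8,
    Concerns about public attitudes 6, Negative self-image 7 items) with
    items 8 and 21 reverse scored.
    """
    path = Path(__file__).parent / "data" / f"{name}.yaml"
    if not path.exists():
        raise DataError(f"no bundled scale named {name!r}")
    return ScaleDefinition.from_yaml(path)


def load_responses(
    path: str | Path,
    scale: ScaleDefinition,
    group_column: str,
    K: int = 4,
) -> tuple[ResponseMatrix, GroupAssignment]:
    """Read a responses CSV into a ResponseMatrix plus group labels.

    The CSV has one row per respondent, one column per item id of
    ``scale`` plus ``group_column``; blank cells are missing.  Codes
    outside ``[1, K]`` and non-integer cells are rejected with the
    offending row/column named.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    items = scale.all_items
    missing_cols = [c for c in items if c not in df.columns]
    if missing_cols:
        raise DataError(f"response file lacks item columns: {missing_cols}")
    if group_column not in df.columns:
        raise DataError(f"response file lacks group column {group_column!r}")

    n = len(df)
    mat = np.full((n, len(items)), np.nan)
    for j, item in enumerate(items):
        col = df[item].str.strip()
        for i, cell in enumerate(col):
            if cell == "":
                continue
            try:
                val = int(cell)
            except ValueError:
                raise DataError(
                    f"non-integer cell {cell!r} at row {i}, column {item!r}"
                ) from None
            if not 1 <= val <= K:
                raise DataError(
                    f"code {val} outside [1, {K}] at row {i}, column {item!r}"
                )
            mat[i, j] = val

    if "person_id" in df.columns:
        person_ids = [str(p) for p in df["person_id"]]
    else:
        person_ids = [str(i) for i in range(n)]
    glabels = [x.strip() if x.strip() != "" else None for x in df[group_column]]
    return (
        ResponseMatrix(mat, person_ids, list(items), K),
        GroupAssignment(np.array(glabels, dtype=object)),
    )


def apply_reverse_coding(m: ResponseMatrix, scale: ScaleDefinition) -> ResponseMatrix:
    """Recode reverse-scored items as ``c -> K+1-c``; an involution."""
    out = m.responses.copy()
    for item in scale.reverse_items:
        if item in m.item_ids:
            j = m.item_ids.index(item)
            out[:, j] = np.where(np.isnan(out[:, j]), np.nan, m.item_categories[j] + 1 - out[:, j])
    return replace(m, responses=out, person_ids=list(m.person_ids), item_ids=list(m.item_ids), item_categories=m.item_categories.copy())


def listwise_subset(
    m: ResponseMatrix,
    g: GroupAssignment,
    items: Sequence[str],
) -> tuple[ResponseMatrix, GroupAssignment]:
    """Keep only persons complete on ``items`` and with a known group.

    Order is preserved; missing values are never imputed.
    """
    if not items:
        raise DataError("listwise_subset needs a non-empty item list")
    if m.n_persons != g.n_persons:
        raise DataError("responses and group labels are misaligned")
    sub = m.subset_items(items)
    complete = ~np.isnan(sub.responses).any(axis=1)
    keep = complete & ~g.missing_mask
    if not keep.any():
        raise DataError("no persons remain after listwise deletion")
    return sub.subset_persons(keep), g.subset(keep)


@dataclass
class CategoryMerge:
    item_id: str
    merged_code: int
    into_code: int
    counts_before: dict[str, list[int]]


@dataclass
class CollapseReport:
    merges: list[CategoryMerge]
    final_categories: dict[str, int]
    failed_items: list[str]

    @property
    def any_collapsed(self) -> bool:
        return bool(self.merges)


def _group_category_counts(col: np.ndarray, g: GroupAssignment, k: int) -> dict[str, list[int]]:
    out = {}
    for level, idx in g.indices_by_level().items():
        vals = col[idx]
        vals = vals[~np.isnan(vals)].astype(int)
        out[level] = [int((vals == c).sum()) for c in range(1, k + 1)]
    return out


def collapse_sparse_categories(
    m: ResponseMatrix,
    g: GroupAssignment,
    min_cell: int = 5,
) -> tuple[ResponseMatrix, CollapseReport]:
    """Merge sparse response categories inward until every group x
    category cell holds at least ``min_cell`` observations.

    Per item, the sparsest category (lowest minimum count over groups;
    ties to the lowest code) is merged with its inward-adjacent
    neighbor — category 1 into 2, the top category into the one below,
    lower-half categories upward, upper-half downward — and codes are
    relabelled contiguously.  The same merge applies to all groups.  An
    item that would collapse to a single category is reported as failed.
    """
    if min_cell < 1:
        raise DataError("min_cell must be >= 1")
    out = m.responses.copy()
    cats = m.item_categories.copy()
    merges: list[CategoryMerge] = []
    failed: list[str] = []

    for j, item in enumerate(m.item_ids):
        while True:
            k = int(cats[j])
            counts = _group_category_counts(out[:, j], g, k)
            mins = [min(counts[lvl][c] for lvl in counts) for c in range(k)]
            sparse = [c for c in range(k) if mins[c] < min_cell]
            if not sparse:
                break
            if k <= 2:
                failed.append(item)
                break
            target = min(sparse, key=lambda c: (mins[c], c))
            code = target + 1  # 1-based
            into = code + 1 if code <= k / 2 else code - 1
            col = out[:, j]
            col[col == code] = into
            col[col > code] -= 1  # relabel contiguously
            cats[j] = k - 1
            merges.append(CategoryMerge(item, code, into, counts))
    report = CollapseReport(merges, {i: int(cats[j]) for j, i in enumerate(m.item_ids)}, failed)
    if failed:
        raise DataError(
            f"items collapsed to a single usable category: {failed}; "
            f"merge trail: {[(x.item_id, x.merged_code, x.into_code) for x in merges]}"
        )
    collapsed = ResponseMatrix(out, list(m.person_ids), list(m.item_ids), m.K, cats)
    return collapsed, report
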