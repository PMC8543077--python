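"""Harmonised 11-item behaviour scale: item metadata, panel container, tabular I/O.

The scale pools six externalising (EXT) items — restlessness, fidgeting,
fighting, distractibility, tantrums, disobedience — and five internalising
(INT) items — worry, fearfulness, solitariness, unhappiness, somatic
complaints.  Eight items carry three ordered categories, three are binary.
All items are stored *recoded* so that a higher code means better behaviour
(category 0 is the worst), which lets the latent factors be read as skills
rather than problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemMeta",
    "ItemPanel",
    "DEFAULT_ITEMS",
    "DEFAULT_GROUPS",
    "REFERENCE_GROUP",
    "item_column",
    "load_panel",
    "prevalence_table",
]

EXT = "EXT"
INT = "INT"


@dataclass(frozen=True)
class ItemMeta:
    """Metadata for one item of the harmonised scale."""

    item_id: int
    title: str
    factor: str  # "EXT" or "INT"
    n_categories: int  # 2 or 3
    positively_worded: bool = False

    def __post_init__(self) -> None:
        if self.factor not in (EXT, INT):
            raise ValueError(f"item {self.item_id}: factor must be EXT or INT")
        if self.n_categories not in (2, 3):
            raise ValueError(f"item {self.item_id}: n_categories must be 2 or 3")


#: The harmonised scale: items 1-6 are externalising, 7-11 internalising;
#: items 1-4 and 7-10 have three categories, items 5, 6 and 11 are binary.
DEFAULT_ITEMS: tuple[ItemMeta, ...] = (
    ItemMeta(1, "Restless", EXT, 3),
    ItemMeta(2, "Squirmy/fidgety", EXT, 3),
    ItemMeta(3, "Fights/bullies", EXT, 3),
    ItemMeta(4, "Distracted", EXT, 3),
    ItemMeta(5, "Tantrums", EXT, 2),
    ItemMeta(6, "Disobedient", EXT, 2, positively_worded=True),
    ItemMeta(7, "Worried", INT, 3),
    ItemMeta(8, "Fearful", INT, 3),
    ItemMeta(9, "Solitary", INT, 3),
    ItemMeta(10, "Unhappy", INT, 3),
    ItemMeta(11, "Aches", INT, 2),
)

DEFAULT_GROUPS: tuple[str, ...] = ("BCS_M", "BCS_F", "MCS_M", "MCS_F")
REFERENCE_GROUP = "BCS_M"


def item_column(item_id: int) -> str:
    return f"item_{item_id}"


def validate_items(items: Sequence[ItemMeta]) -> None:
    ids = [m.item_id for m in items]
    if ids != sorted(ids) or len(set(ids)) != len(ids):
        raise ValueError("item ids must be unique and sorted")
    for m in items:
        if m.factor not in (EXT, INT):
            raise ValueError(f"item {m.item_id}: unknown factor {m.factor!r}")


@dataclass
class ItemPanel:
    """Per-child ordinal item responses, group labels, covariates and outcomes.

    ``data`` holds one row per child with columns ``child_id``, ``group``, one
    ``item_<k>`` column per item (codes ``0..n_categories-1``, higher = better
    behaviour) and any number of covariate/outcome columns.  Analysis rows are
    complete cases on the items; ``n_dropped`` records how many raw rows were
    removed for missing item responses.
    """

    data: pd.DataFrame
    items: Sequence[ItemMeta] = DEFAULT_ITEMS
    n_dropped: int = 0
    covariate_columns: tuple[str, ...] = ()
    outcome_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        validate_items(self.items)
        cols = self.data.columns
        for required in ("child_id", "group"):
            if required not in cols:
                raise ValueError(f"panel is missing the {required!r} column")
        for m in self.items:
            col = item_column(m.item_id)
            if col not in cols:
                raise ValueError(f"panel is missing item column {col!r}")
            vals = self.data[col].to_numpy()
            if np.isnan(vals.astype(float)).any():
                raise ValueError(f"{col}: missing responses in analysis rows")
            if (vals < 0).any() or (vals >= m.n_categories).any():
                raise ValueError(
                    f"{col}: codes outside 0..{m.n_categories - 1}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def item_cols(self) -> list[str]:
        return [item_column(m.item_id) for m in self.items]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.data["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def responses(self, group: str | None = None) -> np.ndarray:
        """Integer response matrix (n_children x n_items)."""
        df = self.data if group is None else self.group_frame(group)
        return df[self.item_cols].to_numpy(dtype=np.int64)

    def group_frame(self, group: str) -> pd.DataFrame:
        sub = self.data[self.data["group"] == group]
        if sub.empty:
            raise ValueError(f"group {group!r} is empty or unknown")
        return sub

    def group_sizes(self) -> dict[str, int]:
        return self.data["group"].value_counts().to_dict()


def load_panel(
    path: str | Path,
    items: Sequence[ItemMeta] = DEFAULT_ITEMS,
    recode_map: Mapping[int, Mapping[object, int]] | None = None,
    groups: Iterable[str] | None = None,
) -> ItemPanel:
    """Read a per-child CSV, recode item categories, and drop incomplete rows.

    Parameters
    ----------
    path
        CSV with header row; one row per child; columns ``child_id``,
        ``group``, one column per item and optional covariates/outcomes.
    items
        Item metadata; item columns are ``item_<id>``.
    recode_map
        Optional ``{item_id: {raw_value: recoded_code}}``.  The map must cover
        every raw category observed for that item; an unmapped category is a
        hard error.  Items without an entry are assumed already coded
        ``0..n_categories-1`` with higher = better.
    groups
        If given, the set of legal group labels; an unknown label is a hard
        error.
    """
    df = pd.read_csv(path)
    if "child_id" not in df.columns or "group" not in df.columns:
        raise ValueError("input CSV must have child_id and group columns")
    if groups is not None:
        legal = set(groups)
        bad = set(df["group"].dropna()) - legal
        if bad:
            raise ValueError(f"unknown group label(s): {sorted(map(str, bad))}")

    recode_map = recode_map or {}
    for m in items:
        col = item_column(m.item_id)
        if col not in df.columns:
            raise ValueError(f"input CSV is missing item column {col!r}")
        if m.item_id in recode_map:
            mapping = dict(recode_map[m.item_id])
            observed = df[col].dropna().unique()
            unmapped = [v for v in observed if v not in mapping]
            if unmapped:
                raise ValueError(
                    f"item {m.item_id}: raw categories {unmapped!r} not in recode map"
                )
            codes = sorted(mapping.values())
            if codes != list(range(m.n_categories)):
                raise ValueError(
                    f"item {m.item_id}: recode map must be onto 0..{m.n_categories - 1}"
                )
            df[col] = df[col].map(mapping)

    item_cols = [item_column(m.item_id) for m in items]
    complete = df[item_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    kept = df.loc[complete].copy()
    kept[item_cols] = kept[item_cols].astype(np.int64)

    reserved = {"child_id", "group", *item_cols}
    extra = tuple(c for c in kept.columns if c not in reserved)
    return ItemPanel(
        data=kept.reset_index(drop=True),
        items=items,
        n_dropped=n_dropped,
        covariate_columns=extra,
    )


def reverse_map(recode_map: Mapping[object, int]) -> dict[int, object]:
    """Inverse of a per-item recode map (recoding is a bijection per item)."""
    inv: dict[int, object] = {}
    for raw, code in recode_map.items():
        if code in inv:
            raise ValueError("recode map is not a bijection")
        inv[code] = raw
    return inv


def prevalence_table(panel: ItemPanel) -> pd.DataFrame:
    """Per-group x per-item category proportions (tidy long format).

    Columns: group, item_id, category, proportion, n.  Proportions sum to one
    within each item x group cell.
    """
    rows = []
    for g in panel.groups:
        sub = panel.group_frame(g)
        n = len(sub)
        if n == 0:
            raise ValueError(f"group {g!r} is empty")
        for m in panel.items:
            counts = np.bincount(
                sub[item_column(m.item_id)].to_numpy(), minlength=m.n_categories
            )
            for cat in range(m.n_categories):
                rows.append(
                    {
                        "group": g,
                        "item_id": m.item_id,
                        "category": cat,
                        "proportion": counts[cat] / n,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)
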