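"""Food-group taxonomy: load, validate, and aggregate recall data to groups.

The heart-protective diet score is computed over 22 food groups, 11 scored
positively (heart-protective: wholegrains, fruits, non-starchy vegetables,
fish, eggs, reduced-fat dairy, ...) and 11 negatively (discouraged: red and
processed meat, refined grains, sweets, sugary drinks, ...). Each group has
a serve size in grams (drinks in mL counted 1:1 as grams) and a list of
24 h recall instrument items. Item-level recall amounts are aggregated to a
participant x group matrix in grams/week: a single 24 h amount contributes
amount x 7.

Alcoholic beverages, highly processed vegetarian alternatives, vegetable
fats and salted nuts are deliberately excluded from the score; recall rows
for items on the ignore list are dropped silently.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FoodItem",
    "FoodGroup",
    "Taxonomy",
    "TaxonomyError",
    "MappingError",
    "load_taxonomy",
    "default_taxonomy",
    "aggregate_group_intake",
    "slugify",
]

N_GROUPS = 22

RECALL_COLUMNS = ["participant_id", "recall_index", "item_id", "amount_g"]


class TaxonomyError(ValueError):
    """Structural or validation failure in a taxonomy definition."""


class MappingError(KeyError):
    """Recall rows reference item_ids absent from the taxonomy and ignore list."""


def slugify(name: str) -> str:
    """Lowercase, replace non-alphanumerics with underscores."""
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


@dataclass(frozen=True)
class FoodItem:
    item_id: str
    name: str
    group_id: str


@dataclass(frozen=True)
class FoodGroup:
    group_id: str
    name: str
    direction: int
    serve_size_g: float
    items: tuple[FoodItem, ...]
    declared_item_count: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise TaxonomyError(
                f"group {self.group_id!r}: direction must be +1 or -1, "
                f"got {self.direction!r}"
            )
        if not self.serve_size_g > 0:
            raise TaxonomyError(
                f"group {self.group_id!r}: serve_size_g must be > 0"
            )

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)


@dataclass(frozen=True)
class Taxonomy:
    """Validated collection of 22 signed food groups."""

    groups: tuple[FoodGroup, ...]
    ignore_items: frozenset[str] = frozenset()
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if len(self.groups) != N_GROUPS:
            raise TaxonomyError(
                f"expected {N_GROUPS} food groups, got {len(self.groups)}"
            )
        n_pos = sum(1 for g in self.groups if g.direction == 1)
        if n_pos != N_GROUPS // 2:
            raise TaxonomyError(
                f"expected {N_GROUPS // 2} positively and {N_GROUPS // 2} "
                f"negatively scored groups, got {n_pos} positive"
            )
        seen: dict[str, str] = {}
        for g in self.groups:
            for it in g.items:
                if it.item_id in seen:
                    raise TaxonomyError(
                        f"item {it.item_id!r} appears in both "
                        f"{seen[it.item_id]!r} and {g.group_id!r}"
                    )
                seen[it.item_id] = g.group_id
        gids = [g.group_id for g in self.groups]
        if len(set(gids)) != len(gids):
            raise TaxonomyError("duplicate group_id in taxonomy")

    @property
    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]

    @property
    def directions(self) -> pd.Series:
        return pd.Series(
            {g.group_id: g.direction for g in self.groups}, name="direction"
        )

    @property
    def serve_sizes(self) -> pd.Series:
        return pd.Series(
            {g.group_id: g.serve_size_g for g in self.groups}, name="serve_size_g"
        )

    def item_to_group(self) -> dict[str, str]:
        return {it.item_id: g.group_id for g in self.groups for it in g.items}

    def __getitem__(self, group_id: str) -> FoodGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)


def _build_group(raw: dict) -> FoodGroup:
    for key in ("name", "direction", "serve_size_g", "items"):
        if key not in raw:
            raise TaxonomyError(f"group definition missing field {key!r}: {raw}")
    gid = raw.get("group_id") or slugify(raw["name"])
    items = tuple(
        FoodItem(item_id=slugify(n), name=n, group_id=gid) for n in raw["items"]
    )
    if len({it.item_id for it in items}) != len(items):
        raise TaxonomyError(f"group {gid!r}: duplicate item ids after slugify")
    return FoodGroup(
        group_id=gid,
        name=raw["name"],
        direction=int(raw["direction"]),
        serve_size_g=float(raw["serve_size_g"]),
        items=items,
        declared_item_count=raw.get("declared_item_count"),
    )


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Load and validate a taxonomy from a YAML config file.

    The file maps ``groups`` to a list of group definitions
    (``name, direction, serve_size_g, declared_item_count, items[]``) and
    optionally an ``ignore_items`` list. Groups whose declared instrument
    item count differs from the number of named items are recorded in
    ``Taxonomy.warnings`` (the source table abbreviates two item lists).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "groups" not in raw:
        raise TaxonomyError(f"{path}: expected a mapping with a 'groups' key")
    groups = tuple(_build_group(g) for g in raw["groups"])
    warnings = tuple(
        f"group {g.group_id!r}: declared_item_count={g.declared_item_count} "
        f"but {len(g.items)} items named"
        for g in groups
        if g.declared_item_count is not None
        and g.declared_item_count != len(g.items)
    )
    ignore = frozenset(slugify(n) for n in raw.get("ignore_items", []))
    return Taxonomy(groups=groups, ignore_items=ignore, warnings=warnings)


def default_taxonomy() -> Taxonomy:
    """The packaged 22-group heart-protective diet taxonomy."""
    ref = resources.files("hpds.data").joinpath("food_groups.yaml")
    with resources.as_file(ref) as path:
        return load_taxonomy(path)


def _validate_recalls(recalls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECALL_COLUMNS if c not in recalls.columns]
    if missing:
        raise ValueError(f"recall table missing columns: {missing}")
    if (recalls["amount_g"] < 0).any():
        bad = recalls.loc[recalls["amount_g"] < 0]
        raise ValueError(
            f"negative recall amounts for items: "
            f"{sorted(bad['item_id'].unique().tolist())}"
        )
    dup = recalls.duplicated(["participant_id", "recall_index", "item_id"])
    if dup.any():
        raise ValueError(
            "duplicate (participant, recall, item) rows in recall table"
        )
    return recalls


def aggregate_group_intake(
    recalls: pd.DataFrame,
    taxonomy: Taxonomy,
    recall_policy: str = "earliest",
    k: int = 3,
) -> pd.DataFrame:
    """Aggregate item-level 24 h recall rows to a participant x group matrix.

    Parameters
    ----------
    recalls
        Long table with columns ``participant_id, recall_index, item_id,
        amount_g`` (grams or mL consumed in one 24 h window).
    taxonomy
        Validated 22-group taxonomy; items on its ignore list are dropped.
    recall_policy
        ``"earliest"`` uses only each participant's minimal recall_index
        occasion (maximizes follow-up from the baseline assessment);
        ``"mean-of-first-k"`` averages per-group weekly amounts over the
        available occasions with recall_index among the first ``k`` distinct
        occasions per participant.
    k
        Number of occasions for ``mean-of-first-k``.

    Returns
    -------
    DataFrame indexed by participant_id with one column per group_id, in
    taxonomy order, holding grams/week (a 24 h amount contributes x7).
    """
    if recall_policy not in ("earliest", "mean-of-first-k"):
        raise ValueError(f"unknown recall_policy {recall_policy!r}")
    recalls = _validate_recalls(recalls)
    mapping = taxonomy.item_to_group()
    known = recalls["item_id"].isin(mapping)
    ignored = recalls["item_id"].isin(taxonomy.ignore_items)
    unmapped = recalls.loc[~known & ~ignored, "item_id"]
    if len(unmapped):
        raise MappingError(
            f"recall items not in taxonomy or ignore list: "
            f"{sorted(unmapped.unique().tolist())}"
        )
    # canonical sorted order so output is invariant to recall row order
    participants = np.sort(recalls["participant_id"].unique())
    use = recalls.loc[known].copy()

    if recall_policy == "earliest":
        first = use.groupby("participant_id")["recall_index"].transform("min")
        use = use.loc[use["recall_index"] == first]
        weekly = _pivot_weekly(use, mapping, taxonomy)
    else:
        ranks = (
            use[["participant_id", "recall_index"]]
            .drop_duplicates()
            .sort_values(["participant_id", "recall_index"])
        )
        ranks["occ_rank"] = ranks.groupby("participant_id").cumcount()
        use = use.merge(ranks, on=["participant_id", "recall_index"])
        use = use.loc[use["occ_rank"] < k]
        per_occ = (
            use.assign(group_id=use["item_id"].map(mapping))
            .groupby(["participant_id", "recall_index", "group_id"])["amount_g"]
            .sum()
            .mul(7.0)
            .unstack("group_id", fill_value=0.0)
        )
        weekly = per_occ.groupby("participant_id").mean()
        weekly = weekly.reindex(columns=taxonomy.group_ids, fill_value=0.0)

    # participants whose every row was ignored still get an all-zero row
    weekly = weekly.reindex(pd.Index(participants, name="participant_id"),
                            fill_value=0.0)
    return weekly


def _pivot_weekly(
    use: pd.DataFrame, mapping: dict[str, str], taxonomy: Taxonomy
) -> pd.DataFrame:
    out = (
        use.assign(group_id=use["item_id"].map(mapping))
        .groupby(["participant_id", "group_id"])["amount_g"]
        .sum()
        .mul(7.0)
        .unstack("group_id", fill_value=0.0)
        .reindex(columns=taxonomy.group_ids, fill_value=0.0)
    )
    out.columns.name = None
    return out
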