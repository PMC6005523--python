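"""Core data structures for stomach-content diet analysis.

A study of this kind starts from a per-specimen table of stomach records:
each fish has a species, a season and a location label, an optional body
length, and a set of food items found in its stomach.  Everything downstream
(frequency-of-occurrence profiles, community matrices, dissimilarities,
permutation tests, overlap indices) is built from this table.

Conventions
-----------
* "Empty" stomachs (no identifiable contents) are retained for specimen
  tallies and the chi-square test of feeding activity, but excluded from all
  multivariate analyses.
* Frequency of occurrence (FOC) of an item in a group of stomachs is the
  number of stomachs containing the item divided by the total number of item
  occurrences in the group, so each group's FOC vector sums to one.  The
  grouping unit is the (species, season) pool of non-empty stomachs and
  occurrence is presence in a stomach (binary), which makes profiles
  independent of within-stomach item counts; other readings are reachable
  through the ``unit`` / ``binarize`` switches of
  :func:`build_community_matrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "DEFAULT_SEASONS",
    "DEFAULT_CATEGORIES",
    "StomachRecord",
    "StomachTable",
    "CommunityMatrix",
    "FOCProfile",
    "CountTable",
    "read_stomach_table",
    "read_stomach_table_long",
    "write_stomach_table",
    "tally_by",
    "empty_stomach_summary",
    "build_community_matrix",
    "foc_profiles",
    "category_importance",
]


class SchemaError(ValueError):
    """Raised when an input file lacks mandatory columns."""


class ValidationError(ValueError):
    """Raised when record contents violate an invariant (e.g. negative counts)."""


#: Hydrological phases of a flood-pulse system, in cycle order.
DEFAULT_SEASONS: tuple[str, ...] = ("receding", "wet", "rising", "dry")

#: The six broad food categories used to aggregate prey items.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "fish",
    "insects",
    "crustaceans",
    "plants",
    "mollusks",
    "micro-fauna",
)

#: Metadata columns of the wide CSV dialect, in canonical order.
META_COLUMNS: tuple[str, ...] = (
    "specimen_id",
    "species",
    "season",
    "location",
    "length_cm",
)


@dataclass(frozen=True)
class StomachRecord:
    """A single specimen's stomach content record.

    ``items`` maps food-item label to a nonnegative occurrence count; a record
    is empty iff the mapping is empty or all counts are zero.
    """

    specimen_id: str
    species: str
    season: str
    location: str
    items: Mapping[str, int]
    length_cm: float | None = None

    def __post_init__(self) -> None:
        for item, count in self.items.items():
            if count < 0:
                raise ValidationError(
                    f"negative count {count} for item {item!r} in specimen "
                    f"{self.specimen_id!r}"
                )
        if self.length_cm is not None and self.length_cm < 0:
            raise ValidationError(
                f"negative length_cm for specimen {self.specimen_id!r}"
            )

    @property
    def is_empty(self) -> bool:
        return not any(c > 0 for c in self.items.values())


@dataclass
class StomachTable:
    """An ordered collection of stomach records with an item vocabulary.

    ``category_map`` assigns each vocabulary item to a broad category; it must
    cover the whole vocabulary.
    """

    records: list[StomachRecord]
    item_vocabulary: list[str]
    category_map: dict[str, str] = field(default_factory=dict)
    seasons: tuple[str, ...] = DEFAULT_SEASONS

    def __post_init__(self) -> None:
        vocab = set(self.item_vocabulary)
        if len(vocab) != len(self.item_vocabulary):
            raise ValidationError("duplicate labels in item_vocabulary")
        for i, rec in enumerate(self.records):
            unknown = set(rec.items) - vocab
            if unknown:
                raise ValidationError(
                    f"record {i} ({rec.specimen_id!r}) uses items outside the "
                    f"vocabulary: {sorted(unknown)}"
                )
        if self.item_vocabulary:
            uncovered = vocab - set(self.category_map)
            if uncovered:
                raise ValidationError(
                    f"category_map does not cover items: {sorted(uncovered)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species_levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.species, None)
        return list(seen)

    def to_dataframe(self) -> pd.DataFrame:
        """Wide-format view: one row per record, one column per item."""
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "specimen_id": rec.specimen_id,
                "species": rec.species,
                "season": rec.season,
                "location": rec.location,
                "length_cm": rec.length_cm,
            }
            for item in self.item_vocabulary:
                row[item] = int(rec.items.get(item, 0))
            rows.append(row)
        cols = list(META_COLUMNS) + list(self.item_vocabulary)
        return pd.DataFrame(rows, columns=cols)

    def validate_margins(
        self,
        location_counts: Mapping[str, Mapping[str, int]] | None = None,
        season_counts: Mapping[str, Mapping[str, int]] | None = None,
    ) -> list[str]:
        """Check per-species margins against externally stated tallies.

        Returns a list of human-readable mismatch reports (empty when all
        margins agree).  Mismatches are reported, never repaired: published
        tables occasionally disagree internally and the caller should know.
        """
        reports: list[str] = []
        if location_counts is not None:
            got = tally_by(self, "species", "location").to_frame()
            for sp, expect in location_counts.items():
                for loc, n in expect.items():
                    have = int(got.loc[sp, loc]) if sp in got.index else 0
                    if have != n:
                        reports.append(
                            f"location margin mismatch for {sp!r} at {loc!r}: "
                            f"table has {have}, stated {n}"
                        )
        if season_counts is not None:
            got = tally_by(self, "species", "season").to_frame()
            for sp, expect in season_counts.items():
                for season, n in expect.items():
                    have = int(got.loc[sp, season]) if sp in got.index else 0
                    if have != n:
                        reports.append(
                            f"season margin mismatch for {sp!r} in {season!r}: "
                            f"table has {have}, stated {n}"
                        )
        return reports


@dataclass
class CommunityMatrix:
    """Sampling-units x food-items matrix with per-row grouping labels.

    Rows are non-empty sampling units (stomachs, or pooled groups); empty
    stomachs are excluded before construction, so no row is all-zero.
    """

    values: np.ndarray
    unit_labels: pd.DataFrame
    item_labels: list[str]
    level: str  # "item" or "category"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("community matrix must be 2-D")
        if self.values.shape[0] != len(self.unit_labels):
            raise ValidationError("unit_labels length does not match row count")
        if self.values.shape[1] != len(self.item_labels):
            raise ValidationError("item_labels length does not match column count")
        if np.any(self.values < 0):
            raise ValidationError("community matrix entries must be nonnegative")
        zero_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero_rows.size:
            raise ValidationError(
                f"all-zero rows in community matrix at indices {zero_rows.tolist()}"
            )

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    def subset(self, mask: np.ndarray) -> "CommunityMatrix":
        return CommunityMatrix(
            self.values[mask],
            self.unit_labels.loc[np.asarray(mask)].reset_index(drop=True),
            list(self.item_labels),
            self.level,
        )


@dataclass(frozen=True)
class FOCProfile:
    """Frequency-of-occurrence profile of one group of stomachs.

    ``p`` is a probability vector over ``items`` (sums to one); these are the
    p_i used by Pianka's overlap index.
    """

    group: tuple
    items: tuple[str, ...]
    p: np.ndarray
    n_stomachs: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if np.any(p < 0):
            raise ValidationError(f"negative FOC entries for group {self.group}")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"FOC profile for group {self.group} sums to {p.sum()!r}, not 1"
            )


@dataclass
class CountTable:
    """Two-way specimen tally over categorical factors, with margins."""

    counts: pd.DataFrame

    @property
    def row_margin(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margin(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    def to_frame(self) -> pd.DataFrame:
        return self.counts.copy()


# ---------------------------------------------------------------------------
# I/O: wide and long delimited-text dialects
# ---------------------------------------------------------------------------

def _records_from_wide(
    df: pd.DataFrame, vocabulary: Sequence[str]
) -> list[StomachRecord]:
    records = []
    for idx, row in df.iterrows():
        items = {}
        for item in vocabulary:
            val = row[item]
            if pd.isna(val):
                val = 0
            count = int(val)
            if count < 0:
                raise ValidationError(f"negative count at row {idx}, item {item!r}")
            if count:
                items[item] = count
        length = row.get("length_cm")
        records.append(
            StomachRecord(
                specimen_id=str(row["specimen_id"]),
                species=str(row["species"]),
                season=str(row["season"]),
                location=str(row["location"]),
                items=items,
                length_cm=None if pd.isna(length) else float(length),
            )
        )
    return records


def read_stomach_table(
    path: str | Path,
    vocabulary: Sequence[str] | None = None,
    category_map: Mapping[str, str] | None = None,
    seasons: Sequence[str] = DEFAULT_SEASONS,
) -> StomachTable:
    """Read a wide-format stomach table (one column per food item).

    Mandatory columns: ``specimen_id, species, season, location``.
    ``length_cm`` and ``is_empty`` are optional; every other column is taken
    as a food item unless ``vocabulary`` restricts the item set, in which
    case leftover columns are reported via a warning.  Emptiness is derived
    from the item counts; an explicit ``is_empty`` column is cross-checked.
    """
    df = pd.read_csv(path)
    mandatory = ("specimen_id", "species", "season", "location")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    if "length_cm" not in df.columns:
        df["length_cm"] = np.nan
    known_meta = set(META_COLUMNS) | {"is_empty"}
    item_cols = [c for c in df.columns if c not in known_meta]
    if vocabulary is not None:
        unknown = [c for c in item_cols if c not in set(vocabulary)]
        if unknown:
            warnings.warn(
                f"ignoring {len(unknown)} column(s) outside the item "
                f"vocabulary: {unknown}",
                stacklevel=2,
            )
        for item in vocabulary:
            if item not in df.columns:
                df[item] = 0
        item_cols = list(vocabulary)
    records = _records_from_wide(df, item_cols)
    if "is_empty" in df.columns:
        declared = df["is_empty"].astype(bool).tolist()
        derived = [r.is_empty for r in records]
        if declared != derived:
            bad = [i for i, (a, b) in enumerate(zip(declared, derived)) if a != b]
            raise ValidationError(
                f"is_empty flag disagrees with item counts at rows {bad}"
            )
    if category_map is None:
        category_map = {item: _default_category(item) for item in item_cols}
    return StomachTable(
        records=records,
        item_vocabulary=list(item_cols),
        category_map=dict(category_map),
        seasons=tuple(seasons),
    )


def read_stomach_table_long(
    path: str | Path,
    category_map: Mapping[str, str] | None = None,
    seasons: Sequence[str] = DEFAULT_SEASONS,
) -> StomachTable:
    """Read the long dialect: one row per (specimen, item) with a count column.

    Specimens listed with no item rows (or only zero counts) become empty
    records; specimen metadata must be constant within a specimen id.
    """
    df = pd.read_csv(path)
    mandatory = ("specimen_id", "species", "season", "location", "item", "count")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    if (df["count"].fillna(0) < 0).any():
        bad = df.index[df["count"].fillna(0) < 0].tolist()
        raise ValidationError(f"negative counts at rows {bad}")
    vocab = sorted(df.loc[df["item"].notna(), "item"].astype(str).unique())
    records = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        meta = grp.iloc[0]
        items: dict[str, int] = {}
        for _, row in grp.iterrows():
            if pd.isna(row["item"]) or pd.isna(row["count"]):
                continue
            c = int(row["count"])
            if c:
                items[str(row["item"])] = items.get(str(row["item"]), 0) + c
        length = meta.get("length_cm", np.nan)
        records.append(
            StomachRecord(
                specimen_id=str(sid),
                species=str(meta["species"]),
                season=str(meta["season"]),
                location=str(meta["location"]),
                items=items,
                length_cm=None if pd.isna(length) else float(length),
            )
        )
    if category_map is None:
        category_map = {item: _default_category(item) for item in vocab}
    return StomachTable(records, vocab, dict(category_map), tuple(seasons))


def write_stomach_table(table: StomachTable, path: str | Path) -> None:
    """Write the wide CSV dialect (UTF-8, comma-separated, header row)."""
    table.to_dataframe().to_csv(path, index=False)


def _default_category(item: str) -> str:
    """Infer a category from a ``category_item`` style label, else 'other'."""
    for cat in DEFAULT_CATEGORIES:
        if item == cat or item.startswith(cat + "_"):
            return cat
    return "other"


# ---------------------------------------------------------------------------
# Tallies and summaries
# ---------------------------------------------------------------------------

_FACTORS = ("species", "season", "location", "specimen_id")


def tally_by(table: StomachTable, rows: str, cols: str) -> CountTable:
    """Cross-tabulate specimen counts over two record factors.

    Includes empty stomachs: the tally counts collected specimens, as in a
    sampling-design table.
    """
    for name in (rows, cols):
        if name not in _FACTORS:
            raise ValueError(f"unknown factor {name!r}; expected one of {_FACTORS}")
    if not table.records:
        return CountTable(pd.DataFrame(dtype=int))
    df = pd.DataFrame(
        {
            rows: [getattr(r, rows) for r in table.records],
            cols: [getattr(r, cols) for r in table.records],
        }
    )
    ct = pd.crosstab(df[rows], df[cols])
    if cols == "season":
        order = [s for s in table.seasons if s in ct.columns]
        order += [s for s in ct.columns if s not in order]
        ct = ct[order]
    return CountTable(ct)


def empty_stomach_summary(table: StomachTable) -> pd.DataFrame:
    """Proportion of empty stomachs per species x season.

    Cells with no specimens are NaN (undefined), not zero.  Also usable as
    the input builder for the chi-square test of whether the seasonal pattern
    of feeding activity depends on species identity.
    """
    if not table.records:
        return pd.DataFrame(dtype=float)
    df = pd.DataFrame(
        {
            "species": [r.species for r in table.records],
            "season": [r.season for r in table.records],
            "empty": [r.is_empty for r in table.records],
        }
    )
    totals = pd.crosstab(df["species"], df["season"])
    empties = pd.crosstab(df["species"], df["season"], values=df["empty"], aggfunc="sum")
    empties = empties.reindex_like(totals).fillna(0)
    prop = empties / totals.where(totals > 0)
    order = [s for s in table.seasons if s in prop.columns]
    order += [s for s in prop.columns if s not in order]
    return prop[order].astype(float)


def empty_stomach_counts(table: StomachTable) -> CountTable:
    """Counts of empty stomachs per species x season (chi-square input)."""
    df = pd.DataFrame(
        {
            "species": [r.species for r in table.records],
            "season": [r.season for r in table.records],
            "empty": [int(r.is_empty) for r in table.records],
        }
    )
    ct = pd.crosstab(df["species"], df["season"], values=df["empty"], aggfunc="sum")
    ct = ct.fillna(0).astype(int)
    order = [s for s in table.seasons if s in ct.columns]
    order += [s for s in ct.columns if s not in order]
    return CountTable(ct[order])


# ---------------------------------------------------------------------------
# Community matrices and FOC profiles
# ---------------------------------------------------------------------------

def build_community_matrix(
    table: StomachTable,
    unit: str = "stomach",
    level: str = "item",
    binarize: bool = True,
) -> CommunityMatrix:
    """Build the units x items matrix that the multivariate analyses consume.

    Empty stomachs are excluded.  ``binarize`` replaces positive counts by 1
    at the stomach level (occurrence scoring) before any pooling, so with
    ``unit='group'`` the pooled entries are numbers of stomachs containing
    each item.  ``level='category'`` sums item columns within each broad food
    category.
    """
    if unit not in ("stomach", "group"):
        raise ValueError(f"unit must be 'stomach' or 'group', got {unit!r}")
    if level not in ("item", "category"):
        raise ValueError(f"level must be 'item' or 'category', got {level!r}")
    nonempty = [r for r in table.records if not r.is_empty]
    if not nonempty:
        raise ValidationError("no non-empty stomachs")
    items = list(table.item_vocabulary)
    X = np.zeros((len(nonempty), len(items)), dtype=float)
    col = {item: j for j, item in enumerate(items)}
    for i, rec in enumerate(nonempty):
        for item, count in rec.items.items():
            X[i, col[item]] = count
    if binarize:
        X = (X > 0).astype(float)
    labels = pd.DataFrame(
        {
            "specimen_id": [r.specimen_id for r in nonempty],
            "species": [r.species for r in nonempty],
            "season": [r.season for r in nonempty],
            "location": [r.location for r in nonempty],
        }
    )
    if level == "category":
        cats = list(dict.fromkeys(table.category_map[i] for i in items))
        C = np.zeros((X.shape[0], len(cats)))
        cat_col = {c: j for j, c in enumerate(cats)}
        for item, j in col.items():
            C[:, cat_col[table.category_map[item]]] += X[:, j]
        X, items = C, cats
    if unit == "group":
        keys = labels[["species", "season"]].apply(tuple, axis=1)
        uniq = list(dict.fromkeys(keys))
        G = np.zeros((len(uniq), X.shape[1]))
        for gi, key in enumerate(uniq):
            G[gi] = X[np.asarray(keys == key)].sum(axis=0)
        labels = pd.DataFrame(
            {
                "specimen_id": ["+".join(k) for k in uniq],
                "species": [k[0] for k in uniq],
                "season": [k[1] for k in uniq],
                "location": ["pooled"] * len(uniq),
            }
        )
        X = G
    return CommunityMatrix(X, labels, items, level)


def foc_profiles(
    matrix: CommunityMatrix,
    by: Sequence[str] = ("species", "season"),
) -> dict[tuple, FOCProfile]:
    """Frequency-of-occurrence profiles per group of the binarized matrix.

    For group g: p_i = (# stomachs in g containing item i) / (total item
    occurrences in g).  Requires a stomach-level presence/absence matrix.
    """
    vals = matrix.values
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValidationError(
            "foc_profiles requires a binarized stomach-level matrix "
            "(build with binarize=True, unit='stomach')"
        )
    keys = matrix.unit_labels[list(by)].apply(tuple, axis=1)
    out: dict[tuple, FOCProfile] = {}
    for key in dict.fromkeys(keys):
        rows = np.asarray(keys == key)
        occ = vals[rows].sum(axis=0)
        total = occ.sum()
        if total == 0:
            raise ValidationError(f"group {key} has no item occurrences")
        out[key] = FOCProfile(
            group=key,
            items=tuple(matrix.item_labels),
            p=occ / total,
            n_stomachs=int(rows.sum()),
        )
    return out


def category_importance(
    profiles: Mapping[tuple, FOCProfile] | Iterable[FOCProfile],
    category_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-group category importance: mean item FOC within each category,
    renormalized so categories sum to one.

    Items with zero FOC still count toward their category's mean, so a
    category of many rare items is not inflated relative to one dominant
    item.
    """
    if isinstance(profiles, Mapping):
        profiles = list(profiles.values())
    else:
        profiles = list(profiles)
    rows = {}
    for prof in profiles:
        uncovered = set(prof.items) - set(category_map)
        if uncovered:
            raise ValidationError(f"category_map does not cover {sorted(uncovered)}")
        cats = list(dict.fromkeys(category_map[i] for i in prof.items))
        means = {}
        for cat in cats:
            members = [j for j, item in enumerate(prof.items) if category_map[item] == cat]
            means[cat] = float(np.mean(prof.p[members]))
        total = sum(means.values())
        rows[prof.group] = {c: m / total for c, m in means.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index = pd.MultiIndex.from_tuples(df.index) if df.index.size and isinstance(
        next(iter(rows)), tuple
    ) else df.index
    return df
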