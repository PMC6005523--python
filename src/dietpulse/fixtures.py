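"""Sampling-design fixture for the three-species Tonle Sap stomach survey.

The published sampling design reports, per species, how many specimens were
collected at each of four locations (summed over seasons) and in each of four
hydrological seasons (summed over locations) — two one-way margins of the
unobserved location x season table.  This module reconstructs a specimen-level
table consistent with those margins so the tally and reporting machinery can
be exercised end to end without the (undeposited) raw data.

The reconstruction is deterministic (northwest-corner allocation) and the
records are *stubs*: design labels only, no stomach contents.  One published
margin pair is internally inconsistent — the N. notopterus season counts sum
to 214 while its location counts sum to 208.  Following the per-specimen
total (which matches the location sums: 236 + 179 + 208 = 623), location
margins are treated as authoritative and that species' season margin is
rescaled to 208 by largest remainder; :func:`margin_report` surfaces the
discrepancy rather than hiding it.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import StomachRecord, StomachTable, read_stomach_table

__all__ = [
    "TABLE1_LOCATION_COUNTS",
    "TABLE1_SEASON_COUNTS",
    "SPECIES",
    "LOCATIONS",
    "table1_stomach_table",
    "bundled_table1_path",
    "load_bundled_table1",
    "margin_report",
]

SPECIES: tuple[str, ...] = (
    "Anabas testudineus",
    "Boesemania microlepis",
    "Notopterus notopterus",
)

#: Gillnet stations around the lake: Kompong Thom, Siem Reap, Kompong
#: Chhnang, Pursat.
LOCATIONS: tuple[str, ...] = ("KT", "SR", "KC", "PS")

SEASONS: tuple[str, ...] = ("receding", "wet", "rising", "dry")

TABLE1_LOCATION_COUNTS: dict[str, dict[str, int]] = {
    "Anabas testudineus": {"KT": 55, "SR": 83, "KC": 50, "PS": 48},
    "Boesemania microlepis": {"KT": 30, "SR": 51, "KC": 59, "PS": 39},
    "Notopterus notopterus": {"KT": 35, "SR": 69, "KC": 48, "PS": 56},
}

TABLE1_SEASON_COUNTS: dict[str, dict[str, int]] = {
    "Anabas testudineus": {"receding": 80, "wet": 56, "rising": 35, "dry": 65},
    "Boesemania microlepis": {"receding": 65, "wet": 31, "rising": 6, "dry": 77},
    # sums to 214 although the same species' location counts sum to 208
    "Notopterus notopterus": {"receding": 78, "wet": 34, "rising": 23, "dry": 79},
}


def _scaled_season_margin(species: str) -> list[int]:
    """Season margin rescaled to the location total by largest remainder."""
    seasons = np.array([TABLE1_SEASON_COUNTS[species][s] for s in SEASONS], float)
    target = sum(TABLE1_LOCATION_COUNTS[species].values())
    if seasons.sum() == target:
        return [int(v) for v in seasons]
    scaled = seasons * target / seasons.sum()
    floors = np.floor(scaled).astype(int)
    short = int(target - floors.sum())
    order = np.argsort(-(scaled - floors))
    floors[order[:short]] += 1
    return floors.tolist()


def _northwest_corner(row_sums: list[int], col_sums: list[int]) -> np.ndarray:
    """Deterministic nonnegative integer matrix with the given margins."""
    if sum(row_sums) != sum(col_sums):
        raise ValueError("margins disagree")
    out = np.zeros((len(row_sums), len(col_sums)), dtype=int)
    rows = list(row_sums)
    cols = list(col_sums)
    i = j = 0
    while i < len(rows) and j < len(cols):
        take = min(rows[i], cols[j])
        out[i, j] = take
        rows[i] -= take
        cols[j] -= take
        if rows[i] == 0:
            i += 1
        else:
            j += 1
    return out


def table1_cells() -> pd.DataFrame:
    """Per (species, location, season) specimen counts consistent with the
    published margins (long format, 48 rows)."""
    frames = []
    for sp in SPECIES:
        locs = [TABLE1_LOCATION_COUNTS[sp][l] for l in LOCATIONS]
        seas = _scaled_season_margin(sp)
        cells = _northwest_corner(locs, seas)
        for i, loc in enumerate(LOCATIONS):
            for j, season in enumerate(SEASONS):
                frames.append((sp, loc, season, int(cells[i, j])))
    return pd.DataFrame(frames, columns=["species", "location", "season", "n"])


def table1_stomach_table() -> StomachTable:
    """Expand the reconstructed design cells into 623 record stubs."""
    abbrev = {sp: "".join(w[0] for w in sp.split()) for sp in SPECIES}
    records = []
    for _, row in table1_cells().iterrows():
        for k in range(int(row["n"])):
            records.append(
                StomachRecord(
                    specimen_id=f"{abbrev[row['species']]}-{row['location']}-"
                    f"{row['season']}-{k + 1:03d}",
                    species=row["species"],
                    season=row["season"],
                    location=row["location"],
                    items={},
                )
            )
    return StomachTable(records, item_vocabulary=[], category_map={})


def bundled_table1_path() -> Path:
    """Path of the bundled specimen-stub CSV (core_data wide dialect)."""
    return Path(resources.files("dietpulse") / "data" / "table1_records.csv")


def load_bundled_table1() -> StomachTable:
    return read_stomach_table(bundled_table1_path())


def margin_report() -> list[str]:
    """Validation report of the reconstructed table against both published
    margins; nonempty exactly because of the N. notopterus inconsistency."""
    return table1_stomach_table().validate_margins(
        location_counts=TABLE1_LOCATION_COUNTS,
        season_counts=TABLE1_SEASON_COUNTS,
    )
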