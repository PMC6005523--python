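"""Synthetic stomach-content generator with known ground truth.

Emulates the structure of a seasonal multi-species stomach survey in a
flood-pulse lake: several species sampled over four hydrological seasons at
several locations, ~30 food items falling into six broad categories,
season-dependent probabilities of empty stomachs, species-specific seasonal
diet shifts, and a tunable amount of between-species dietary overlap.  Every
generated table ships with the generating parameters (:class:`TruthParams`)
so downstream estimators can be checked for parameter recovery, power and
type-I error without any external data.

Generative model
----------------
Per species s, a baseline item-probability vector is a mixture

    b_s = rho * shared + (1 - rho) * own_s,

where ``shared`` is one Dirichlet draw common to all species and ``own_s``
is species-specific; ``rho`` (overlap_share) therefore dials the expected
Pianka overlap from ~0 (disjoint-ish diets) to 1 (identical diets when
baselines coincide).  Per season t,

    p_{s,t} = (1 - delta) * b_s + delta * q_{s,t},

with ``q_{s,t}`` an independent Dirichlet draw, so ``delta`` (season_shift)
is a directly interpretable effect size for seasonal-difference tests
(delta = 0 means no seasonal diet change).

Each specimen is empty with the season's empty probability; otherwise its
number of distinct items m is zero-truncated Poisson and the m items are
drawn without replacement with probabilities p_{s,t}.  Occurrence therefore
equals the draw, matching the binarized frequency-of-occurrence pipeline.
Note that for m > 1, weighted sampling without replacement flattens
*inclusion* probabilities relative to p_{s,t}; empirical FOC profiles match
the generating vectors exactly only in the single-item regime
(items_per_stomach close to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import optimize, stats

from .core_data import (
    DEFAULT_CATEGORIES,
    DEFAULT_SEASONS,
    StomachRecord,
    StomachTable,
)
from .fixtures import SPECIES, TABLE1_SEASON_COUNTS

__all__ = ["SimConfig", "TruthParams", "generate", "expected_pianka"]


def default_cell_sizes(
    species: Sequence[str],
    seasons: Sequence[str],
    n_locations: int,
) -> dict[tuple[str, str, str], int]:
    """Per-(species, season, location) sample sizes mimicking the magnitudes
    of the published design: the per-(species, season) totals of the survey
    split as evenly as possible over the locations."""
    template = [
        [TABLE1_SEASON_COUNTS[sp][se] for se in DEFAULT_SEASONS] for sp in SPECIES
    ]
    out = {}
    for i, sp in enumerate(species):
        for j, se in enumerate(seasons):
            total = template[i % len(template)][j % len(template[0])]
            base, extra = divmod(total, n_locations)
            for k in range(n_locations):
                out[(sp, se, f"L{k + 1}")] = base + (1 if k < extra else 0)
    return out


@dataclass
class SimConfig:
    """Parameters of the synthetic survey.  Defaults are the study-like
    conditions: 3 species x 4 seasons x 4 locations, 30 items in 6
    categories, sample sizes of the published design's magnitude, highest
    empty-stomach probability in the receding season and lowest in the dry
    season (overall ~15%), a moderate seasonal diet shift and intermediate
    between-species overlap."""

    n_species: int = 3
    seasons: tuple[str, ...] = DEFAULT_SEASONS
    n_locations: int = 4
    n_items: int = 30
    category_sizes: tuple[int, ...] = (5, 5, 5, 5, 5, 5)
    cell_sizes: Mapping[tuple[str, str, str], int] | int | None = None
    empty_prob: Mapping[str, float] | float = field(
        default_factory=lambda: {
            "receding": 0.25,
            "wet": 0.15,
            "rising": 0.12,
            "dry": 0.05,
        }
    )
    baseline_conc: float = 0.5
    season_shift: float = 0.3  # delta in [0, 1]
    overlap_share: float = 0.5  # rho in [0, 1]
    items_per_stomach: float = 3.0  # mean of the zero-truncated Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.season_shift <= 1.0:
            raise ValueError("season_shift must lie in [0, 1]")
        if not 0.0 <= self.overlap_share <= 1.0:
            raise ValueError("overlap_share must lie in [0, 1]")
        if self.items_per_stomach < 1.0:
            raise ValueError("items_per_stomach is a mean of a count >= 1")
        if sum(self.category_sizes) != self.n_items:
            raise ValueError("category_sizes must partition n_items")
        for p in self._empty_prob_map().values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("empty_prob values must lie in [0, 1]")
        for n in self._cell_size_map().values():
            if n <= 0:
                raise ValueError("cell_sizes must be positive")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1}" for i in range(self.n_species))

    @property
    def locations(self) -> tuple[str, ...]:
        return tuple(f"L{i + 1}" for i in range(self.n_locations))

    @property
    def item_labels(self) -> tuple[str, ...]:
        labels = []
        for cat, size in zip(DEFAULT_CATEGORIES, self.category_sizes):
            labels += [f"{cat}_{k + 1}" for k in range(size)]
        return tuple(labels)

    @property
    def category_map(self) -> dict[str, str]:
        return {
            label: label.rsplit("_", 1)[0] for label in self.item_labels
        }

    def _empty_prob_map(self) -> dict[str, float]:
        if isinstance(self.empty_prob, Mapping):
            missing = [s for s in self.seasons if s not in self.empty_prob]
            if missing:
                raise ValueError(f"empty_prob missing seasons {missing}")
            return {s: float(self.empty_prob[s]) for s in self.seasons}
        return {s: float(self.empty_prob) for s in self.seasons}

    def _cell_size_map(self) -> dict[tuple[str, str, str], int]:
        if self.cell_sizes is None:
            return default_cell_sizes(self.species, self.seasons, self.n_locations)
        if isinstance(self.cell_sizes, int):
            return {
                (sp, se, loc): self.cell_sizes
                for sp in self.species
                for se in self.seasons
                for loc in self.locations
            }
        return {k: int(v) for k, v in self.cell_sizes.items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seasons" in raw:
            raw["seasons"] = tuple(raw["seasons"])
        if "category_sizes" in raw:
            raw["category_sizes"] = tuple(raw["category_sizes"])
        if "cell_sizes" in raw and isinstance(raw["cell_sizes"], list):
            raw["cell_sizes"] = {
                (d["species"], d["season"], d["location"]): int(d["n"])
                for d in raw["cell_sizes"]
            }
        return cls(**raw)


@dataclass
class TruthParams:
    """Ground truth behind one generated table: the realized per-(species,
    season) item-probability vectors, the expected pairwise Pianka overlaps
    they imply, and the empty-stomach probabilities used."""

    item_labels: tuple[str, ...]
    p: dict[tuple[str, str], np.ndarray]  # (species, season) -> prob vector
    expected_overlap: dict[tuple[str, str, str], float]  # (spA, spB, season)
    empty_prob: dict[str, float]

    def __post_init__(self) -> None:
        for key, vec in self.p.items():
            if abs(float(np.sum(vec)) - 1.0) > 1e-9:
                raise ValueError(f"probability vector for {key} does not sum to 1")

    def to_frame(self) -> "pd.DataFrame":  # noqa: F821 - sidecar convenience
        import pandas as pd

        rows = []
        for (sp, se), vec in self.p.items():
            row = {"species": sp, "season": se}
            row.update(dict(zip(self.item_labels, vec)))
            rows.append(row)
        return pd.DataFrame(rows)


def _pianka(p1: np.ndarray, p2: np.ndarray) -> float:
    num = float(np.dot(p1, p2))
    den = float(np.sqrt(np.dot(p1, p1) * np.dot(p2, p2)))
    return num / den


def expected_pianka(truth: TruthParams, pair: tuple[str, str], season: str) -> float:
    """Pianka's overlap of the two generating probability vectors."""
    a, b = sorted(pair)
    key = (a, b, season)
    if key not in truth.expected_overlap:
        raise KeyError(f"no such pair/season: {pair}, {season!r}")
    return truth.expected_overlap[key]


def _ztp_lambda(mean: float) -> float:
    """Rate of the zero-truncated Poisson with the given mean."""
    if mean <= 1.0 + 1e-12:
        return 1e-9
    return float(
        optimize.brentq(lambda lam: lam / (1 - np.exp(-lam)) - mean, 1e-9, 1e3)
    )


def _sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson by CDF inversion (exact, vectorized)."""
    p0 = np.exp(-lam)
    u = rng.uniform(p0, 1.0, size=size)
    return stats.poisson.ppf(u, lam).astype(int)


def generate(config: SimConfig) -> tuple[StomachTable, TruthParams]:
    """Draw one synthetic stomach table plus its ground truth.

    Fully reproducible: the same config (seed included) yields an identical
    table.  Raises if a drawn per-stomach item count exceeds the vocabulary
    size (infeasible without-replacement draw).
    """
    rng = np.random.default_rng(config.seed)
    n_items = config.n_items
    species = config.species
    seasons = config.seasons

    shared = rng.dirichlet(np.full(n_items, config.baseline_conc))
    truth_p: dict[tuple[str, str], np.ndarray] = {}
    for sp in species:
        own = rng.dirichlet(np.full(n_items, config.baseline_conc))
        base = config.overlap_share * shared + (1 - config.overlap_share) * own
        for se in seasons:
            q = rng.dirichlet(np.full(n_items, config.baseline_conc))
            truth_p[(sp, se)] = (
                (1 - config.season_shift) * base + config.season_shift * q
            )

    overlap = {}
    for i, a in enumerate(species):
        for b in species[i + 1 :]:
            for se in seasons:
                overlap[(a, b, se)] = _pianka(truth_p[(a, se)], truth_p[(b, se)])

    empty_prob = config._empty_prob_map()
    cell_sizes = config._cell_size_map()
    lam = _ztp_lambda(config.items_per_stomach)
    items = np.asarray(config.item_labels, dtype=object)

    records: list[StomachRecord] = []
    for sp in species:
        for se in seasons:
            p = truth_p[(sp, se)]
            for loc in config.locations:
                n = cell_sizes[(sp, se, loc)]
                empties = rng.uniform(size=n) < empty_prob[se]
                ms = _sample_ztp(rng, lam, n)
                for k in range(n):
                    sid = f"{sp}-{se}-{loc}-{k + 1:04d}"
                    if empties[k]:
                        records.append(
                            StomachRecord(sid, sp, se, loc, items={})
                        )
                        continue
                    m = int(ms[k])
                    if m > n_items:
                        raise ValueError(
                            f"drew {m} distinct items but only {n_items} exist"
                        )
                    chosen = rng.choice(items, size=m, replace=False, p=p)
                    records.append(
                        StomachRecord(sid, sp, se, loc, items={it: 1 for it in chosen})
                    )

    table = StomachTable(
        records=records,
        item_vocabulary=list(config.item_labels),
        category_map=config.category_map,
        seasons=tuple(seasons),
    )
    truth = TruthParams(
        item_labels=config.item_labels,
        p=truth_p,
        expected_overlap=overlap,
        empty_prob=empty_prob,
    )
    return table, truth


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Convenience for replicate loops: same conditions, new seed."""
    return replace(config, seed=seed)
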