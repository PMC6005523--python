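"""Simulation experiments: calibration, power and recovery studies.

These are the Monte-Carlo studies that justify trusting the estimators on
real stomach tables: type-I error of the seasonal ANOSIM when the generator
imposes no seasonal diet shift, its power under a strong shift, coverage of
the Pianka bootstrap null, rejection power of the dispersion test for
clearly unequal spreads, and recovery of generator-truth overlap.  They are
used by the test suite, the analysis drivers and the acceptance script, so
replicate counts are arguments with study-scale defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import build_community_matrix
from .dissimilarity import DissimilarityMatrix, bray_curtis
from .dispersion import permdisp_test
from .group_tests import GroupLabels, anosim
from .overlap import bootstrap_null, pianka, seasonal_overlap
from .simulate import SimConfig, expected_pianka, generate

__all__ = [
    "anosim_two_season_pvalue",
    "anosim_rejection_rate",
    "pianka_flag_rate",
    "pianka_recovery",
    "permdisp_rejection_rate",
    "simper_identity_residual",
]


def _two_season_config(
    delta: float, n_per_group: int, seed: int, **overrides
) -> SimConfig:
    """One species, wet-vs-dry contrast, one location, no empty stomachs."""
    kwargs = dict(
        n_species=1,
        seasons=("wet", "dry"),
        n_locations=1,
        cell_sizes=n_per_group,
        empty_prob=0.0,
        season_shift=delta,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def anosim_two_season_pvalue(
    delta: float, n_per_group: int, seed: int, n_perm: int = 199
) -> float:
    """p-value of the wet-vs-dry ANOSIM on one synthetic draw."""
    table, _ = generate(_two_season_config(delta, n_per_group, seed))
    matrix = build_community_matrix(table, unit="stomach", level="item", binarize=True)
    D = bray_curtis(matrix)
    groups = GroupLabels(matrix.unit_labels["season"].to_numpy())
    return anosim(D, groups, n_perm=n_perm, seed=seed).p_value


def anosim_rejection_rate(
    delta: float,
    n_per_group: int,
    n_rep: int,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> float:
    """Fraction of replicates in which the seasonal ANOSIM rejects at alpha.

    With ``delta = 0`` this estimates the type-I error; with a positive
    shift it estimates power.
    """
    rejections = 0
    for r in range(n_rep):
        p = anosim_two_season_pvalue(delta, n_per_group, seed=seed * 100003 + r,
                                     n_perm=n_perm)
        rejections += p <= alpha
    return rejections / n_rep


def pianka_flag_rate(
    n_rep: int = 200,
    delta: float = 0.0,
    n_per_cell: int = 30,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of (pair, season) observed overlaps flagged outside the
    bootstrap null's 95% CI, across generator replicates.

    Under ``delta = 0`` (no seasonal variation — the null of the bootstrap
    procedure is true) this should sit near 5%.
    """
    outside = 0
    total = 0
    for r in range(n_rep):
        cfg = SimConfig(
            n_species=2,
            n_locations=1,
            cell_sizes=n_per_cell,
            empty_prob=0.0,
            season_shift=delta,
            seed=seed * 100003 + r,
        )
        table, _ = generate(cfg)
        res = bootstrap_null(
            table, ("sp1", "sp2"), n_boot=n_boot, seed=seed * 100003 + r
        )
        for flag in res.flags.values():
            outside += flag != "inside"
            total += 1
    return outside / total


def pianka_seasonal_flag_any_rate(
    n_rep: int = 50,
    rho_by_season: dict[str, float] | None = None,
    n_per_cell: int = 60,
    n_boot: int = 500,
    seed: int = 0,
) -> float:
    """Sensitivity check: with a strong generator-imposed seasonal change in
    overlap, the fraction of replicates flagging at least one season."""
    if rho_by_season is None:
        rho_by_season = {"receding": 0.1, "wet": 0.37, "rising": 0.63, "dry": 0.9}
    seasons = tuple(rho_by_season)
    hits = 0
    for r in range(n_rep):
        rep_seed = seed * 100003 + r
        rng = np.random.default_rng(rep_seed)
        # per-season overlap imposed by drawing each season's pair of
        # vectors as a shared/own mixture with that season's rho
        n_items = 30
        p: dict[tuple[str, str], np.ndarray] = {}
        for se in seasons:
            shared = rng.dirichlet(np.full(n_items, 0.5))
            rho = rho_by_season[se]
            for sp in ("sp1", "sp2"):
                own = rng.dirichlet(np.full(n_items, 0.5))
                p[(sp, se)] = rho * shared + (1 - rho) * own
        table = _table_from_vectors(p, seasons, n_per_cell, rep_seed)
        res = bootstrap_null(table, ("sp1", "sp2"), n_boot=n_boot, seed=rep_seed)
        if any(flag != "inside" for flag in res.flags.values()):
            hits += 1
    return hits / n_rep


def _table_from_vectors(p, seasons, n_per_cell, seed):
    """Build a stomach table directly from per-(species, season) vectors."""
    from .core_data import StomachRecord, StomachTable
    from .simulate import SimConfig as _SC

    cfg = _SC(n_species=2, seasons=seasons, n_locations=1, cell_sizes=n_per_cell,
              empty_prob=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    items = np.asarray(cfg.item_labels, dtype=object)
    records = []
    for (sp, se), vec in p.items():
        for k in range(n_per_cell):
            m = 1 + int(rng.poisson(2.0))
            m = min(m, len(items))
            chosen = rng.choice(items, size=m, replace=False, p=vec)
            records.append(
                StomachRecord(f"{sp}-{se}-{k:04d}", sp, se, "L1",
                              items={it: 1 for it in chosen})
            )
    return StomachTable(records, list(cfg.item_labels), cfg.category_map,
                        tuple(seasons))


def pianka_recovery(
    n_per_cell: int = 500,
    rho: float = 0.7,
    delta: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed seasonal Pianka vs. generator-truth expectation.

    Uses the single-item-per-stomach regime, in which empirical FOC
    profiles converge exactly to the generating vectors (see the generator
    notes on without-replacement flattening).
    """
    cfg = SimConfig(
        n_species=2,
        n_locations=1,
        cell_sizes=n_per_cell,
        empty_prob=0.0,
        overlap_share=rho,
        season_shift=delta,
        items_per_stomach=1.0,
        seed=seed,
    )
    table, truth = generate(cfg)
    observed = seasonal_overlap(table)[0]
    rows = []
    for season, o in observed.by_season.items():
        e = expected_pianka(truth, observed.pair, season)
        rows.append(
            {"season": season, "observed": o, "expected": e, "error": o - e}
        )
    return pd.DataFrame(rows)


def permdisp_rejection_rate(
    radius_a: float = 0.1,
    radius_b: float = 1.0,
    n_per_group: int = 20,
    n_rep: int = 100,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
) -> float:
    """Rejection rate of the dispersion test for two Gaussian clouds of
    clearly different spread (Euclidean distances)."""
    rejections = 0
    for r in range(n_rep):
        rng = np.random.default_rng(seed * 100003 + r)
        a = rng.normal(scale=radius_a, size=(n_per_group, 2))
        b = rng.normal(scale=radius_b, size=(n_per_group, 2)) + 5.0
        pts = np.vstack([a, b])
        from scipy.spatial.distance import pdist, squareform

        D = DissimilarityMatrix(
            squareform(pdist(pts)),
            pd.DataFrame({"specimen_id": [str(i) for i in range(len(pts))]}),
            "euclidean",
        )
        groups = GroupLabels(np.array(["a"] * n_per_group + ["b"] * n_per_group))
        res = permdisp_test(D, groups, n_perm=n_perm, seed=seed * 100003 + r)
        rejections += res.p_value <= alpha
    return rejections / n_rep


def simper_identity_residual(n_instances: int = 100, seed: int = 0) -> float:
    """Max |sum of per-item SIMPER averages - mean between-group
    Bray-Curtis| over random community matrices (should be ~0)."""
    from .core_data import CommunityMatrix
    from .group_tests import simper

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n_a = int(rng.integers(3, 8))
        n_b = int(rng.integers(3, 8))
        n_items = int(rng.integers(2, 10))
        Y = rng.integers(0, 5, size=(n_a + n_b, n_items)).astype(float)
        Y[Y.sum(axis=1) == 0, 0] = 1.0  # no empty units by contract
        matrix = CommunityMatrix(
            Y,
            pd.DataFrame(
                {
                    "specimen_id": [str(i) for i in range(n_a + n_b)],
                    "species": ["x"] * (n_a + n_b),
                    "season": ["wet"] * n_a + ["dry"] * n_b,
                    "location": ["L1"] * (n_a + n_b),
                }
            ),
            [f"item{i}" for i in range(n_items)],
            "item",
        )
        labels = GroupLabels(matrix.unit_labels["season"].to_numpy())
        res = simper(matrix, labels, n_perm=1, seed=0)
        D = bray_curtis(matrix)
        between = D.d[:n_a, n_a:]
        worst = max(worst, abs(res.average.sum() - between.mean()))
    return worst
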