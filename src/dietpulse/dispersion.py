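"""Diet breadth as multivariate dispersion, with a permutation F-test.

A species' diet breadth in a given season is operationalized as the average
distance of its sampling units (non-empty stomachs) to their group centroid
in the principal-coordinate embedding of the Bray-Curtis matrix — larger
values mean a broader, more variable diet.  Between-species differences per
season are tested with a one-way permutation F-test on the per-unit
distances (the multivariate homogeneity-of-dispersions procedure): group
labels are permuted and the distances *recomputed* under each relabeling,
because the exchangeable unit is the observation, not its distance.

Bray-Curtis embeddings are generally non-Euclidean; squared distances to
centroids subtract the imaginary-axis part and are clamped at zero (with a
warning) before the square root, the standard correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import StomachTable, ValidationError, build_community_matrix
from .dissimilarity import DissimilarityMatrix, PcoaResult, bray_curtis, pcoa
from .group_tests import GroupLabels, _check_groups

__all__ = [
    "DispersionResult",
    "group_dispersion",
    "permdisp_test",
    "dispersion_by_season",
]


@dataclass
class DispersionResult:
    """Per-group mean distances to centroid plus the permutation F-test."""

    group_means: dict  # group level -> mean distance (the diet breadth)
    unit_distances: np.ndarray
    labels: np.ndarray
    F_statistic: float
    p_value: float
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [{"group": g, "diet_breadth": m} for g, m in self.group_means.items()]
        )
        df["p_value"] = self.p_value
        return df


def _distances_to_centroids(
    coords: PcoaResult, labels: np.ndarray
) -> np.ndarray:
    """Distance of each unit to its own group's centroid.

    Squared distance = (squared Euclidean on real axes) - (squared Euclidean
    on imaginary axes), clamped at zero.
    """
    xr, xi = coords.real_coords, coords.imag_coords
    sq = np.empty(len(labels))
    for g in dict.fromkeys(labels.tolist()):
        rows = labels == g
        cr = xr[rows].mean(axis=0) if xr.size else np.zeros(xr.shape[1])
        ci = xi[rows].mean(axis=0) if xi.size else np.zeros(xi.shape[1])
        sq[rows] = ((xr[rows] - cr) ** 2).sum(axis=1) - (
            (xi[rows] - ci) ** 2
        ).sum(axis=1)
    if np.any(sq < -1e-12):
        warnings.warn(
            "negative squared distances from imaginary axes clamped at 0",
            stacklevel=3,
        )
    return np.sqrt(np.clip(sq, 0.0, None))


def group_dispersion(
    D: DissimilarityMatrix, groups: GroupLabels
) -> tuple[np.ndarray, dict]:
    """Per-unit distances to group centroids and per-group means."""
    labels = np.asarray(groups.labels)
    if len(labels) != D.n_units:
        raise ValidationError("labels length does not match dissimilarity matrix")
    levels, counts = np.unique(labels.astype(str), return_counts=True)
    if np.any(counts < 2):
        raise ValidationError(
            f"groups of size 1 have undefined dispersion: "
            f"{levels[counts < 2].tolist()}"
        )
    coords = pcoa(D)
    dist = _distances_to_centroids(coords, labels)
    means = {
        g: float(dist[labels == g].mean()) for g in dict.fromkeys(labels.tolist())
    }
    return dist, means


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F on per-unit distances; 0 when within-group variance
    vanishes together with between-group variance."""
    grand = values.mean()
    ss_between = ss_within = 0.0
    k = 0
    for g in dict.fromkeys(labels.tolist()):
        grp = values[labels == g]
        ss_between += len(grp) * (grp.mean() - grand) ** 2
        ss_within += ((grp - grp.mean()) ** 2).sum()
        k += 1
    n = len(values)
    scale = float((values**2).sum()) + 1e-300
    if ss_within <= 1e-12 * scale:
        return 0.0 if ss_between <= 1e-12 * scale else np.inf
    return (ss_between / (k - 1)) / (ss_within / (n - k))


def permdisp_test(
    D: DissimilarityMatrix,
    groups: GroupLabels,
    n_perm: int = 1000,
    seed: int = 0,
) -> DispersionResult:
    """Permutation test for equality of multivariate dispersions.

    The PCoA embedding is computed once; each permutation reassigns the
    group labels, recomputes centroids and distances in that embedding, and
    re-evaluates the F statistic.  p = (#{F_perm >= F} + 1) / (n_perm + 1).
    """
    labels = np.asarray(groups.labels)
    if len(labels) != D.n_units:
        raise ValidationError("labels length does not match dissimilarity matrix")
    _check_groups(labels)
    levels, counts = np.unique(labels.astype(str), return_counts=True)
    if np.any(counts < 2):
        raise ValidationError(
            f"groups of size 1: {levels[counts < 2].tolist()}"
        )
    coords = pcoa(D)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist = _distances_to_centroids(coords, labels)
        F = _anova_f(dist, labels)
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            perm_dist = _distances_to_centroids(coords, perm)
            if _anova_f(perm_dist, perm) >= F:
                exceed += 1
    means = {
        g: float(dist[labels == g].mean()) for g in dict.fromkeys(labels.tolist())
    }
    return DispersionResult(
        group_means=means,
        unit_distances=dist,
        labels=labels,
        F_statistic=float(F),
        p_value=(exceed + 1) / (n_perm + 1),
        n_perm=n_perm,
        seed=seed,
    )


def dispersion_by_season(
    table: StomachTable,
    level: str = "item",
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, DispersionResult]]:
    """The season-wise diet-breadth analysis: one between-species dispersion
    test per season.

    Returns a seasons x species table of diet breadths with the per-season
    permutation p-value in the last column, plus the full per-season
    results.  Per-season seeds are derived from ``seed`` by offset so the
    four tests are independently reproducible.
    """
    matrix = build_community_matrix(table, unit="stomach", level=level, binarize=True)
    D = bray_curtis(matrix)
    seasons = [s for s in table.seasons
               if s in set(matrix.unit_labels["season"])]
    results: dict[str, DispersionResult] = {}
    rows = []
    for i, season in enumerate(seasons):
        mask = (matrix.unit_labels["season"] == season).to_numpy()
        sub = DissimilarityMatrix(
            D.d[np.ix_(mask, mask)],
            matrix.unit_labels.loc[mask].reset_index(drop=True),
            D.metric_name,
        )
        groups = GroupLabels(sub.unit_labels["species"].to_numpy())
        res = permdisp_test(sub, groups, n_perm=n_perm, seed=seed + i)
        results[season] = res
        row = {"season": season}
        row.update({sp: res.group_means.get(sp, np.nan) for sp in table.species_levels})
        row["p_value"] = res.p_value
        rows.append(row)
    return pd.DataFrame(rows), results
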