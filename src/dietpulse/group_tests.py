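"""Permutation tests of group differences in diet composition.

ANOSIM (analysis of similarities) asks whether between-group rank
dissimilarities exceed within-group ones; SIMPER (similarity percentages)
decomposes the average between-group Bray-Curtis dissimilarity into per-item
contributions; the chi-square test of independence checks whether the
seasonal pattern of empty stomachs depends on species.

Both permutation tests permute *group labels*, use add-one p-values
p = (b + 1) / (n_perm + 1) so a Monte-Carlo p is never zero, and record
their seed in the result object.  The observed labeling is never counted
among the permutations.

A note on the R statistic's range: R = (rbar_between - rbar_within) /
(n(n-1)/4) lies in [-1, 1].  Strong group structure gives R near 1; R near
zero means high and low ranks are evenly mixed within and between groups;
negative values (more similarity between groups than within) are possible
though rarely of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from .core_data import CommunityMatrix, CountTable, ValidationError
from .dissimilarity import DissimilarityMatrix

__all__ = [
    "GroupLabels",
    "AnosimResult",
    "SimperResult",
    "ChiSquareResult",
    "anosim",
    "simper",
    "chi_square_independence",
]


@dataclass
class GroupLabels:
    """Per-unit categorical assignment used by the permutation tests."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    @property
    def levels(self) -> list:
        return list(dict.fromkeys(self.labels.tolist()))

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_units(cls, D: DissimilarityMatrix, factor: str) -> "GroupLabels":
        return cls(D.unit_labels[factor].to_numpy())


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_perm: int
    null_R: np.ndarray
    seed: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"statistic": self.R, "p_value": self.p_value,
              "n_perm": self.n_perm, "seed": self.seed}]
        )


@dataclass
class SimperResult:
    """Per-item decomposition of the mean between-group dissimilarity."""

    items: list[str]
    average: np.ndarray
    sd: np.ndarray
    p_values: np.ndarray
    overall_mean_dissimilarity: float
    n_perm: int
    seed: int
    p_adjusted: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "item": self.items,
                "average_contribution": self.average,
                "sd": self.sd,
                "p_value": self.p_values,
            }
        )
        if self.p_adjusted is not None:
            df["p_holm"] = self.p_adjusted
        return df


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"statistic": self.statistic, "df": self.df, "p_value": self.p_value}]
        )


def _check_groups(labels: np.ndarray, min_size: int = 2) -> None:
    levels, counts = np.unique(labels.astype(str), return_counts=True)
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    small = levels[counts < min_size]
    if small.size:
        raise ValidationError(
            f"groups of size < {min_size}: {small.tolist()}"
        )


def anosim(
    D: DissimilarityMatrix,
    groups: GroupLabels,
    n_perm: int = 1000,
    seed: int = 0,
) -> AnosimResult:
    """Clarke's analysis of similarities.

    All n(n-1)/2 dissimilarities are ranked (average ranks on ties) and

        R = (rbar_between - rbar_within) / (n(n-1)/4).

    Significance comes from permuting the unit labels ``n_perm`` times.  A
    constant dissimilarity matrix carries no group information; R is then 0
    by construction and a warning is emitted.
    """
    labels = np.asarray(groups.labels)
    if len(labels) != D.n_units:
        raise ValidationError("labels length does not match dissimilarity matrix")
    _check_groups(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    dcond = D.condensed()
    n = D.n_units
    if np.ptp(dcond) == 0:
        warnings.warn("constant dissimilarity matrix: R defined as 0", stacklevel=2)
    ranks = stats.rankdata(dcond)
    denom = n * (n - 1) / 4.0
    iu, ju = np.triu_indices(n, k=1)

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        if within.all() or not within.any():  # cannot happen after _check_groups
            return 0.0
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    R = r_stat(labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = r_stat(rng.permutation(labels))
    p = (np.count_nonzero(null >= R) + 1) / (n_perm + 1)
    return AnosimResult(R=float(R), p_value=float(p), n_perm=n_perm,
                        null_R=null, seed=seed)


def simper(
    matrix: CommunityMatrix,
    groups: GroupLabels,
    n_perm: int = 1000,
    seed: int = 0,
    holm: bool = False,
) -> SimperResult:
    """Similarity-percentage decomposition between exactly two groups.

    For each between-group pair of units (j, k) the Bray-Curtis
    dissimilarity splits additively over items:

        delta_i(j,k) = |y_ij - y_ik| / sum_m (y_mj + y_mk),

    so the per-item averages over all between-group pairs sum exactly to the
    mean between-group dissimilarity.  Per-item significance is assessed by
    permuting group labels: p_i = (#{perm average_i >= observed_i} + 1) /
    (n_perm + 1).  No multiplicity correction by default (``holm=True``
    adds a Holm-adjusted column).
    """
    labels = np.asarray(groups.labels)
    levels = list(dict.fromkeys(labels.tolist()))
    if len(levels) != 2:
        raise ValidationError(
            f"simper contrasts exactly 2 groups, got {len(levels)}; "
            "call pairwise for more"
        )
    _check_groups(labels, min_size=1)
    Y = matrix.values

    def contributions(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = Y[lab == levels[0]]
        b = Y[lab == levels[1]]
        diff = np.abs(a[:, None, :] - b[None, :, :])
        denom = (a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :])[..., None]
        delta = (diff / denom).reshape(-1, Y.shape[1])
        return delta.mean(axis=0), delta.std(axis=0, ddof=0)

    avg, sd = contributions(labels)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(Y.shape[1], dtype=int)
    for _ in range(n_perm):
        perm_avg, _ = contributions(rng.permutation(labels))
        exceed += perm_avg >= avg
    p = (exceed + 1) / (n_perm + 1)
    adjusted = _holm(p) if holm else None
    return SimperResult(
        items=list(matrix.item_labels),
        average=avg,
        sd=sd,
        p_values=p,
        overall_mean_dissimilarity=float(avg.sum()),
        n_perm=n_perm,
        seed=seed,
        p_adjusted=adjusted,
    )


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def chi_square_independence(counts: CountTable) -> ChiSquareResult:
    """Pearson chi-square test of independence on a two-way count table.

    No continuity correction (matching the classical multi-df test);
    df = (rows - 1)(cols - 1).
    """
    obs = counts.to_frame().to_numpy(dtype=float)
    if obs.size == 0:
        raise ValidationError("empty count table")
    if np.any(obs < 0):
        raise ValidationError("counts must be nonnegative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValidationError("zero margin in count table")
    res = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        expected=np.asarray(res.expected_freq),
    )
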