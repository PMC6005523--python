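"""Non-metric multidimensional scaling (Kruskal stress-1).

NMDS embeds sampling units in a low-dimensional space so that the *rank
order* of configuration distances matches the rank order of the input
dissimilarities — only the ordering of the Bray-Curtis values matters,
which suits occurrence data.  The fit alternates

1. a monotone (isotonic) regression of configuration distances on the rank
   order of the dissimilarities, yielding fitted "disparities" (ties in the
   input receive average ranks and are averaged within tied blocks), and
2. a Guttman-transform configuration update toward those disparities,

minimizing Kruskal's stress-1 = sqrt(sum (d_config - disparity)^2 /
sum d_config^2).  Multiple starts (a PCoA start plus random starts) guard
against local minima; the best-stress solution is returned, centered and
rotated to its principal axes so results are comparable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .dissimilarity import DissimilarityMatrix, pcoa

__all__ = ["NmdsResult", "nmds", "stress1"]


@dataclass
class NmdsResult:
    configuration: np.ndarray  # units x k, centered, principal-axis rotated
    stress: float
    n_starts: int
    best_start_index: int
    converged: bool
    seed: int
    stress_history: list[np.ndarray]  # per start, recorded iterates

    def to_frame(self, unit_labels: pd.DataFrame | None = None) -> pd.DataFrame:
        k = self.configuration.shape[1]
        df = pd.DataFrame(
            self.configuration, columns=[f"axis{i + 1}" for i in range(k)]
        )
        if unit_labels is not None:
            df = pd.concat([unit_labels.reset_index(drop=True), df], axis=1)
        return df


def _disparities(dcond: np.ndarray, conf_dist: np.ndarray) -> np.ndarray:
    """Monotone fit of configuration distances on the dissimilarity ranks."""
    ranks = stats.rankdata(dcond)  # average ranks; ties averaged by isotonic fit
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    return iso.fit_transform(ranks, conf_dist)


def stress1(configuration: np.ndarray, D: DissimilarityMatrix) -> float:
    """Kruskal's stress-1 of a configuration against a dissimilarity matrix.

    Zero iff the configuration distances are a monotone transform of the
    dissimilarities.  A degenerate all-coincident configuration against a
    non-constant D has no meaningful fit: returns 1 with a warning.
    """
    X = np.asarray(configuration, dtype=float)
    if X.shape[0] != D.n_units:
        raise ValueError("configuration and dissimilarity sizes disagree")
    dcond = D.condensed()
    conf = pdist(X)
    if np.allclose(conf, 0.0):
        if np.ptp(dcond) > 0:
            warnings.warn(
                "all configuration points coincide: stress undefined, "
                "returning 1",
                stacklevel=2,
            )
            return 1.0
        return 0.0
    dhat = _disparities(dcond, conf)
    return float(np.sqrt(((conf - dhat) ** 2).sum() / (conf**2).sum()))


def _guttman_update(X: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    """One Guttman transform step toward the disparities."""
    n = X.shape[0]
    d = squareform(pdist(X))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, squareform(dhat) / np.where(d > 0, d, 1.0), 0.0)
    B = -ratio
    np.fill_diagonal(B, ratio.sum(axis=1))
    return (B @ X) / n


def _principal_axes(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each axis positive
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    return X @ vt.T


def nmds(
    D: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> NmdsResult:
    """Fit a k-dimensional NMDS configuration.

    Start 0 is the PCoA configuration (truncated/padded to k axes); the
    remaining ``n_starts - 1`` starts are standard-normal random.  Within a
    start, iteration stops when the stress decrease falls below ``tol`` (or
    stress reaches ~0); the best final stress across starts wins.
    """
    n = D.n_units
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k = {k} requires more than {n} units")
    dcond = D.condensed()
    rng = np.random.default_rng(seed)

    starts: list[np.ndarray] = []
    # The metric start is computed on the *rank-transformed* dissimilarities
    # so the whole fit depends on D only through its rank order (exact
    # invariance under monotone transforms of the input).
    ranks = stats.rankdata(dcond)
    Drank = DissimilarityMatrix(
        squareform(ranks / ranks.max()),
        pd.DataFrame({"specimen_id": [str(i) for i in range(n)]}),
        "rank",
    )
    pc = pcoa(Drank).real_coords
    init = np.zeros((n, k))
    m = min(k, pc.shape[1])
    init[:, :m] = pc[:, :m]
    starts.append(init)
    for _ in range(n_starts - 1):
        starts.append(rng.standard_normal((n, k)))

    best: tuple[float, np.ndarray, int, bool] | None = None
    history: list[np.ndarray] = []
    for s_idx, X in enumerate(starts):
        X = X.copy()
        prev = np.inf
        iterates = []
        converged = False
        for _ in range(max_iter):
            conf = pdist(X)
            if np.allclose(conf, 0.0):
                X = X + 1e-6 * rng.standard_normal(X.shape)
                conf = pdist(X)
            dhat = _disparities(dcond, conf)
            cur = float(np.sqrt(((conf - dhat) ** 2).sum() / (conf**2).sum()))
            iterates.append(cur)
            if prev - cur < tol:
                converged = True
                break
            prev = cur
            X = _guttman_update(X, dhat)
        history.append(np.asarray(iterates))
        final = iterates[-1]
        if best is None or final < best[0]:
            best = (final, X, s_idx, converged)

    assert best is not None
    stress, X, idx, converged = best
    # stress-1 is scale-free; fix the output scale so RMS configuration
    # distance equals RMS input dissimilarity (comparable across runs)
    conf = pdist(X)
    if conf.sum() > 0:
        X = X * np.sqrt((dcond**2).sum() / (conf**2).sum())
    return NmdsResult(
        configuration=_principal_axes(X),
        stress=stress,
        n_starts=n_starts,
        best_start_index=idx,
        converged=converged,
        seed=seed,
        stress_history=history,
    )


def group_ellipses(
    coords: pd.DataFrame, group_col: str = "species"
) -> pd.DataFrame:
    """1-SD covariance ellipse parameters per group (for Fig-style biplots).

    Returns center, semi-axes and orientation of each group's covariance
    ellipse at one standard deviation; the ellipse convention is recorded in
    the ``kind`` column of the output.
    """
    rows = []
    for g, grp in coords.groupby(group_col):
        xy = grp[["axis1", "axis2"]].to_numpy()
        center = xy.mean(axis=0)
        cov = np.cov(xy.T) if len(xy) > 1 else np.zeros((2, 2))
        eigval, eigvec = np.linalg.eigh(cov)
        angle = float(np.degrees(np.arctan2(eigvec[1, 1], eigvec[0, 1])))
        rows.append(
            {
                group_col: g,
                "center_x": center[0],
                "center_y": center[1],
                "semi_major": float(np.sqrt(max(eigval[1], 0.0))),
                "semi_minor": float(np.sqrt(max(eigval[0], 0.0))),
                "angle_deg": angle,
                "kind": "1-sd covariance ellipse",
            }
        )
    return pd.DataFrame(rows)


def plot_nmds(
    coords: pd.DataFrame,
    group_col: str = "species",
    ax=None,
):
    """Fig-style NMDS biplot with per-group 1-SD ellipses."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    if ax is None:
        _, ax = plt.subplots()
    for g, grp in coords.groupby(group_col):
        sc = ax.scatter(grp["axis1"], grp["axis2"], s=12, label=str(g))
        color = sc.get_facecolor()[0]
        e = group_ellipses(grp.assign(**{group_col: g}), group_col).iloc[0]
        ax.add_patch(
            Ellipse(
                (e["center_x"], e["center_y"]),
                2 * e["semi_major"],
                2 * e["semi_minor"],
                angle=e["angle_deg"],
                fill=False,
                edgecolor=color,
            )
        )
    ax.set_xlabel("NMDS axis 1")
    ax.set_ylabel("NMDS axis 2")
    ax.legend()
    return ax
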