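#!/usr/bin/env python
"""NMDS ordination of the stomach-content matrix.

Two-dimensional non-metric MDS of the item-level Bray-Curtis matrix, with
per-(species, season) 1-SD covariance ellipses summarizing diet spread and
overlap, plus a biplot figure.

Writes results/nmds_coords.csv and results/nmds_ellipses.csv; the biplot
figure goes to scratch/nmds_biplot.png.
"""

from pathlib import Path

from dietpulse.core_data import build_community_matrix, read_stomach_table
from dietpulse.dissimilarity import bray_curtis
from dietpulse.ordination import group_ellipses, nmds, plot_nmds

OUT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 606


def main() -> None:
    table = read_stomach_table(OUT / "synthetic_survey.csv")
    matrix = build_community_matrix(table, level="item")
    res = nmds(bray_curtis(matrix), k=2, n_starts=20, seed=SEED)
    coords = res.to_frame(matrix.unit_labels)
    coords.to_csv(OUT / "nmds_coords.csv", index=False)
    ell = group_ellipses(coords, group_col="species")
    ell.to_csv(OUT / "nmds_ellipses.csv", index=False)

    SCRATCH.mkdir(exist_ok=True)
    import matplotlib

    matplotlib.use("Agg")
    ax = plot_nmds(coords, group_col="species")
    ax.set_title(f"NMDS of stomach contents (stress = {res.stress:.3f})")
    ax.figure.savefig(SCRATCH / "nmds_biplot.png", dpi=150)

    print(f"stress = {res.stress:.4f} (best of {res.n_starts} starts, "
          f"converged={res.converged})")
    print("species ellipses (1 SD):")
    print(ell.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
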