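#!/usr/bin/env python
"""Diet composition summaries: empty stomachs, FOC profiles, category importance.

On the synthetic survey from 02_simulate_survey.py: the proportion of empty
stomachs per species and season with the chi-square test of whether the
seasonal feeding pattern depends on species, and each species' seasonal
diet described by frequency-of-occurrence profiles aggregated to the six
broad food categories.

Writes results/empty_stomachs.csv, results/empty_chisq.csv and
results/category_importance.csv.
"""

from pathlib import Path

from dietpulse.core_data import (
    build_community_matrix,
    category_importance,
    empty_stomach_counts,
    empty_stomach_summary,
    foc_profiles,
    read_stomach_table,
)
from dietpulse.group_tests import chi_square_independence

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_stomach_table(OUT / "synthetic_survey.csv")

    prop = empty_stomach_summary(table)
    prop.to_csv(OUT / "empty_stomachs.csv")
    chi = chi_square_independence(empty_stomach_counts(table))
    chi.summary().to_csv(OUT / "empty_chisq.csv", index=False)
    print("proportion of empty stomachs:")
    print(prop.round(3))
    print(f"\nspecies x season independence of empty counts: "
          f"chi2 = {chi.statistic:.2f}, df = {chi.df}, p = {chi.p_value:.2f}")

    matrix = build_community_matrix(table, unit="stomach", level="item",
                                    binarize=True)
    profiles = foc_profiles(matrix, by=("species", "season"))
    imp = category_importance(profiles, table.category_map)
    imp.to_csv(OUT / "category_importance.csv")
    print("\ncategory importance (species, season -> share of diet):")
    print(imp.round(2))


if __name__ == "__main__":
    main()
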