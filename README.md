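# dietpulse

Seasonal stomach-content diet analysis for multi-species fish surveys in
flood-pulse systems — built around the classic Tonle Sap Lake design:
three species (*Anabas testudineus*, *Boesemania microlepis*, *Notopterus
notopterus*) sampled at four locations over the four hydrological phases
(receding, wet, rising, dry), with ~30 prey types grouped into six broad
categories.

It is written for trophic ecologists who have a per-specimen table of
stomach records (species, season, location, per-item occurrences, empty
stomachs flagged) and want the standard seasonal-diet toolkit with
reproducible permutation statistics:

- **Frequency of occurrence (FOC).** For a group of non-empty stomachs,
  item *i*'s FOC is the number of stomachs containing *i* divided by the
  total number of item occurrences, so each group's profile `p` sums to 1.
  Category importance is the mean item FOC per category, renormalized.
- **Empty-stomach chi-square.** Pearson test of independence on the
  species × season table of empty counts (df = (r−1)(c−1)).
- **ANOSIM.** Clarke's rank test on the Bray–Curtis matrix,
  `R = (r̄_between − r̄_within) / (n(n−1)/4)` ∈ [−1, 1], with label
  permutations and add-one p-values.
- **SIMPER.** Per-item decomposition of the mean between-group Bray–Curtis
  dissimilarity, `δ_i(j,k) = |y_ij − y_ik| / Σ_m (y_mj + y_mk)`, with
  per-item permutation significance.
- **Diet breadth.** Mean distance of a group's stomachs to their centroid
  in the PCoA embedding of the Bray–Curtis matrix (imaginary axes handled
  by signed squared distances), with a permutation F-test of
  between-species differences per season.
- **NMDS.** Kruskal stress-1 ordination (isotonic regression + Guttman
  updates, multiple starts), exactly invariant under monotone transforms
  of the input dissimilarities.
- **Pianka overlap.** `O = Σ p1_i p2_i / √(Σ p1_i² Σ p2_i²)` per species
  pair and season, tested against a bootstrap null (stomach rows resampled
  with replacement, seasons pooled) with 95% percentile intervals.

A synthetic-survey generator (`dietpulse.simulate`) emulates the study's
structure with known ground truth — Dirichlet diet vectors, a tunable
seasonal shift δ and between-species overlap share ρ — so every estimator
ships with type-I, power and recovery studies (`dietpulse.experiments`).

## Worked example

```python
from dietpulse import (SimConfig, generate, build_community_matrix,
                       bray_curtis, anosim, GroupLabels, StomachTable)

table, truth = generate(SimConfig(seed=42))        # 3 sp x 4 seasons x 4 sites
wetdry = StomachTable(
    [r for r in table.records if r.species == "sp1" and r.season in ("wet", "dry")],
    table.item_vocabulary, table.category_map, table.seasons)
m = build_community_matrix(wetdry, unit="stomach", level="item", binarize=True)
res = anosim(bray_curtis(m), GroupLabels(m.unit_labels["season"].to_numpy()),
             n_perm=999, seed=1)
print(f"R = {res.R:.3f}, p = {res.p_value:.3f}")
```

prints

```
R = 0.035, p = 0.009
```

i.e. a weak but detectable wet-vs-dry diet shift for this species at the
generator's default seasonal effect (δ = 0.3) — R near 0 means high and
low dissimilarity ranks are mixed within and between seasons; R near 1
would mean complete separation.

The full study workflow is scripted under `analysis/` (run in numeric
order; outputs land in `results/`):

| script | what it does |
| --- | --- |
| `01_reconstruct_survey_design.py` | expands the bundled specimen-count fixture, tallies species × location/season, reports the published margin inconsistency |
| `02_simulate_survey.py` | draws the synthetic survey + ground truth used by 03–07 |
| `03_diet_composition.py` | empty-stomach proportions + chi-square, FOC profiles, category importance |
| `04_seasonal_contrast.py` | wet-vs-dry ANOSIM (item level) and SIMPER (category level) per species |
| `05_diet_breadth.py` | per-season dispersion (diet breadth) tests across species |
| `06_ordination.py` | 2-D NMDS with per-species 1-SD ellipses |
| `07_dietary_overlap.py` | Pianka index per pair/season vs bootstrap null |
| `08_calibration.py` | Monte-Carlo type-I/power/coverage/recovery studies |

The same workflow is available as one call (`dietpulse.run_pipeline`) or
from the shell (`dietpulse run config.yaml`, plus single-stage commands
`simulate | anosim | simper | dispersion | nmds | overlap`).

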