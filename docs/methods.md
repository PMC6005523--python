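# Methods

This note documents the models, estimators, defaults and numerical choices
behind `dietpulse`, and what the synthetic-data studies do and do not show
about real stomach-content data.

## Data model

A stomach table is an ordered list of specimen records: species, season
(an ordered label set, by default the four flood-pulse phases receding /
wet / rising / dry — no dates are parsed), location, optional body length
(cm), and a mapping of food-item labels to occurrence counts.  A record is
*empty* iff all counts are zero.  Empty stomachs are kept for specimen
tallies and the chi-square test of feeding activity but excluded from all
multivariate analyses, since an all-zero row has undefined Bray–Curtis
distances.

**Frequency of occurrence.** The sampling unit for diet profiles is the
(species, season) pool of non-empty stomachs; "occurrence" is presence of
an item in a stomach (binary), so profiles are independent of how many
fragments of an item a stomach held.  FOC of item *i* in group *g* is

    p_i = (# stomachs in g containing i) / (Σ_k # stomachs in g containing k),

a probability vector (Σ p_i = 1, enforced to 1e-12).  An alternative
per-stomach or count-weighted reading is reachable through the
`unit` / `binarize` switches of `build_community_matrix`; the binary pooled
reading is the package default because it matches the standard FOC
convention in diet studies.

**Category importance** is the mean item FOC within each of the six broad
categories (fish, insects, crustaceans, plants, mollusks, micro-fauna),
renormalized across categories.  Items with zero FOC still count toward
their category's mean, so a category of many rare items is not inflated.

## Dissimilarity and embedding

Bray–Curtis, `d_jk = Σ|y_ij − y_ik| / Σ(y_ij + y_ik)`, is used throughout
(zero-tolerant, bounded in [0, 1]).  Note it is *not* invariant to row
scaling of count data; after binarization it is — this is a property test,
not an accident.

PCoA Gower-centers `−d²/2` and eigendecomposes; axes with
`|λ| ≤ 1e-8·max|λ|` are dropped as numerical noise.  Bray–Curtis matrices
are generally non-Euclidean, so negative-eigenvalue axes are kept as an
explicit imaginary branch rather than discarded or corrected: with all
axes retained, `d² = (real-part squared distance) − (imaginary-part
squared distance)` exactly, which is what the dispersion computation
needs.

## Group tests

**ANOSIM.** All n(n−1)/2 dissimilarities are ranked (average ranks on
ties, Clarke's formulation);
`R = (r̄_between − r̄_within) / (n(n−1)/4)` ∈ [−1, 1].  (Field summaries
sometimes describe the statistic as ranging over [0, 1]; the implemented
range is the statistic's true one — negative values mean more similarity
between groups than within.)  Significance by label permutation,
`p = (b + 1)/(n_perm + 1)` with default `n_perm = 1000`; the add-one form
keeps Monte-Carlo p-values positive and the observed labeling is never
counted among the permutations.  A constant dissimilarity matrix yields
R = 0 with a warning.  The seasonal contrast defaults to wet vs dry at
*item* level; running all six season pairs would demand multiplicity
adjustments and is deliberately not wrapped.

**SIMPER** contrasts exactly two groups at *category* level by default.
Per between-group pair (j, k), item contributions
`δ_i = |y_ij − y_ik| / Σ_m (y_mj + y_mk)` sum to the pair's Bray–Curtis
dissimilarity, so per-item averages over all between-group pairs sum
exactly to the mean between-group dissimilarity (identity asserted to
1e-10).  Per-item p-values permute group labels; no multiplicity
correction by default (an optional Holm flag exists).

**Chi-square** on the species × season empty-stomach counts is the plain
Pearson test without continuity correction, df = (r−1)(c−1); a 3 × 4
design gives df = 6.

## Diet breadth (dispersion)

Breadth of a group is the mean distance of its units to the group
centroid (coordinate mean, not spatial median) in PCoA space; squared
distances subtract the imaginary-axis part and are clamped at zero with a
warning.  Because the signed decomposition reproduces d² exactly, a
group's breadth depends only on its own units' dissimilarities — adding
unrelated groups cannot change it.  The between-species test per season is
a one-way F on the per-unit distances; the null permutes *labels* and
recomputes centroids and distances under each relabeling (the
exchangeable unit is the observation, not its distance),
`p = (#{F_perm ≥ F} + 1)/(n_perm + 1)` with 1000 permutations by default.
Distances are computed from the dissimilarity matrix via PCoA rather than
from NMDS coordinates; the breadth API accepts any `DissimilarityMatrix`,
so an NMDS-space reading can be obtained by feeding it distances between
NMDS coordinates.  No small-sample bias adjustment for unequal group
sizes is applied.

## NMDS

Kruskal stress-1 with isotonic regression of configuration distances on
the rank order of the input (ties get average ranks and are averaged
within tied blocks by the isotonic fit) alternating with Guttman
configuration updates.  Defaults: k = 2, 20 starts (one metric start plus
19 random), 300 iterations, convergence when the stress decrease falls
below 1e-6.  The metric start is the PCoA of the *rank-transformed*
dissimilarities, so the entire fit depends on the input only through its
rank order and stress is exactly invariant under strictly monotone
transforms.  The returned configuration is centered, rotated to principal
axes with a deterministic sign convention, and rescaled so RMS
configuration distance equals RMS input dissimilarity (stress-1 is
scale-free; the rescaling only standardizes output units).  An
all-coincident configuration against a non-constant input has no
meaningful fit: stress is reported as 1 with a warning.  Plot ellipses are
1-SD covariance ellipses of group coordinates (the convention is recorded
in the output).

## Pianka overlap and the bootstrap null

`O = Σ p1_i p2_i / √(Σ p1_i² Σ p2_i²)` on item-level FOC profiles
(30 items by default; category level available).  The null of *no
seasonal variation in overlap* is simulated by resampling each species'
non-empty stomach rows — seasons pooled — with replacement, rebuilding
profiles and recomputing O, 1000 times; a season's observed value is
flagged above/below when outside the 2.5/97.5 percentile interval (linear
interpolation).  Resampling is independent per species because the
observed statistic conditions on species identity.  The resample size
defaults to each species' mean per-season non-empty count (rounded), so
null sampling noise matches that of a seasonal estimate; pooled-size and
explicit sizes are provided, and the size used is recorded in the result.
Flags at 12 simultaneous (pair, season) comparisons are unadjusted.

**Finite-sample attenuation.** The plug-in index is slightly biased
downward when profiles are estimated: the numerator is unbiased for
independent species, but `E[Σ p̂²] = Σ p² + Σ var(p̂_i)`, giving a relative
denominator inflation of roughly `(1 − Σp²)/(n Σp²)` per profile.  With
n = 500 single-item stomachs and flat profiles (Σp² ≈ 0.06) this is a
~2–3% downward bias in O, comparable to the recovery tolerance; with
dominance-structured profiles (Σp² ≳ 0.2, typical of real diets) it is
negligible.  The recovery study reports the raw observed-minus-truth
error and does not debias, because the plug-in estimator is the field
standard.

## Synthetic generator

Per species s a baseline diet vector `b_s = ρ·shared + (1−ρ)·own_s`
(Dirichlet draws, concentration 0.5 per item); per season t,
`p_{s,t} = (1−δ)·b_s + δ·q_{s,t}` with q an independent Dirichlet draw.
δ ("season_shift") is the effect size for seasonal-difference tests; ρ
("overlap_share") dials expected Pianka overlap toward 1.  Stomachs are
empty with a season-specific probability (defaults .25/.15/.12/.05 for
receding/wet/rising/dry: highest when the lake recedes, lowest in the dry
season, ~15% overall); otherwise the number of distinct items is
zero-truncated Poisson (mean 3 by default) and items are drawn *without
replacement* with probabilities `p_{s,t}`, so occurrence equals the draw
and the binarized pipeline sees exactly the generative occurrences.
Default cell sizes mirror the published survey's per-(species, season)
totals split evenly over four locations.  Everything is reproducible from
one integer seed.

A consequence of without-replacement draws: for stomachs with m > 1
items, *inclusion* probabilities are flattened relative to `p_{s,t}`, so
empirical FOC profiles converge to the generating vectors exactly only in
the single-item regime (`items_per_stomach → 1`).  Convergence and
overlap-recovery studies therefore run with `items_per_stomach = 1`;
power and type-I studies use the default multi-item stomachs, where the
small flattening is irrelevant because both groups are affected equally.

What the generator does *not* emulate: spatial structure beyond the
location factor, ontogenetic (size-dependent) diet shifts, differential
digestion rates among prey, and within-stomach item abundances.  Passing
calibration on this generator shows the estimators are correct and
well-calibrated under exchangeable sampling — not that real surveys meet
those assumptions.

## Study sizes used by the shipped studies

Type-I error: 500 replicates of a one-species wet/dry survey (20
stomachs/group, 199 permutations each — the permutation test is exact at
any permutation count, 199 keeps 500 replicates fast).  Power: δ = 0.6,
30/group, 100 replicates.  Dispersion power: Gaussian clouds with sd 0.1
vs 1.0, 20/group, 100 replicates.  Bootstrap coverage: 200 two-species
surveys at δ = 0 (30/cell), 1000 bootstrap draws each.  Recovery: one
two-species survey with 500 single-item stomachs per (species, season).
The full pipeline at survey scale (n ≈ 620, 1000 permutations and
bootstrap draws, 20 NMDS starts) completes in about a minute on one CPU.

## Known limitations

- SIMPER's per-item permutation p-values share the known tendency of
  high-variance items to appear significant; interpret with the sd column.
- The bootstrap null pools seasons, so strong seasonal *sample-size*
  imbalance makes the default mean-per-season resample size only an
  approximation to any one season's noise.
- NMDS on heavily tied binary Bray–Curtis matrices often has high stress
  (> 0.2 on realistic surveys); the ordination is a visual companion, and
  inference rests on the permutation tests.
- The published design's N. notopterus margins are internally
  inconsistent (seasons sum to 214, locations to 208); the bundled fixture
  follows the location margins (grand total 623) and reports — never
  repairs — the discrepancy.
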