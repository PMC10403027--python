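# Methods

This note documents the models and procedures implemented in
`eolpathways`, the choices made where the design was genuinely open, and
what the synthetic-data generator does and does not establish.

## Daily care-state sequences

The unit of analysis is the care state occupied on each of the 365 days
preceding death, over the alphabet {ACUTE, REHAB, HAH, PSY, HOME}.  HOME
is the background state: it pools living at home, community care and
nursing homes, which claims data cannot separate reliably.

Conventions (fixed, documented, and in one case configurable):

* **Day of death included.** Sequence index 365 is the day of death
  itself (day offset 0).  `encode_daily_states(..., include_death_day=False)`
  shifts the window to end the day before death for sensitivity analyses;
  the default is used everywhere else.
* **Same-day overlaps** between care episodes resolve by care intensity:
  ACUTE > REHAB > HAH > PSY > HOME.  Claims data can code a transfer day
  under two stays; ranking by intensity is the only defensible
  deterministic rule and is applied uniformly.
* **Window-spanning stays** are truncated at the 365-day boundary by the
  generator (an episode starting before day 364 contributes only its
  in-window days).

Serializations: one row per patient with 365 single-character codes
(`A`, `R`, `D` for hospital-at-home, `P`, `H`), or run-length encoding
(`A:12;H:353`).

## Optimal matching and the LCS identity

Dissimilarity between two sequences is the minimum total cost of an edit
script (insertions, deletions, substitutions) transforming one into the
other, computed by the standard O(|x||y|) dynamic program.  The default
cost scheme is indel = 1 and constant substitution = 2 with zero
diagonal.  Under these costs a substitution never strictly beats a
delete+insert pair, so OM coincides with the LCS metric
`d(x,y) = |x| + |y| - 2*LCS(x,y)`; the test suite asserts this equality
*exactly* on hundreds of random pairs, and checks the DP against an
exhaustive edit-script enumeration on short sequences.  Consequences used
as invariants: distances between equal-length sequences are even
integers; `d(x,y) <= |x| + |y|`; the metric axioms hold.

Distances are computed on the full 365-day sequences (no run-length
compression), as pairwise kernels compiled with numba; a pure-Python
fallback keeps the package importable without numba, at a large speed
penalty.  Arbitrary symmetric non-negative substitution matrices are
accepted; with the default integer costs all distances are exact
integers, so equality assertions in tests are exact, while floating
schemes are compared at 1e-9.

## Ward hierarchical ascending classification

Clustering operates directly on the OM dissimilarity matrix via the
Lance–Williams recurrence with Ward coefficients.  Two conventions exist
in the field; both are implemented:

* `variant="squared"` (default): the recurrence is applied to *squared*
  dissimilarities and merge heights are reported on the original scale.
  For Euclidean inputs this is exactly greedy minimisation of the
  within-cluster sum-of-squares increase (the maintained quantity equals
  2×ΔSSQ, so heights are `sqrt(2 ΔSSQ)`), which the tests verify against
  an exhaustive raw-coordinate oracle on all configurations of n ≤ 7,
  and against scipy's `linkage(..., method="ward")` heights.
* `variant="raw"`: the recurrence applied to the dissimilarities as
  given, for comparability with pipelines that use that convention.

Merge ties break on the lexicographically smallest active index pair, so
the tree is a pure function of the matrix; the resulting partition is
invariant to input permutation up to label renaming (labels 1..k are
assigned in order of each cluster's first patient).  Heights are
monotone non-decreasing (Ward is reducible); every run asserts this.
The linkage holds the full n×n matrix: the reference ceiling is the
10,000-patient analysis sample; the test suite runs at n ≤ 1,000.

**Choosing k.**  The published typologies report 3, 3 and 2 clusters
without a selection rule.  `select_k` scores each candidate k by the
relative drop between the merge height that would destroy the k-cluster
partition and the one that created it, and returns the largest drop;
ties and degenerate trees (all heights zero) fall back to a configured
default (3 by default, matching the reported typologies).  The same rule
is free to return different k for different disease cohorts.

**Naming.**  Clusters are named from chronogram shape: mean share of
days in hospital states below 12% → "few and late hospitalizations";
otherwise, if less than 25% of expected hospital days fall before the
last 90 days → "acute care during the last 3 months of life"; else
"early and repeated hospitalizations".  Thresholds are keyword
arguments; the defaults separate the three default archetypes cleanly.

## Expenditure decomposition

* Means, SDs, medians and quartiles are over **all** cohort patients,
  zero-cost patients included; "% users" reports uptake separately
  (population-wide means are what make category means sum to the total
  mean — an identity asserted in tests and reproduced exactly from the
  published table values).
* IQR is reported as a single width Q3 − Q1 with linear-interpolation
  quartiles (numpy default).  SD is the sample SD, defined as 0 for a
  single patient.
* The "last 3 months" window is 90 days (`short_window`, configurable);
  `window_share` is spending at offsets < 90 over spending < 365, with
  0/0 → 0.
* The top expenditure decile contains N − ⌊0.9N⌋ patients; boundary ties
  resolve by a stable rank on patient id.
* Full precision is kept internally; rounding to whole euros and
  one-decimal percentages happens only in the report-rendering stage.

## Cohort descriptives and association

Age bands use the half-open convention [lower, upper) with open first
(<20) and last (≥90) bands; Charlson classes 0 / 1–2 / 3–4 / ≥5
partition the non-negative integers; missing deprivation quintile is a
first-class category.  Place of death is classified by the final-day
state.  The pathway-association model is an ordinary maximum-likelihood
logistic regression (statsmodels) of membership in a designated cluster
versus the rest, reporting exponentiated coefficients with Wald 95%
intervals; a constant outcome or (quasi-)perfect separation raises an
error rather than returning silent output.

## The synthetic generator: what it emulates, and what it does not

The generator's defaults *are* the stated world of the reference
population: 50.6% female; age at death ~ Normal(78.5, 14.9²) truncated to
[1, 110]; nine diagnosis prevalences (dementia 19.0%, COLD 17.3%, breast
cancer 2.3%, ...); Charlson ~ rounded truncated Normal(4.3, 3.7²) on
[0, ∞) — *drawn*, not computed from codes, since the code-mapping
algorithms are external; deprivation quintiles at the published shares
with 6.7% missing; 27% palliative-care flags; 5% zero-spend patients.
Breast and prostate cancer are drawn sex-specifically so population
prevalences are preserved without impossible cases.

**Archetypes.** Three templates encode the published narratives: (1)
home for 348 days, one 12-day acute stay near death; (2) home for 275
days, then alternating acute/rehabilitation blocks exactly filling the
last 90 days; (3) repeated acute, rehabilitation and hospital-at-home
spells across the whole year.  Mixture weights default to the published
dementia cluster sizes (0.67, 0.27, 0.06).  Noise resamples each day
independently to a uniformly random *other* state (default 5%);
independence keeps recovery analysis tractable.  The final day is never
resampled: it encodes the recorded place of death.  Optional
per-archetype hospital-death probabilities overwrite a short terminal
segment (default 3 days); the calibrated defaults (0.507, 0.75, 0.80)
give a mixture-weighted in-hospital death share of 0.59.  With the
probabilities unset and noise 0, a sequence equals its template
expansion exactly.

**Claims.** Hospital-state days of non-zero-spend patients emit per-diem
claims in the matching category (psychiatric per-diems are booked under
"other services", which pools psychiatric care in the published table
layout); per-diems default to order-of-magnitude French tariffs (acute
1,300 €/day, rehabilitation 700, hospital-at-home 250, psychiatry 500).
Ambulatory categories are time-inhomogeneous Poisson event streams with
a last-90-day rate multiplier (default 3) and lognormal event costs —
the zero-inflated, heavy-right-skew shape (mean ≫ median) seen in the
published summaries.

**What a green test does not establish.**  The generator reproduces
*marginals and structure*, not the joint distribution of a real claims
warehouse: archetype membership is independent of demographics and
comorbidity; noise days are costed like real hospital days; ambulatory
rates are invented plumbing.  Consequently synthetic per-patient
spending runs higher than the published population mean (the archetypes
deliberately encode hospital-intensive narratives, and 5% noise alone
adds ~17 costed hospital days), and the synthetic 3-month spending share
(~0.69) exceeds the published 44%.  No acceptance criterion targets
these quantities; the published spending identities are checked from the
printed values through the table-assembly path instead.  Cluster
*recovery* tests establish that the sequence-analysis machinery finds
planted structure — not that three clusters exist in any real
population.

## Numerical choices and degenerate inputs

Exact integer arithmetic wherever the default costs allow; symmetry and
zero-diagonal of dissimilarity matrices validated at 1e-9; chronogram
rows validated to sum to 1 at 1e-9; cluster cost shares sum to 1 at
1e-12.  Empty cohorts are valid for simulation (empty tables, success)
but rejected by analysis entry points; empty clusters are excluded from
profiles with a warning; `sample_patients` with n ≥ population returns
the whole population.  All generation and analysis is deterministic
given the configured seeds; the pipeline derives per-stage seeds from
one global seed and stamps every output directory with a manifest
(seed, config digest, file digests).

## Known limitations

* O(n²) memory and O(n³) time in the linkage bound the analysis sample
  (reference ceiling 10,000; tests use ≤ 1,000).
* The generator draws Charlson scores and palliative flags directly; it
  cannot be used to validate code-mapping algorithms.
* No inflation adjustment, DRG pricing, payer splits, or nursing-home /
  home distinction — out of scope by design.
* Index-plot and chronogram rendering are thin matplotlib helpers; the
  data products (long-format tables) are the supported interface.
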