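# eolpathways

End-of-life **care-pathway sequence analysis** and **last-year-of-life
spending decomposition** for claims-like decedent cohorts.

Health-services researchers studying the last year of life work from
administrative claims: for each decedent one can reconstruct, day by day,
the *place of care* — acute hospitalization, rehabilitation,
hospital-at-home, psychiatry, or home (community care and nursing homes
pooled) — and every costed service claim.  This package implements that
analysis as a tested, reusable pipeline:

1. **Daily state sequences.**  Each patient's last 365 days become a
   sequence $s = (s_1, \dots, s_{365})$ over the 5-state care alphabet,
   with the final element the day of death.
2. **Optimal-matching dissimilarity.**  Pairwise dissimilarities are edit
   distances: the minimum total cost of insertions/deletions (*indels*,
   cost 1) and substitutions (cost 2) transforming one sequence into the
   other.  Under these costs OM is the **LCS metric**,
   $d(x,y) = |x| + |y| - 2\,\mathrm{LCS}(x,y)$, computed by dynamic
   programming (numba-accelerated).
3. **Ward typology.**  Hierarchical ascending classification of the
   dissimilarity matrix with Ward's criterion (Lance–Williams recurrence
   on squared dissimilarities, heights on the original scale), cut into
   $k$ pathway clusters ($k$ fixed or chosen at the dendrogram elbow) and
   named from chronogram shape: *few and late hospitalizations*, *acute
   care during the last 3 months of life*, *early and repeated
   hospitalizations*.
4. **Expenditure decomposition.**  Per-service-category summary tables
   (% users, mean, SD, % of total, median, IQR width over **all** cohort
   patients, zeros included), last-3-months spending shares, top-decile
   summaries ($N - \lfloor 0.9N \rfloor$ patients), per-cluster cost
   summaries and cost shares $n_k \bar c_k / \sum_j n_j \bar c_j$.
5. **Cohort descriptives.**  Characteristics tables (sex, age bands,
   deprivation quintiles, Charlson classes 0 / 1–2 / 3–4 / ≥5, diagnosis
   prevalences), place of death from the final-day state, palliative-care
   uptake, and logistic-regression odds ratios for pathway membership.

Because national claims warehouses are not publicly available, the
package ships a **synthetic claims-cohort generator** whose defaults
reproduce published decedent-population marginals (50.6% female, mean age
78.5 ± 14.9, 19% dementia, 27% palliative-care use, 5% zero-spend, 59%
in-hospital deaths), so the entire pipeline is reproducible and testable
offline, with known ground-truth pathway labels for validation.

## Worked example

```python
import eolpathways as eol

model, truth = eol.CarePathwayModel.simulate(
    eol.CohortConfig(n_patients=300, seed=7),
    eol.ArchetypeConfig(seed=7),
    eol.CostConfig(seed=7),
)
res = model.fit(k=3, seed=0)
print(res.summary())
```

```
            Care Pathway Typology
==========================================================================
No. sequences: 300      clusters (k): 3    ward variant: squared
OM costs: indel=1, substitution=2
--------------------------------------------------------------------------
cluster      n      %    mean cost     median  name
      1    202   67.3       41,547     42,335  few and late hospitalizations
      2     83   27.7      113,496    117,456  acute care during the last 3 months of life
      3     15    5.0      176,895    188,906  early and repeated hospitalizations
==========================================================================
```

The three clusters recover the generator's archetypes exactly (adjusted
Rand index 1.0 against the ground-truth labels returned by
`simulate()`), with cluster sizes near the configured 67/27/6% mixture.
Mean 12-month spending rises steeply from the home-centred pathway to the
early-and-repeated-admissions pathway — the qualitative signature this
analysis is designed to expose.  Derived summaries hang off the results
object:

```python
res.window_share()        # share of spending in the last 90 days -> 0.693
res.top_decile()          # DecileSummary(n=300, count=30, threshold=120920.3..., share=0.226)
res.cost_table().to_display()   # 11 service categories + total
res.chronograms()         # per-cluster daily state distributions
res.association()         # odds ratios for cluster-3 membership
```

A `click` CLI wraps the same pipeline
(`eolpathways simulate | analyze | report | all`), writing delimited
tables plus a provenance manifest (seed, config digest, file digests) at
every stage.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main analysis from scratch: it simulates a
2,000-patient cohort with the calibrated defaults, samples 400 patients
for the pairwise sequence analysis, builds the Ward typology with
elbow-selected $k$, runs the expenditure decomposition and report stage,
logs a run summary to stderr, and writes the results JSON to `--out`.
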