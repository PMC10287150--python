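# grindex

Genetic-rescue suitability scoring and tie-corrected nonparametric analysis
for survey tables of federally listed vertebrate species.

The package implements, as a tested and reusable pipeline:

- **Survey data model** (`grindex.records`): validated species records with
  the nine coded survey questions (codes `2/1/0/-1` plus a distinct missing
  state, never conflated with 0), CSV reading/writing in a configurable
  dialect (`NA` missing token by default), eligibility filtering
  (populations / extinct / island / marine / US-range rules with an
  exclusion log), and the categorical recodings: recovery-priority category
  (1–6 High, 7–12 Moderate, 13–18 Low), fast/slow life history at the 4-year
  maturity cutoff, and the ordinal populations-remaining catalogue.
- **Suitability scoring** (`grindex.scoring`): the integer suitability index
  (sum of the nine codes, missing = 0, bounded in [-5, 5]), missing-question
  counts, candidate classification (index >= 2 by default), and stratified
  index distributions.
- **Nonparametric statistics** (`grindex.stats`): from-formula
  implementations of mid-ranks with tie bookkeeping, tie-corrected
  Kruskal-Wallis H, Dunn's pairwise z with Bonferroni adjustment,
  Mann-Whitney U/W (exact enumeration for small untied samples; tie-corrected
  normal approximation with continuity correction otherwise), Kendall's
  tau-b with the tie-adjusted normal p-value, Fisher's exact test for r x c
  tables (full enumeration when feasible, seeded Monte-Carlo fallback), and
  the chi-square / normal tail functions they need. Library routines
  (scipy, R) are used only as independent cross-check oracles in the tests.
- **Synthetic cohorts** (`grindex.simulate`): seeded generation of cohorts
  with per-question categorical response tables (including NA mass),
  group/region/status weights, an ordinal populations variable, and a
  configurable association between the suitability index and translocation
  status; plus a deterministic 12-record fixture cohort with hand-computed
  scores shipped as package data.
- **Analysis pipeline** (`grindex.pipeline`): the full test battery
  (index by evaluator / taxon / region / populations / translocation status;
  Dunn post-hoc when the parent test is significant; Mann-Whitney by listing
  status and life history; Fisher translocation x taxon; Kendall tau-b for
  populations ordinal, missingness, and priority category; populations
  ordinal by translocation status), with per-test complete-case dropping and
  effective-n accounting, rendered as JSON, CSV bundle, or Markdown.

## CLI

```sh
# generate a synthetic cohort (seeded, reproducible)
grindex simulate --out cohort.csv --seed 42 [--config cfg.yaml]

# score a cohort: per-species results + distribution summary
grindex score --in cohort.csv --out results/ [--filter]

# run the full statistical battery
grindex analyze --in cohort.csv --out report.json --seed 17 \
    [--format json|csv-bundle|markdown] [--config cfg.yaml]
```

The optional YAML/JSON config may contain `dialect`, `catalogue`,
`eligibility`, `analysis`, and `simulation` sections; see
`grindex/config.py` for the accepted keys. `-v` logs per-test timing and
effective sample sizes to stderr.

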