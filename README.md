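# insightbench

Exact probabilistic benchmarking of a single binary answer profile against a
normative population described by per-item solution rates.

Given a battery of items where item *j* is solved by a fraction *p_j* of a
human reference sample, and one agent's 0/1 answer vector over the same
items, the package computes:

- the **exact score distribution** — the Poisson-binomial PMF of the total
  score under independent per-item successes, by brute-force outcome
  enumeration (oracle) or by `O(n²)` convolution (`score_pmf_dp`), and its
  mode;
- the **occurrence probability** of any specific answer combination
  (product of `p_j` over correct items and `1 − p_j` over incorrect ones,
  accumulated in log space);
- the **conditional placement** of a combination among *all* combinations
  attaining the same total score: its percentile rank (fraction with strictly
  smaller probability) and whether it clears the top-*q* nearest-rank
  threshold. Level sets up to 10⁷ combinations are enumerated directly; the
  pooled 30-item score-12 level set (86,493,225 combinations) is handled by a
  bounded-memory **meet-in-the-middle** factorization over two battery
  halves;
- the supporting **classical statistics**: two-sided Fisher exact test
  (probability-mass rule, exact integer arithmetic), Wilcoxon rank-sum with
  midranks and tie-corrected normal approximation, and midpoint-interpolation
  median/IQR summaries;
- **synthetic cohorts** (independent Bernoulli answers, seed-reproducible)
  for Monte-Carlo validation of every analytic quantity.

The 30-item reference battery (15 practice + 15 transfer items with their
human solution rates) and the benchmarked agent's answer vectors ship inside
the package, so the full reference analysis needs no external data.

## CLI

```sh
# full analysis of the built-in battery -> JSON report on stdout
insightbench analyze

# custom data, report to file, plus plot-ready CSV tables
insightbench analyze --battery my_battery.csv --q 0.05 \
    --out report.json --export-fig 3 --export-fig 5 --fig-dir figures/

# synthetic battery + cohort (fully determined by --seed)
insightbench simulate --n-items 15 --n-subjects 1000 --seed 7 \
    --rate-model beta:2,2 --out-matrix cohort.csv

# Monte-Carlo cross-checks of the analytic machinery
insightbench validate --seed 0
```

Battery CSV format: header `item_id,set_label,solution_rate[,answer]`; rates
are decimal proportions or percent strings (`21.1%`). When the battery file
carries an `answer` column it doubles as the profile source.

The report JSON contains one block per problem set (plus a pooled block):
exact score PMF, mode, the profile's occurrence probability, percentile rank,
top-*q* threshold and membership flag — at full precision with
3-significant-figure display strings — together with the between-set Fisher
and rank-sum comparisons, the rate summaries, and the conventions used.

## Library

```python
import insightbench as ib

battery = ib.builtin_battery("practice")      # or ib.read_battery("file.csv")
profile = ib.builtin_profile("practice")

pmf = ib.score_pmf_dp(battery)                # exact score distribution
mode, tied = ib.pmf_mode(pmf)
report = ib.placement(battery, profile, q=0.05)
report.profile_probability, report.percentile_rank, report.in_top_q
```

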