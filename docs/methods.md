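# Methods

## Setting and model

A stochastic answer generator (temperature > 0) is queried n times on
each of N multiple-choice cases with k options each; every call returns
one option label and a verbalized confidence on a 0–100 scale, plus
resource metadata. The package treats the n repetitions of one
(case, model) pair as exchangeable draws from an unknown per-case answer
distribution, and asks how well different summaries of those draws
predict whether the case is answered correctly.

Five confidence metrics are computed per (case, model), each with a
representative answer whose correctness it is scored against:

* first self-reported confidence → first response;
* mean self-reported confidence (over majority-answer responses) →
  majority-vote option;
* relative entropy score R_H = 1 − H/log₂k, H the Shannon entropy (bits)
  of answer frequencies → majority-vote option;
* majority-vote percentage → majority-vote option;
* Top Weighted Score, max over options of (count × mean confidence)/n →
  highest-weighted option.

Raw H is carried alongside R_H; being a strictly monotone transform, it
yields an identical ROC AUC (with sign flipped so higher = more
confident) and is reported as a sixth row in evaluation tables, without
calibration statistics (it has no natural [0, 1] scale).

### Numerical choices

* Entropy uses log base 2 with 0·log 0 ≡ 0, and sums over the *sorted*
  count multiset so permuted answer patterns give bitwise-identical H;
  this makes label invariance and the AUC(R_H) = AUC(−H) identity exact
  rather than approximate.
* Frequency or weighted-score ties are broken by canonical option order
  (first label in the case's option list) and flagged in the output, so
  downstream analyses can inspect or exclude tied cases. Zero-count
  options carry a missing mean confidence, never 0, so they cannot win
  the Top Weighted Score.
* Depth truncation takes the first d repetitions in generation order
  (never a random subsample), and the majority option is recomputed at
  each depth; "first response" always means repetition index 1.

## Evaluation stack

* **ROC AUC** uses the midrank (Mann–Whitney) estimator with DeLong
  structural-component variance; 95% CI = AUC ± 1.96·SE truncated to
  [0, 1]; p is a two-sided normal test of AUC = 0.5. The O(m·n) pairwise
  matrix is used directly — sample sizes here are hundreds of cases, not
  millions.
* **Spearman ρ** comes from midranks (scipy), with a Fisher-z 95% CI
  using SE 1/√(n−3) and the two-sided p from the t approximation. Bands:
  negligible ≤ 0.10 < weak ≤ 0.39 < moderate ≤ 0.69 < strong ≤ 0.89 <
  very strong. The score–correctness pair is continuous-vs-binary; ρ is
  computed exactly as defined, without rank-biserial reinterpretation.
* **Calibration** maps every metric to [0, 1] first (percentage-scaled
  metrics ÷ 100, R_H unchanged) — ECE and Brier compare a confidence to
  a 0/1 outcome and need a common domain. ECE uses fixed equal-width
  10-bin partitioning, bins half-open [lo, hi) with the last bin closed
  at 1.0 so confidence 1.0 is counted; empty bins contribute 0. Brier is
  the binary mean squared error (correct vs incorrect), not a multiclass
  score.
* **Bootstrap CIs** (default 1000 iterations) resample *cases* with
  replacement — the only exchangeable unit — and take the 2.5/97.5
  percentile interval; a resample on which a statistic is undefined is
  redrawn and counted. Fixed seeds make intervals bit-reproducible.
* **Mann–Whitney** (correct vs incorrect score distributions) uses exact
  enumeration when both groups have ≤ 8 members and no cross-group ties,
  otherwise the tie-corrected normal approximation.
* **Cochran Q** is computed across the depth conditions {first output,
  majority@5, @10, @15, @20}; an all-constant correctness matrix returns
  Q = 0, p = 1 rather than an error. With two conditions Q coincides
  with the McNemar chi-square without continuity correction.
* **Fleiss κ** treats the n repetitions as interchangeable raters; bands
  > 0.8 almost perfect, 0.61–0.80 substantial, 0.41–0.60 moderate,
  0.21–0.40 fair, else poor. κ is also exposed per depth d (first d
  repetitions), matching the depth-truncation rule.
* **Temporal holdout** is a two-sided Fisher exact test (minimum-
  likelihood summation) on the 2×2 table of publication stratum ×
  majority-vote correctness; undated cases are excluded with a count.
* No multiple-testing correction is applied by default; raw p values are
  reported at α = .05.

Fleiss κ and Cochran Q are delegated to statsmodels, Spearman/
Mann–Whitney/Fisher exact to scipy; each is verified in the test suite
against an independent from-scratch formula or enumeration oracle.
DeLong variance, ECE and the bootstrap are implemented here.

## I/O conventions

Logs are JSON-lines or CSV; case tables are CSV with `|`-joined options;
everything UTF-8 with ISO-8601 dates. Verbalized confidences arrive as
model-generated text, so the parser tolerates `"85%"`, whitespace and
out-of-range values (clamped), counts every deviation, and never drops a
record silently: lenient mode (default) routes malformed records to a
rejects report, strict mode raises naming the line. Values in (0, 1] are
rescaled ×100 only behind an explicit fraction flag, off by default.
Missing confidence is legal at I/O time; metrics that need it fail
loudly downstream instead.

## Synthetic generator

`simulate_model` emulates the regime the pipeline targets, per case:

1. truth drawn uniformly over the k options; a latent *modal* option
   equals the truth with probability `accuracy`, otherwise uniform over
   the rest;
2. an answer-probability vector p ~ Dirichlet(α) with α = 1 everywhere
   except α_modal = `concentration` (≥ 10⁶ is treated as the unanimous
   limit); `concentration_incorrect`, when set, replaces the
   concentration on cases whose modal option is wrong — models being
   more consistent when right is what makes consistency metrics
   informative;
3. n i.i.d. answers from p;
4. confidences from a truncated normal on [0, 100] with mean
   `conf_mu_correct` when the response matches the link target (the
   modal option by default — reproducing confidently-wrong behaviour —
   or the truth with `conf_link="truth"`), else `conf_mu_incorrect`;
   `overconfidence_shift` is added and clamped. `calibrated=True`
   instead sets every confidence to 100·p_truth, a perfectly calibrated
   oracle for the first response;
5. processing times and token counts from log-normal draws (median 8 s,
   σ = 0.6; 4200/420 input/output tokens, σ = 0.3) — arbitrary but
   realistic magnitudes that exist purely to exercise resource
   reporting.

Defaults are the study conditions the package was built around: N = 94
cases, k = 5, n = 20 repetitions, accuracy 0.60 (observed model range
roughly 0.44–0.74), concentration 36. Under the Dirichlet closed form
E[Σpⱼ²] = Σ αⱼ(αⱼ+1)/(α₀(α₀+1)), concentration 36 gives an expected
Fleiss κ ≈ 0.77, inside the observed 0.73–0.80 band; confidence means
88/78 with SD 8 reproduce high, clustered self-reports. Publication
dates are spread uniformly over two years around a nominal 2025-02-01
cutoff so the temporal-holdout path runs by default.

What the generator does **not** emulate: case difficulty correlated with
image content, systematic per-option biases, drift across repetitions
(answers are exchangeable by construction), non-numeric confidence
strings beyond what the parser tests inject, and any attempt to fit the
four real models' parameters (their raw responses are not public).
Passing tests therefore demonstrate that the *pipeline* measures what it
claims under a known mechanism — not that any particular real model is
well or poorly calibrated.

## Recovery suite

`recovery_suite` runs simulate → group → profile → evaluate over a named
grid of generator conditions (default: an informative cell, a
zero-information cell, calibrated and overconfident cells, and a
concentration ladder; 300–500 cases per cell, 2–3 replicates) and
checks, against Monte-Carlo targets computed from the generator itself:

* realized Fleiss κ within ±0.05 of the E[Σp²]-based target;
* with both signals informative, TWS AUC ≥ max(consistency AUC,
  self-report AUC) − 0.02 on average over replicates;
* the +20-point overconfidence shift raises self-reported ECE by > 0.10
  over the calibrated cell;
* realized κ increases monotonically along the concentration ladder.

The expected chance agreement uses uniform marginals (1/k), exact here
because truths are uniform by construction.

## Design choices on genuinely open points

* Mean self-reported confidence at depth d averages over the
  depth-d majority (recomputed), not the full-depth majority; the
  alternative is a one-line change in `self_reported` but the
  depth-specific rule is the one consistent with per-depth analysis.
* The Cochran Q condition set is {first, 5, 10, 15, 20} — one Q per
  model across all reported depth conditions.
* Bootstrap bin edges for ECE are absolute on [0, 1] and identical in
  every resample (with fixed equal-width bins the distinction from
  per-resample edges is moot).
* The CLI exposes one global seed; bootstrap and simulation derive
  independent child streams from it, so adding an analysis never
  perturbs another's draws.

## Problem sizes

Default test and recovery runs use 94–500 cases with 20 repetitions and
50–1000 bootstrap iterations; these sizes make every statistic's
sampling noise small relative to the tolerances asserted while keeping
the full suite fast on a single CPU.

## Known limitations

* ECE with 10 fixed bins is unstable at small N when confidences
  cluster (many near-empty bins); the reliability table is exposed so
  users can inspect bin occupancy.
* The DeLong p value tests AUC = 0.5 per metric; no paired AUC-vs-AUC
  contrast between metrics is provided.
* Fisher's exact test is conservative; the temporal holdout has limited
  power with a small post-cutoff stratum.
* The generator's exchangeability assumption means it cannot reveal
  order effects (e.g. drift across the 20 repetitions) that real API
  logs might contain.
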