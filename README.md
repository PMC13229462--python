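# repconf

Confidence measurement for **repeated categorical outputs of stochastic
answer generators** — typically multimodal large language models queried
many times on the same multiple-choice case (e.g. radiology quiz cases
with k = 5 answer options).

LLMs readily attach a verbalized confidence ("confidence: 0–100%") to an
answer, but such self-reports are notoriously overconfident. An
alternative signal is *self-consistency*: query the model n times at
nonzero temperature and measure how strongly the answers agree. `repconf`
implements both families of confidence metrics, a hybrid of the two, and
the complete statistical machinery needed to judge which metric actually
tracks correctness.

## Metrics

For one case answered n times over k options with answer frequencies
p₁,…,p_k:

| metric | definition | representative answer |
|---|---|---|
| first self-reported confidence | confidence attached to repetition 1 | first response |
| mean self-reported confidence | mean confidence over responses choosing the majority answer | majority-vote option |
| relative entropy score R_H | 1 − H / log₂ k, with H = −Σ pᵢ log₂ pᵢ (bits) | majority-vote option |
| majority-vote percentage | 100 · max count / n | majority-vote option |
| Top Weighted Score (TWS) | max over options of count · mean confidence / n | highest-weighted option |

R_H is 1 for a unanimous pattern ([A A A A A]) and 0 for a uniform one
([A B C D E]); it sees dispersion the majority share is blind to
([A A A B B] scores higher than [A A A B C], both are 60% majorities).
TWS blends consistency with verbalized confidence: A chosen 12/20 times
at mean confidence 80 scores 12·80/20 = 48; B chosen 8/20 at 90 scores 36.

Each metric is paired with the correctness of its *representative
answer*, and evaluated for

* **discrimination** — ROC AUC with DeLong variance (95% CI, p vs 0.5),
* **association** — Spearman ρ with Fisher-z CI and interpretation bands,
* **calibration** — fixed 10-bin expected calibration error and binary
  Brier score with case-resampling bootstrap CIs,
* **repeatability** — Fleiss κ across the n repetitions,
* **repetition economics** — accuracy, Cochran Q and cumulative
  time/token cost at repetition depths 1/5/10/15/20, and
* **contamination** — a temporal-holdout Fisher exact test on cases
  published before vs after a cutoff date.

A Dirichlet–multinomial synthetic generator (`repconf.synthetic`)
produces response logs with the same statistical structure (tunable
accuracy, agreement/κ, confidence miscalibration), so the entire pipeline
is testable without any API access.

## Worked example

```python
from repconf import CaseRecord, ResponseRecord, ResponseSet, build_profile

case = CaseRecord("case_1", ("A", "B", "C", "D", "E"), "A")
answers = ["A"] * 12 + ["B"] * 8
confs = [80.0] * 12 + [90.0] * 8
records = tuple(
    ResponseRecord("case_1", "gpt-x", i + 1, a, c)
    for i, (a, c) in enumerate(zip(answers, confs))
)
profile = build_profile(ResponseSet(case, "gpt-x", records))
print(f"H   = {profile.entropy_H:.3f} bits")
print(f"R_H = {profile.r_h:.3f}")
print(f"majority = {profile.majority_option} ({profile.majority_pct:.0f}%)")
print(f"TWS = {profile.tws_option} ({profile.tws:.0f})")
```

prints

```
H   = 0.971 bits
R_H = 0.582
majority = A (60%)
TWS = A (48)
```

— 12 of 20 answers agree on A, giving 0.971 bits of answer entropy and a
relative entropy score of 0.582; A wins the majority vote with 60% and
also the Top Weighted Score with 12·80/20 = 48. Since A is the ground
truth, every metric's representative answer is correct here
(`profile.correctness` is all `True`).

## Command line

```bash
repconf simulate --out demo --n-cases 40 --seed 5
repconf evaluate --input demo/responses.jsonl --cases demo/cases.csv \
                 --out demo/eval.csv --iters 200 --seed 5
```

writes a tidy table of (model, metric, statistic, point, lo, hi, p) rows,
e.g. for one simulated model:

```
            metric statistic  point    lo    hi     p
        first_conf       auc  0.509 0.314 0.705 0.925
               tws       auc  0.372 0.179 0.565 0.194
               tws       ece  0.136 0.054 0.271   NaN
```

Other subcommands: `validate` (strict/lenient log validation with a
rejects report), `profiles` (per-case metric CSV at several repetition
depths), `depth` (accuracy by repetition count, Cochran Q, κ by depth,
temporal holdout), `resources` (cumulative time/token costs), and
`recover` (the parameter-recovery suite over a grid of generator
conditions).

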