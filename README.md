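# simon2stage

Exact statistical inference for single-arm phase II trials run under
Simon's two-stage design when the second-stage sample size ended up
different from the planned one — shortened by funding loss, slow accrual
or drop-out, or extended by coordination error — for reasons unrelated to
the observed responses.

## The problem

A Simon two-stage design is indexed by four integers `(r1, n1, rt, nt)`:
enroll `n1` patients, stop for futility if at most `r1` respond, otherwise
enroll to `nt` and declare the treatment active if the total responder
count exceeds `rt`. Because of the interim stopping rule, the naive
binomial analysis of the final counts is wrong: the stopping stage `M` and
cumulative responder count `S_M` must be analysed jointly, and when the
realized stage-2 size `n2*` differs from the planned `n2 = nt − n1` the
analysis should condition on `n2*` (a conditional likelihood, valid when
the size change is non-informative).

The package provides, for any design and observed outcome
`(x1, x2, n2*)`:

- the **UMVUE** of the response rate π given the sequential rule,

  π̃ = Σₓ C(n1−1, x−1) C(n2*, s−x) ⁄ Σₓ C(n1, x) C(n2*, s−x),

  summed over stage-1 counts `x` compatible with continuation, evaluated
  in exact integer arithmetic (stage-1 stops give x1/n1);
- **likelihood-ratio ordered mid-p values**: each sample path `(m, s)` is
  ranked by T(m, s, π0) = π̂^s (1−π̂)^{n−s} ⁄ π0^s (1−π0)^{n−s} with
  π̂ = s/n, and the p-value sums the null mass of strictly more extreme
  paths plus half the observed path's mass; inverting the acceptance
  region {π0 : p(π0) ≥ α} yields an exact confidence interval. This
  ordering is defined for *every* outcome, including `x1 > rt` and
  `x2 = 0`;
- the **Koyama–Chen conditional method** for comparison: calibrate π\*
  from A(x1, n2, π\*) = P_{π0}[X2 ≥ x2 | n2\*] with
  A(x, n2, π) = P_π[X2 > rt − x | n2], sum the p-value over stage-1
  counts, and invert the p-value function for a median-unbiased estimate
  and interval — with its two documented failure modes surfaced as
  structured errors/warnings;
- exact **operating characteristics** (type I error, power, PET, expected
  sample size), design search (optimal/minimax), and a Monte Carlo
  **simulation study** of CI width, coverage, power and bias under random
  stage-2 size deviation.

## Worked example

A hepatobiliary-cancer trial tested a 16-week progression-free-survival
rate of 0.15 against 0.30 with a Simon optimal design
`(r1, n1, rt, nt) = (3, 19, 8, 39)`. Stage 1 saw 8/19 responses; the
second stage was terminated by funding loss after 6 of the planned 20
patients, 4 of whom were progression-free.

```python
from simon2stage import SimonDesign, TwoStageModel

design = SimonDesign(r1=3, n1=19, rt=8, nt=39, pi0=0.15)
model = TwoStageModel.from_counts(design, x1=8, x2=4, n2_actual=6)
print(model.fit(pi0=0.15, level=0.90).summary())
```

```
Simon two-stage exact inference
================================================================
Design: r1/n1 = 3/19, rt/nt = 8/39 (planned n2 = 20)
Outcome: x1 = 8, x2 = 4, actual n2 = 6 (s = 12, n = 25)
Null rate pi0 = 0.15
----------------------------------------------------------------
method            estimate            CI     p-value   (90% CI)
UMVUE-ordering       0.480    (0.305, 0.621)           —
LR                   0.480    (0.322, 0.646)   5.768e-05
KC                   0.435    (0.271, 0.605)    0.000862
================================================================
```

The conditional-likelihood UMVUE is 0.48 (exactly 12/25 here) with a 90%
likelihood-ratio interval (0.322, 0.646); the conditional Koyama–Chen
analysis gives 0.435 with (0.271, 0.605) — wider, and lower because the
median-unbiased inversion discounts the strong stage-2 showing. Both
p-values are far below 0.10, so the drug clears the design's bar despite
the truncated second stage.

The same analysis is available from the shell:

```bash
simon2stage infer --r1 3 --n1 19 --rt 8 --nt 39 \
    --x1 8 --x2 4 --n2-actual 6 --pi0 0.15 --level 0.9
```

and `simon2stage design` / `simon2stage simulate` expose the design
search and the Monte Carlo study (a ready-made study configuration ships
as `simon2stage/configs/table1.yaml`).

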