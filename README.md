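# leqate

Equating the total scores of two health or functioning scales with
Leunbach's power-series model: conditional maximum-likelihood estimation,
conditional tests of fit with parametric-bootstrap p-values, direct
(common-person) and indirect (common-scale) raw-score equating, and a
bootstrap Standard Error of Equating (SEE) — as an importable library, a
set of narrative examples, and a thin command-line tool.

## The problem

Clinicians and researchers measure the same construct (sleep disturbance,
fatigue, physical functioning …) with different instruments whose raw
totals live on different ordinal metrics: a 3 on one scale is not a 3 on
another.  A *crosswalk* (raw-score conversion table) lets scores be
compared and pooled.  This package builds such crosswalks for pairs of
bounded integer total scores, either measured on the same respondents or
linked through a third scale administered in both samples, and quantifies
the uncertainty of every converted score.

## The model

Each total score is treated as a power-series "super item" driven by one
latent person parameter ξ (θ = log ξ):

    P(X_i = x | ξ) = ξ^x γ_ix / Σ_h ξ^h γ_ih ,  x = 0 … m_i .

Under conditional independence given ξ the total R = X₁ + X₂ is again
power-series with ω_r = Σ_x γ₁x γ₂,r−x, and

    P(X₁ = x | R = r) = γ₁x γ₂,r−x / ω_r

does not involve ξ — the total score is sufficient.  Consequently the γ's
are estimated by conditional maximum likelihood (iterative proportional
fitting) with no assumptions about the person distribution, model fit is
checked by three conditional tests (likelihood ratio, Goodman–Kruskal
gamma discrepancy, person-misfit count) with parametric-bootstrap
p-values, and a score a on scale A is equated to B by true-score equating:
find θ̂ with E(X_A | θ̂) = a, evaluate E(X_B | θ̂), round.  The SEE of each
converted score is its standard deviation over bootstrap replications of
the whole procedure; a weighted SEE mean below 0.91 is regarded as
acceptable.  Details and design choices: `docs/methods.md`.

## Worked example

`python examples/direct_equating.py` simulates 722 respondents answering an
ESS-shaped 0–24 scale (A) and a 0–12 scale (B) from one latent trait, fits
and checks the model, and prints the conversion table (abridged):

```
simulated 722 persons; score table 25x13
CML converged after 534 IPF cycles (max change 1.0e-09)
fit tests: LRT p=0.430, Gamma p=0.660, misfit count 30 (4.2%, p=0.715)
verdict: fit (only p <= 0.01, or two tests at 5%, count against the model)

raw-score conversion A -> B (SEE from 199 bootstrap replicates):
 source_score     theta  expected_target  equated_target  see  weight
            1      -inf              0.0               0 0.00   0.006
            2 -3.275480              0.5               1 0.50   0.010
            ...
           12  0.064415              5.9               6 0.00   0.079
            ...
           23       inf             12.0              12 0.00   0.006

weighted SEE mean 0.19 -> acceptable (bound 0.91)
```

Reading a row: a raw score of 12 on A corresponds to person estimate
θ̂ = 0.064, an expected B score of 5.9, hence the converted score 6; across
bootstrap replicates the converted score never moved (SEE 0.00); 7.9% of
the sample took raw score 12 (its weight in the SEE summary).  Rows for
raw scores nobody took (here 0 and 24) are absent: γ for unobserved scores
is inestimable and no interpolation is attempted.

Other examples: `indirect_equating.py` (B→C through a common scale, and
why the indirect SEE is larger), `fit_test_power.py` (which violations the
conditional tests can and cannot detect), `see_arithmetic.py` (how a
bootstrap error distribution turns into an SEE).

## Command line

```sh
leqate simulate scenario.yaml -o scores.csv --seed 7
leqate fit scores.csv --scale-a ESS --scale-b NSIF -S 1000 --seed 1 --out fit.json
leqate equate scores.csv --scale-a ESS --scale-b NSIF -S 1000 --seed 1 --out ess_to_nsif.csv
leqate indirect sample1.csv sample2.csv --scale-b MOS --via ESS --scale-c PSQI --out mos_to_psqi.csv
leqate report fit.json ess_to_nsif.summary.json
```

Input is a wide CSV (one row per person, one integer column per scale);
every stochastic command records its seed and S in its outputs.

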