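# Methods

## Model and procedure

The package tests whether a high-dimensional block X (n×p, p ≫ n allowed)
adds predictive value for a binary outcome y beyond a low-dimensional
clinical block Z (n×q). The working model is additive on the logit scale,

    logit P(y=+1 | z, x) = β₀ + Σⱼ βⱼ zⱼ + β₀* + Σₖ βₖ* xₖ,

with null hypothesis H₀: all βₖ* = 0. The procedure is two-stage:

1. **Clinical offset.** Maximum-likelihood logistic regression of y on Z
   (IRLS). The fitted linear predictor η̂ is frozen and used as an offset —
   a per-sample term with coefficient fixed at 1 — in everything that
   follows. Freezing is the point: step 2 is forced to explain only
   residual structure, so redundancy between X and Z cannot masquerade as
   additional value. Variants: a published risk score (probability scale →
   logit transform; linear scale → verbatim) replaces the fit entirely, or
   the offset is the intercept log(n₊/n₋) when no adjustment is wanted.

2. **Componentwise-linear-least-squares boosting.** Functional gradient
   descent on the binomial log-likelihood loss, started at f⁽⁰⁾ = η̂.
   Per iteration: negative gradient uᵢ = y′ᵢ − expit(fᵢ) (y′ = 1(y=+1));
   p univariate OLS fits of u on (1, Xₖ); the column with the smallest
   residual sum of squares wins (ties → smallest index); update
   f ← f + ν(â + b̂ X_{k*}). The accumulated fit is linear and sparse (at
   most m_stop nonzero coefficients), reported on the original X scale so
   that offset + β̂₀* + Xβ̂* reproduces the internal state exactly.

The test statistic is the average negative binomial log-likelihood ℓ of the
fitted probabilities. The null distribution comes from B re-runs of step 2
on row-permuted X (one σ per permutation applied jointly to all p columns,
preserving within-row correlation; Z and y fixed), and

    p = (1 + #{b : ℓ_b ≤ ℓ}) / (B + 1),

the add-one convention: strictly positive, exactly discrete-uniform under
the null, ties counted conservatively toward the null.

### Parameterization note

The implementation works on the full logit scale throughout: loss
−[y′ log π + (1−y′) log(1−π)], gradient y′ − π. Parts of the boosting
literature use a half-logit parameterization on y ∈ {−1, +1}; the two
differ only by a factor-2 rescaling of f absorbed into the effective step
length. The full-logit convention is used because it makes the step-1 GLM
linear predictor the offset verbatim and the m_stop = 0 boosting fit equal
to the clinical model exactly (a tested identity).

## Tunable parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| ν (step length) | 0.1 | (0, 1] | standard boosting shrinkage default; results depend weakly on it when m_stop adapts |
| m_stop | 100 fixed, or AIC | iterations | the method's only real tuning parameter; 100–1000 are standard fixed choices |
| m_max (AIC cap) | 1000 | iterations | the AIC curve flattens; a large cap costs only time |
| B (permutations) | 200 | ≥ 1 | p-value resolution is 1/(B+1); set as high as feasible |
| probability clip ε | 1e−10 | — | keeps ℓ finite when a fit saturates |
| separation bound | max\|β̂\| > 15 | log-odds | a clinical fit this extreme is (quasi-)separated; "additional value" is then ill-posed, so the default is a hard error (`allow_nonconverged` downgrades to a warning) |
| GLM tolerance / max iter | 1e−8 / 100 | — | IRLS convergence criteria for step 1 |

## AIC stopping

The boosting fit after m iterations is treated as a linear smoother on the
working-response scale. Each base fit applies the rank-2 hat matrix
H_k = (1/n)11′ + cc′/‖c‖² (intercept + centered column c), and the
aggregated operator follows B_m = B_{m−1} + ν H_{k*_m}(I − B_{m−1}) from
B₀ = 0. Degrees of freedom df(m) = trace(B_m) — df(0) = 0, df after one
step = 2ν, non-decreasing, bounded by n. AIC(m) = 2n·ℓ(m) + 2·df(m); the
smallest minimizer over 1…m_max is selected. This trace recursion is the
classical L2-smoother approximation applied on the gradient scale; it is an
approximation for binomial loss, adequate because only *relative* AIC
across m matters here. The q+1 clinical parameters are excluded from df:
the offset is fixed, not estimated, in step 2.

Under permutation, AIC selection is **re-run on every permuted dataset** by
default, so the identical procedure maps data → ℓ on original and permuted
data — the exchangeability the permutation p-value relies on. The cheaper
variant (select once, reuse m for all permutations) is available as
`aic_rerun=False` / `--aic-once`. The dense n×n operator is guarded at
n > 5000 (use fixed m_stop beyond that).

## Synthetic-data generator

`simulate_dataset` draws the Gaussian two-group shift design: y a fair
coin; informative molecular columns N(μ_X, 1) in the y=+1 group versus
N(0, 1); the other p − p* columns N(0, 1) throughout; clinical covariates
the same with shift μ_Z. Named settings: null (p*=0); (a) p*=5, μ_X=0.5;
(b) p*=5, μ_X=0.8; (c) p*=50, μ_X=0.3; (d) p*=50, μ_X=0.5; (e) p*=200,
μ_X=0.3 — all with μ_Z=0, n=100, p=1000, q=5 — plus the redundancy pair
(f1) independent informative Z and X with μ_Z=μ_X=1, and (f2) identical to
f1 except X₁…X₅ are *exact copies* of Z₁…Z₅. Noise is drawn before shifts
are added, so a shared seed across settings gives common random numbers —
the right harness for power comparisons along a shift grid.

What the generator does **not** emulate: correlated features (beyond the
exact-duplication case), heavy tails, batch structure, missingness, or
class imbalance. Passing tests therefore demonstrate calibration and power
under clean Gaussian shifts; on real data the test remains valid (the
permutation argument needs only exchangeability of rows of X under H₀) but
power transfers only qualitatively.

### Study profiles and problem sizes

The full-scale benchmark profile is n=100, p=1000, B=200, 100 replicates.
The test suite and `scripts/acceptance.py` run a reduced "desk" profile —
p=200, B=99, 50 replicates, n kept at 100 — chosen so a study completes in
minutes on one CPU; the 200-replicate null-calibration and redundancy
studies additionally reduce n to 50. One caveat of small n: at n=50 with
q=5 strongly informative clinical covariates (μ_Z=1), the step-1 logistic
fit is (quasi-)separated in roughly one replicate in seven, so the f1/f2
contrast is run at the design's n=100, where separation does not occur.

## Numerical choices

- **Outcome coding**: the two sorted source levels map to (−1, +1), lower
  level → −1; invariant to row order, recorded in the result.
- **Tie-break** in the componentwise argmin: smallest column index.
- **Zero-variance columns**: slope 0, RSS equal to the total sum of
  squares — retained but never selected unless every column is constant
  (then a warning and a null update).
- **Centering**: X columns are mean-centered inside the fit by default.
  Because every base fit contains an intercept, centering is mathematically
  neutral — slopes, selections and original-scale coefficients are
  unchanged — and serves only numerical symmetry; a flag disables it.
  No variance standardization is applied by default (selection is
  scale-sensitive; standardize upstream if desired).
- **Permutations** are drawn with replacement from the permutation group;
  the identity is not excluded (its probability is negligible for n ≥ 10
  and excluding it would break exactness of the add-one p-value).
- **Reproducibility**: one master seed spawns B independent substreams
  (`numpy` SeedSequence), so the permutation loop is bit-identical for any
  thread count; the generator is bit-identical across runs for a fixed
  seed.
- **Loss monotonicity**: with logistic curvature ≤ 1/4 and ν ≤ 1, each
  update provably does not increase the training loss; the suite asserts
  the non-increasing path per iteration.

## Known limitations

- The AIC degrees of freedom are an L2 approximation on the gradient
  scale, not an exact binomial df; different AIC variants can shift m_opt
  (the test decision is insensitive to m_stop over a wide range, which the
  suite checks).
- The dense hat-operator recursion is O(n²) per iteration; AIC mode is
  impractical for n in the many thousands (guarded).
- Single global hypothesis only: no per-feature follow-up tests and no
  multiplicity machinery.
- Binary outcomes and linear molecular effects only; no survival or
  nonlinear extensions.
- A separated clinical fit (possible at small n with strong covariates)
  makes the question ill-posed; the default is to refuse rather than
  silently saturate the offset.
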