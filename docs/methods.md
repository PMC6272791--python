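# Methods

## Model

`plsvip` fits single-response partial least squares (PLS1) by NIPALS.
X (n compounds × m descriptors) and y (the activity; for the packaged
dataset the clearance index CI, dimensionless) are autoscaled — mean
centred and divided by the sample SD with the n−1 denominator — before
component extraction. Autoscaling is a deliberate choice: the source data
carry descriptors on wildly different scales, VIP is scale-sensitive, and
unit-variance scaling is the convention of SIMCA-style PLS. The scaling
parameters are stored on the fit and inverted for prediction, so all
reported errors are in original y units.

For one response the NIPALS inner iteration converges in a single pass
(w_a ∝ X′y_residual), making the fit fully deterministic; X and y are
deflated after each component. If the residual X block (or its covariance
with the y residual) collapses below 1e−12 (relative) before the requested
A components, the fit raises an error naming the achievable rank;
cross-validation helpers instead truncate to the component count every
fold achieves. The regression vector is recovered as B = W(P′W)⁻¹q and
reported in original units with an explicit intercept; the score-space and
coefficient-space prediction routes agree to 1e−8 and are asserted as an
invariant.

## Component count

A is chosen by maximising leave-one-out q² over A = 1…min(10, m, n−1),
ties broken toward smaller A. q² = 1 − PRESS/TSS, with TSS taken about the
full training-set mean and every fold rescaled on its own n−1 rows (no
information leak through the scaling).

## VIP and the selection loop

VIP_j = √( m Σ_a w²_ja s_a / Σ_a s_a ). Three weightings s_a are
available:

- `y_contribution` (default): s_a = max(0, 1 − Σ_i(y_i − t_ia q_a)²/Σ_i y_i²)
  on the autoscaled response — the fraction of y-variance explained by the
  a-th component's y-contribution t_a q_a. The literal comparison of y with
  the raw score t_a is dimensionally inconsistent (scores are not on the y
  scale), so the y-contribution is substituted; this equals
  q_a² t_a′t_a / TSS, strictly positive for every extracted component.
- `eq2_literal`: the same expression with the raw score t_ia in place of
  t_ia q_a, clamped at zero. On wide noise matrices every term can clamp to
  zero, in which case VIP is undefined and an explicit degenerate-fit error
  is raised.
- `component_ssy`: the classical q_a²·t_a′t_a sum-of-squares weighting
  (proportional to the default's numerator, hence identical VIPs up to the
  shared normalisation).

Because the W columns have unit norm, Σ_j VIP²_j = m under any
non-negative weighting; the test suite asserts this on every fit.

The selection loop keeps descriptors with VIP strictly greater than 1.000,
re-selects A each round (the optimal component count drifts as the pool
shrinks), and records (m, A, r², RMSE, q², RMSV) of the current model
before reduction. It deliberately runs past the q² optimum — until m stops
decreasing, fewer than two descriptors remain, no VIP exceeds 1, or 50
rounds — and the final subset is then chosen from the whole trace. The
default rule is the smallest m that is a local q² maximum: among the
near-optimal models, prefer the most parsimonious, which matters when the
compound count is small. `global_max_q2` is available as an alternative.
Peak detection uses strict inequalities for interior points; the first
trace entry counts as a peak when its q² is ≥ its single neighbour (so a
flat or monotonically falling trace returns the full model), the last only
when strictly greater.

## Validation battery

- **LOO**: each compound predicted from a model refitted (and rescaled) on
  the remaining n−1; deterministic.
- **LMO**: per repeat, a random permutation partitions the compounds into
  ⌈n/M⌉ disjoint groups of size ≤ M; one q² per repeat over all n
  out-of-fold predictions. Partitioning (rather than resampling single
  groups) is what keeps the repeat-to-repeat spread on the ±0.02 scale;
  M = 1 reduces exactly to LOO. Reported as mean ± Student-t 95% CI
  halfwidth, t(0.975, repeats−1)·SD/√repeats.
- **y-randomization**: y shuffled, model refitted at the *same* A
  (re-optimising A on shuffled responses would mix selection variance into
  the null), training r² and LOO q² recorded per repeat. The category
  bands on the mean r²: ≤0.2 (with mean q² < 0.2) none, 0.2–0.3
  negligible, 0.3–0.4 tolerable, >0.4 recognized chance correlation. The
  bands leave one edge case open — mean r² ≤ 0.2 with mean q² ≥ 0.2 — which
  is mapped to "negligible" as the conservative reading.
- **External**: r_p² is the squared Pearson correlation between observed
  and predicted. This convention (rather than 1 − PRESS/TSS) is the one
  consistent with the packaged dataset's reference values for both the
  22- and 19-compound test sets; the PRESS form goes strongly negative on
  the full test set. RMSE/RMSV/RMSP all use denominator n, keeping the
  training and test formulas consistent. Residuals are predicted −
  observed.
- **Golbraikh–Tropsha**: k = Σ(y·ŷ)/Σŷ² (observed regressed on predicted
  through the origin) and k′ = Σ(y·ŷ)/Σy² the converse — this assignment
  reproduces the packaged dataset's reference slopes (0.93, 1.01). R²₀ is
  the through-origin determination coefficient of predicted vs observed,
  R′²₀ the converse; ratios are (R² − R²₀)/R², the direction of the
  published pass criterion (<0.1). Note the reference ratios printed for
  this dataset cannot be reproduced from two-decimal values — they are
  hypersensitive to prediction rounding — so only the slopes are treated
  as reproducible quantities.
- **Outlier rule**: |residual| > 3 × training RMSE.

All randomness (LMO partitions, y-permutations) flows from a single
integer seed through one `numpy` Generator per call; seeds are recorded in
the result objects and reports.

## Applicability domain

Leverage is computed on the autoscaled matrix of the final model variables
(no intercept column), scaling parameters from training only. Training
leverages lie in [0,1] and sum to the rank of the scaled matrix. When the
Gram matrix is rank deficient (possible after aggressive selection), a
pseudo-inverse (rcond 1e−10) is used and a warning issued. h\* = 3k/n with
k the number of model variables. In the Williams data, training compounds
are standardized on their LOO residuals, test compounds on their
prediction residuals, both divided by the training RMSE — the same scale
the 3×RMSE outlier rule uses.

## Packaged dataset

88 compounds with observed CI (range 0.04–1.57) and, for the 87 modelled
ones, the calculated CI of the reference 48-descriptor model; 65 train /
22 test, plus mefloquine (CI = 1.57) retained in the table but flagged
excluded, honouring its deletion as an activity outlier while keeping the
table complete. Calculated values are stored exactly as printed (two
decimals); statistics recomputed from them therefore carry rounding noise
of roughly ±0.02 on correlation-type values and ±0.01 on RMSE-type values,
which is the tolerance used wherever they are compared to reference
numbers. Two compound names are stored corrected from their source
typography, with the printed strings kept in an alias column. A SHA-256
checksum guards the file at load.

## Synthetic generator

`generate_synthetic_qsar` emulates the *statistical* pathology of a raw
descriptor pool, not chemistry: `latent_rank` (default 3) standard-normal
factors drive y (unit-norm coefficient vector, additive noise of SD
`noise_sd` = 0.1, about 10% of the response scale) and the informative
descriptors, which are exact random combinations of the latents — so in
the noiseless limit the response is exactly recoverable and q² → 1.
Defaults mirror a small-campaign shape: n = 87 compounds, 10 informative
descriptors, 180 iid noise descriptors, 3 correlated blocks of 4
(base + jitter of SD 0.1, pairwise |r| ≈ 0.995), 10 constant columns;
columns shuffled into one table. Everything derives from one seed and is
bit-reproducible.

What passing on this generator does **not** show: real descriptor pools
have heavy-tailed, discrete and bounded columns, block correlation
structure tied to descriptor families, and signal spread over many weakly
informative variables; results on the generator demonstrate algorithmic
correctness and qualitative behaviour (enrichment, q² peaking), not
performance on real chemistry.

## Problem sizes

Tests and examples run the full loop on the default 87×212 generator
(seconds per seed); cross-validated component selection reuses one
A_max-component fit per fold to get all truncated-model predictions, which
is what keeps the iterative selection loop cheap. The dataset-derived
statistics are exact-arithmetic recomputations on 65/22/19 pairs.

## Known limitations

Single-response PLS only (no PLS2, no nonlinear kernels); no descriptor
computation from structures (descriptor tables are the input contract);
LMO partitions rather than resamples; the applicability domain is the
leverage/residual definition only (no distance-to-centroid or density
variants).
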