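# Methods

## The contamination model

After pooling, two processes deposit off-target tag counts on a droplet.
Cell-bound contamination comes from free tags binding the cell surface; in
the reaction-kinetic picture the amount bound is proportional to surface
area, and the cell's total tag count N_total is the observable proxy for
surface area. Ambient contamination comes from free or debris-bound tags
co-encapsulated with the cell and has a constant expected count per tag
across droplets. For a cell negative for tag B the expected contamination
is

    mu_B = p_B * (N_total - sum_k M_k) + M_B = p_B * (N_total + C),

with p_B the cell-bound fraction, M_k the ambient means, and C a
tag-specific constant. Over the one-to-two orders of magnitude that
N_total spans in practice, ln(N_total + C) is approximately affine in
ln(N_total), which gives the working regression

    ln(mu^neg) = beta1^neg * ln(N_total) + beta0^neg,

with counts taken as NB(mu, theta) (variance mu + mu^2/theta) to absorb
the overdispersion observed in real tag libraries. With zero ambient
contamination C = 0 and beta1^neg = 1 exactly; ambient contamination
flattens the slope below 1. For positive cells the count of the tag itself
cannot be modeled pre-pooling, but the remainder N_total − X is the pooled
contamination by all other tags; treating that pool as a single meta-tag
with shared binding chemistry yields the same NB regression form in the
(N_total − X, N_total) space. The sum-of-NBs-is-NB step is a modeling
assumption (exact only under a shared success probability), not a theorem,
and is used as such.

## EM classification

For each tag, the latent Z_i indicates whether cell i is positively
labeled. The E step computes

    P(Z_i=1 | X_i) = p(N_total - X_i | Z=1) pi_1 /
                     [ p_adj(X_i | Z=0) pi_0 + p(N_total - X_i | Z=1) pi_1 ]

in log space (log-sum-exp; posteriors never NaN even when both densities
underflow). `p_adj` is a floor adjustment: a cell whose tag count lies
*below* the fitted negative mean is at least as consistent with being
negative as a cell at the mean, so its negative density is replaced by the
density at the rounded fitted mean on the first iteration and by 1 on
later iterations. Without this, low-count cells far below the negative
mean would be pushed toward the positive class by the thin lower tail of
the NB. The priors pi_0, pi_1 are the class fractions of the previous
posterior at a 0.5 cutoff; before the first E step they are the class
fractions of the cosine initialization (the original behavior at
iteration 1 is unspecified; this choice is ours).

The M step refits the two regressions on the current hard assignment,
each class independently down-sampled to `max_fit_cells` (default 5000)
when larger. Down-sampling ranks cells by a deterministic blake2b hash of
(seed, tag index, barcode) and keeps the lowest-ranked, so results are
invariant to cell order and to the order tags are processed, and a single
top-level seed reproduces everything bitwise.

Initialization: Z0_i = 1 iff the cosine similarity between the cell's
count vector and the tag's canonical unit vector is >= 0.5 (computed on
raw counts; a log1p option exists but defaults off). Tags with fewer than
10 cells on either side of the cutoff are excluded ("unfit") with zero
posteriors rather than aborting the run, so samples with very few cells
degrade gracefully. Convergence is declared when the binary assignment at
posterior 0.5 is unchanged between consecutive iterations (assignment
stability is what matters downstream and is robust to likelihood
plateaus); the iteration cap is 30. Ties: cosine >= cutoff counts
positive, posterior must be strictly > cutoff to count positive. Cells
with N_total = 0 are excluded from fitting and called negative.

Note that this is a classification-EM variant, not a textbook EM: the
M step refits on hard assignments, priors are hard class fractions, and
the floor-adjusted negative "density" is improper from iteration 2 on.
As a result the observed-data log-likelihood (recorded per iteration in
`TagFitResult.loglik_trace` as a diagnostic) is not guaranteed monotone
and small decreases between iterations are normal; assignment stability,
not likelihood ascent, is the convergence criterion.

## GLM-NB fitting

The two-coefficient log-link NB regression is fit by alternating IRLS for
(beta0, beta1) at fixed theta with safeguarded Newton steps on ln(theta)
for the profile likelihood, stopping at a relative log-likelihood change
below 1e-8 or 50 outer iterations. theta is bounded to [1e-3, 1e5]; a fit
at the bound, a degenerate design (constant ln N_total), or hitting the
iteration cap is flagged unconverged. The scheme reproduces the reference
MLE: on test fixtures the estimates agree with statsmodels'
NegativeBinomial maximum likelihood to ~1e-5 in the coefficients. The
pmf/cdf use scipy's nbinom with n = theta, p = theta/(theta + mu).

## Randomized quantile residuals

For count y with fitted F, r = Phi^{-1}(u) with u uniform on
(F(y−1), F(y)]; residuals are standard normal iff the model is correctly
specified. The deterministic mid-quantile mode takes the interval
midpoint, removing randomization noise for automated checks — note that
with a single shared mean the mid-quantile residuals are supported on as
many points as the count range, so a KS test at large n can reject on
discreteness alone; calibration checks should use per-cell fitted means
(as the classifier produces), whose mixed supports are effectively
continuous. Residuals at F(y) = 1 in double precision are +inf; for
plotting they are capped to the maximum finite residual + 1. Q-Q plots
use Phi^{-1}((k − 0.5)/n) as theoretical quantiles.

## Simulator

Step 1 (staining): each sample's log-mean staining level is drawn from a
normal centered on the midpoint of the configured range (default 5–7 in
natural log) with sd = range/4, clipped to the range; each cell's true
count is log-normal around its sample mean (per-cell log-sd 0.6),
rounded half-up, floored at 1. Step 2 (cell-bound): the cell's own true
count serves as its N_total surface proxy, and each other tag k
contributes NB(p_k N_total, theta_k) counts. By default a cell's own tag
receives no cell-bound draw (its staining count is the signal; a
`self_contamination` switch restores it) — the generator's choice, made
to avoid double-counting signal. Step 3 (ambient): NB(M_k, theta_k) per
droplet per tag, reusing the tag's theta for ambient dispersion unless
configured otherwise. Doublets merge random singlet pairs without
replacement — true and cell-bound rows add, ambient is drawn once per
droplet — with the doublet count d solving d = floor(fraction × final
droplets). A doublet of two same-sample cells is scored as a singlet of
that tag. Optional zero-inflation drops each entry with probability
exp(−lambda x²) (~14% for a unit count at lambda = 2, ~61% at 0.5). Read
down-sampling keeps a uniform subset of a cell's reads without
replacement (multivariate hypergeometric over tags); cell down-sampling
keeps a uniform droplet subset with truth kept aligned.

Default per-tag parameters are drawn uniformly from p_k in (0.005, 0.02),
M_k in (1, 5), theta in (2, 10) — a moderate-contamination condition —
with cells per sample from a bounded log-normal (bounds 50–5000,
log-mean 6.5, log-sd 0.75, i.e. imbalanced samples). Presets s1–s5 span
small/clean (4 tags, p ~ 0.001–0.005) through large/noisy (30 tags,
p ~ 0.02–0.05, M ~ 5–20, lambda = 0.5); they are approximations assembled
from published ranges, not exact published configurations.

What the simulator does not emulate: transcriptome content (no gene
counts, so no expression-based doublet rescue), cell-type-specific
staining biases, batch structure, or empty-droplet ambient profiles.
Passing tests on simulated data therefore demonstrate correctness of the
statistical machinery under the generative model the method assumes, not
performance on any particular real dataset.

## Problem sizes used in tests

The benchmark-scale checks run at 30 tags / ~20–28k droplets (singlet
recall, fit-down-sampling equivalence) and 10 tags / ~11k droplets
(initialization robustness, cell down-sampling), chosen to match pooled
experiments of realistic size while keeping the suite fast; kernel-level
oracle checks run at n = 2000–20000.

## Known limitations

- Doublets are not modeled explicitly. A doublet's counts sit far in the
  tails of both the positive and negative model for each of its tags, so
  its call is decided by a contest of vanishing densities and is
  sensitive to the fitted dispersions. On small pools (4 tags and/or
  fewer than ~5k droplets) this makes doublet calls bistable with respect
  to the initialization cutoff: whichever class absorbs the doublets
  during initialization deflates its fitted theta and keeps them. At
  pooled-experiment scale (10–30 tags, ≥ ~10k droplets) final calls are
  stable across initialization cutoffs 0.2–0.9 in all conditions tested.
  Expression-based doublet detection remains the recommended complement.
- Near-zero contamination (p below ~0.005) makes the positive-space
  regression degenerate (near-constant tiny remainders), destabilizing
  its dispersion estimate; the model targets data where contamination is
  present, which is the motivating regime.
- The affine approximation to ln(N_total + C) degrades for datasets whose
  N_total spans far more than two orders of magnitude (very heterogeneous
  cell sizes).
- The prior at iteration 1 and the FASTQ read-layout conventions (10x 3'
  v3 defaults, Hamming-distance-1 unique correction) are this package's
  documented choices where the method leaves them open.
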