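# Methods

## Prevalence weighting from mechanistic axes

The cohort is an N×M matrix C of mechanistic-axis coefficients plus a table
of simulated ACR-N responses x_{i,t,s} (percent improvement; negative values
are worsening) per therapy t and sample time s. Each axis is split at its
empirical median into two bins; values equal to the median go to the lower
bin (half-open intervals (−∞, med] / (med, ∞)), a deterministic tie rule
that makes bin assignments reproducible from the cutpoints alone. An axis
that is constant across the cohort cannot be split and is reported as
degenerate rather than silently dropped.

A solution assigns each axis one free probability p_j ∈ [0, 1] on the upper
bin (the lower bin holds 1 − p_j, so the marginals sum to one). The
unnormalized weight of VP i is the product over axes of its bin
probabilities; weights are normalized over the cohort at the end (for a
global normalization the result does not depend on whether intermediate
factors are normalized). If a solution with some p_j ∈ {0, 1} annihilates
every occupied bin pattern, the total mass is zero and an explicit
all-mass-lost error is raised; inside the optimizer this state is mapped to
the worst finite objective instead.

### Correlated axis pairs

A dependence between two axes k, l is introduced with a Gaussian copula: the
pair's product of marginal bin probabilities is replaced by the probability
that a standard bivariate normal with correlation ρ falls in the rectangle
whose margins reproduce the bin probabilities. The latent cutpoint for an
axis with upper-bin probability p is z* = Φ⁻¹(1 − p); LOWER maps to
(−∞, z*], UPPER to (z*, ∞), so the marginals are 1 − p and p and the ρ = 0
case reduces exactly to the independent product. The cohort mean and SD per
axis are recorded on the solution for completeness, but the rectangle limits
depend only on p and the bin membership. Only disjoint bivariate pairs are
supported; higher-dimensional couplings are out of scope.

The bivariate normal CDF is evaluated through the single-integral identity
Φ₂(h, k; ρ) = Φ(h)Φ(k) + (1/2π)∫₀^ρ exp(−(h² − 2rhk + k²)/(2(1−r²)))/√(1−r²) dr
with adaptive quadrature at absolute tolerance 1e−12, comfortably inside the
1e−8 contract for rectangle probabilities; tests cross-check the arcsin
orthant closed form, scipy's bivariate CDF, and Monte-Carlo sampling.

### Optimization coordinates

For optimization, probabilities map to unconstrained angles by the two-bin
hyperspherical transform p = sin²θ and correlations by ρ = tanh η. Any real
vector is a valid point (sin² is periodic), which removes box-edge
complications from the simplex search; the round trip is exact to 1e−12.

## Scoring a population

For each therapy×timepoint target the weighted mean x̄ = Σ w_i x_i, the
weighted SD s = √(N Σ w_i (x_i − x̄)²/(N − 1)) (N = cohort size; reduces to
the sample SD under uniform weights), and the weighted bin fractions
f_b = Σ_{x_i ∈ bin b} w_i are computed. Bins are half-open [lo, hi) with the
extreme bins extended to ±∞ by default (clipping); a strict mode errors on
out-of-range responses instead. Trial-side statistics missing from a target
are reconstructed from its binned counts via midpoints, mean = Σ c_b n_b/N_T
and sd = √(Σ n_b (c_b − mean)²/(N_T − 1)); the default ACR-N bins are <20,
20–50, 50–70, ≥70 with midpoints 10, 35, 60, 85 (the edge midpoints are
configurable; 35 for the 20–50 bin is the standard convention).

Three p-values per target: a two-sided Welch t-test on the means (Welch
rather than pooled, so the variance comparison is not double-counted with
the F-test), a variance-ratio F-test made two-sided by doubling the smaller
tail (a one-sided flag exists), and a χ² test of the trial counts against
expected counts N_T·f_b floored at 1e−6·N_T and renormalized, with B − 1
degrees of freedom. The weighted population enters the t/F tests with the
Kish effective sample size (Σw)²/Σw², floored at 2 so the tests remain
defined for near-degenerate weightings; a configurable alternative uses the
trial's N on both sides. Fisher's method aggregates the included p-values:
X = −2 Σ ln p ~ χ²(2k), composite = P(χ²(2k) ≥ X). The optimization
objective is Σ ln p with p floored at 1e−300, which keeps the objective
finite (≈ −690 per zero p-value) and Nelder–Mead stable off-optimum; the
composite is a strictly increasing function of the objective at fixed k. A
population is accepted when composite > 0.05 (configurable threshold).

Note a deliberate dof asymmetry: with Kish sizing, equal SDs give a
two-sided F p-value of about 0.95 rather than 1 (the doubled tail is
asymmetric when the dof differ). Under the trial-N mode the self-consistency
is exact: targets generated from a solution score p = 1 on mean and SD at
that solution, and only bin-count rounding remains.

## Calibration and ensembles

Nelder–Mead (standard coefficients 1, 2, 0.5, 0.5; convergence when the
simplex objective spread falls below 1e−6 or after 2,000 iterations) runs in
the unconstrained space. Initialization draws p_j ~ Uniform(0, 1) and
ρ ~ Uniform(−0.5, 0.5); up to `restarts` (default 5) runs are performed,
stopping early once a run is accepted, and the best solution is returned
with a monotone best-so-far trace. Non-convergence returns the best-so-far
with a flag, never an exception.

Ensembles repeat calibration with per-attempt seeds derived from the master
seed and attempt index, so the member set is reproducible and independent of
scheduling. Once any member exists, new attempts start from a Gaussian
perturbation (SD `sigma_seed`, default 0.25, in unconstrained coordinates)
of a uniformly chosen accepted member; before that, from random solutions.
Members are accepted when composite > threshold; an optional minimum
L∞ distance on p deduplicates near-identical members (off by default). The
attempt budget defaults to 20× the requested ensemble size; exhausting it
with zero acceptances is an error with diagnostics.

On small, fully identified tasks (few axes, exact targets) all members
converge to nearly the same solution; genuine ensemble diversity requires an
under-determined task — many axes, or responses the targets leave
unconstrained — which is also the realistic regime (tens of axes, a handful
of trial statistics). The ensemble-contrast example is constructed that way.

## Downstream analyses

*Responder contrast.* Members are split by their weighted mean response to a
chosen therapy: strong above `hi_cut`, weak below `lo_cut`, the band between
excluded (defaults 48 and 44.75 ACR-N %, the reference rituximab cuts —
the high cut above and the weak cut at the observed trial mean). Per-axis
medians and interquartile ranges of p_j are tabulated per group and axes are
ordered by the absolute difference of group medians. Empty groups warn but
do not abort.

*Scenario re-statting.* Fixed, previously calibrated weights are applied to
an alternate per-VP response vector (aligned by vp_id, misalignment is an
error) and the population statistics recomputed — no re-optimization — so
the population-level effect of a simulated pathway perturbation is isolated.

*Multianalyte biomarkers.* The mediator panel is pruned: analytes with
pairwise Pearson |ρ| > 0.8 (configurable) are joined into connected
components, and each multi-member component keeps exactly the analyte with
the lowest mean absolute correlation against all other analytes in the
panel, ties broken by column order; constant columns are retained and
flagged. Then every size-k subset of retained analytes (k defaults to 5) is
fit by prevalence-weighted least squares to the per-VP response; the subset
maximizing weighted R² wins. Because alternate populations differ only in
their weights, the regression must be weighted for the analysis to vary
across the ensemble (an unweighted flag exists). The weighted fit reports
adj R² = 1 − (1 − R²)(n_eff − 1)/(n_eff − k − 1) and
BIC = n_eff ln(Σ w_i r_i²) + (k + 1) ln n_eff with n_eff the Kish size —
weighted analogues are required once weights enter the fit. A combinatorial
budget (default 200,000 subsets) guards the exhaustive search. Selection
frequencies across populations summarize marker robustness.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes, not
disease biology: axes are i.i.d. Uniform(0, 1) (median-splittable by
construction; Beta alternatives can be passed as explicit axis values);
responses are clip(a_t + Σ_j b_tj C_ij + ε, −21, 100) with ε ~ N(0, σ_t),
the clip range matching the observed simulated ACR-N envelope (21% worsening
to 100% improvement); default loadings b_tj ~ N(0, 25²) give trial-like
response SDs near 20–25%, intercepts 35/40/30% for the three default
therapies, and residual σ_t = 5%. Mediators are linear readouts of the axes
with unit-scale loadings plus N(0, 0.3) noise, and collinearity is injected
by duplicating leading columns with noise at 5% of the column SD to exercise
the pruning path. Default task size is 200 VPs × 10 axes with three therapy
arms of N_T = 400 — large enough that rounding effects are small, small
enough that the full acceptance run takes seconds.

Targets derive from a stored ground-truth solution (default p* ~
Uniform(0.15, 0.85)): *exact* mode takes bin counts as the largest-remainder
rounding of N_T·f_b (counts always sum to N_T) and the mean/SD as the exact
weighted values, so the truth scores near-perfectly and recovery is
well-posed; *sampled* mode draws counts multinomially and recomputes mean/SD
from the sampled counts via midpoints. All draws derive from the spec's
master seed through named substreams.

What passing the synthetic tests does *not* show: the generator's responses
are linear in the axes with homoscedastic noise, mediators are linear
readouts, and axes are independent uniforms — real biosimulation output has
none of these guarantees, and recovery of a known truth says nothing about
the biological validity of weights fit to real trial data. For M > 3 the
recovery contract is the achieved composite, not per-axis error: multi-axis
tasks are identifiability-limited and distinct p vectors can induce nearly
identical weight patterns.

## Known limitations

- Midpoint reconstruction of trial statistics is biased for the SD: mapping
  responses to bin midpoints replaces within-bin spread with midpoint
  distances, inflating the binned SD relative to the continuous weighted SD
  (measured 12.6 vs 7.2 ACR-N % on the default task). Consequently,
  evaluating the generating truth against *sampled*-mode targets rejects on
  the F-test even though the truth generated the data; the calibration
  compensates by fitting the midpoint-based target. The distribution-free
  sanity check that does hold, and is tested, is that the χ² bin p-values at
  truth dominate the uniform distribution.
- Only bivariate axis correlations are supported, and only disjoint pairs.
- Best-subset regression is exhaustive by design; panels must be pruned (or
  the budget raised) before large k.
- The acceptance rule compares a weighted pseudo-sample against trial counts
  with classical two-sample tests; the Kish size is a standard surrogate,
  not an exact sampling theory for weighted cohorts.
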