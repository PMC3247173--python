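# Methods

This note documents the statistical model behind `snpmix`, the choices made
where the design was genuinely open, and what the simulation-backed tests
do and do not establish.

## The consistency statistic

Each protein's normalized log2 sample/reference ratios from a balanced,
repeated reference design follow

    Y_ijkl = μ + T_j + S_k(j) + δ_ijk + ε_ijkl,
    i = 1..I experiments, j = 1..J groups, k = 1..K patients, l = 1..L replicates,

where T_j are fixed group effects, S_k(j) random patient effects, δ the
between-array (between-experiment) error with variance σ²_δ and ε the
within-array error with variance σ²_ε. A probe that lost structure reports
irreproducibly, inflating both error strata, so z = σ²_δ + σ²_ε is the
per-protein consistency statistic.

Estimation is least squares on the balanced design via expected mean
squares (EMS):

    σ̂²_ε = MS_within = Σ (Y_ijkl − Ȳ_ijk·)² / (I·J·K·(L−1)),
    σ̂²_δ = (MS_exp − MS_within) / L,
    MS_exp = L Σ (Ȳ_ijk· − Ȳ_·jk·)² / (J·K·(I−1)).

EMS rather than REML because for balanced, complete data the EMS estimator
*is* the least-squares-derived one, is unbiased, and is exactly invariant to
every fixed effect (the per-(j,k) centering absorbs μ, T_j and S_k(j)).
Negative σ̂²_δ (possible under method-of-moments) is truncated to zero by
default before summing — z feeds a density model on the variance-total
scale — with a flag to disable truncation. The mixture is fitted to raw z
without a log transform. Proteins with no signal at all are dropped with a
logged count.

## The semi-nonparametric density family

Each mixture component is a semi-nonparametric (SNP) density

    f(z|θ) = [Σ_{j=0}^{K} a_j w^j]² φ(w)/v,   w = (z − u)/v,

a squared truncated Hermite expansion times a Gaussian kernel. K = 0 is
exactly Gaussian; K = 1 adds skewness; K = 2 additionally admits heavy
tails and bimodality. The unit-integral restriction E[P(Z)²] = 1 (Z
standard normal) is enforced by a trigonometric parameterization:
a = (sin φ, cos φ) for K = 1 and

    a₀ = sin φ₁ − cos φ₁ cos φ₂ / √2,  a₁ = cos φ₁ sin φ₂,  a₂ = cos φ₁ cos φ₂ / √2

for K = 2. The √2 denominator is the one that makes the restriction hold
identically (expanding E[P(Z)²] = a₀² + a₁² + 3a₂² + 2a₀a₂ shows the cross
terms cancel exactly); the property tests verify it to 1e-10 over random
angles. Angles are unconstrained reals — the transform is periodic and
wrapping would only introduce kinks into the likelihood surface.

Moments are closed-form through Gaussian moment algebra
(m₁ = 2a₀a₁ + 6a₁a₂, m₂ = a₀² + 3(a₁² + 2a₀a₂) + 15a₂²), and the CDF is
closed-form because each incomplete moment ∫_{−∞}^x wᵏ φ(w) dw (k ≤ 4) is a
polynomial combination of φ and Φ. Sampling inverts the CDF on a fixed
8001-point grid over [u − 10v, u + 10v]: deterministic given the seed, no
envelope tuning, and directly testable against the CDF (the
Kolmogorov–Smirnov distance at n = 10⁵ is below 0.01). Density zeros at
polynomial roots return log-density −∞; downstream code floors log terms at
−745 before exponentiating so responsibilities never become NaN.

## Mixture fitting

The two-component log-likelihood is maximized by EM. The E-step computes
responsibilities in log space. In the M-step the mixing proportion is
updated to the mean responsibility — its exact maximizer, which keeps the
quasi-Newton machinery on the component parameters only — and each
component takes one Newton-like step

    θ ← θ − (d²Q − B)⁻¹ d¹Q

on its expected complete-data log-likelihood Q, with B maintained by
Davidon's rank-one update fed by the change of the Q-gradient across
E-steps. B starts at zero (a pure Newton step on Q, the simplest choice
consistent with an update rule that only defines increments). Scales are
optimized as log v so every iterate stays in the valid space; gradients are
analytic and the Hessian is closed-form for K = 0 and a central difference
of the analytic gradient otherwise.

Safeguards, all of which exist because neither the EM-gradient step nor the
rank-one update is guaranteed monotone on its own:

* the step is used only if it is an ascent direction for Q; otherwise the
  pure Newton step (B = 0) is tried;
* a step that would decrease the *observed* log-likelihood is halved up to
  20 times, then replaced by a bounded numerical maximization of Q
  (L-BFGS-B), and never accepted below the current value;
* iterates are boxed (u within the data range ± 10 sd, v within
  [1e-4, 100] sd) so a component cannot collapse onto a single point — the
  classic unbounded-likelihood spike of location-scale mixtures, which is
  not a useful maximum.

The observed log-likelihood is therefore monotone to numerical tolerance
(asserted over 100 random datasets in the tests). Convergence is declared
at relative log-likelihood change below 1e-8 (default), capped at 500
iterations. Initialization splits the data at the median, moment-matches
each half, starts all angles at π/2 (the Gaussian shape) and jitters
additional starts with a seeded RNG; the best final log-likelihood over
`n_starts` starts wins. After fitting, components are relabelled so the
lower-mean component is first. Fits with a boundary mixing proportion are
flagged, not rejected.

Single-density (null) fits use the closed-form Gaussian MLE for K = 0 and
bounded multistart L-BFGS-B otherwise, with canonical shape starts
(Gaussian, both skew directions, bimodal) moment-matched to the sample —
without the bimodal starts a K = 2 null on well-separated data reliably
lands in the Gaussian local optimum.

## Choosing the number of components

Model selection minimizes −2 logL + C(N)·p over the 3 null orders and the
9 (K₀, K₁) pairs, with C(N) = 2 (AIC), log N (BIC, the default) or
2 log log N (HQ), p counting (u, v, K angles) per component plus the mixing
proportion. Ties break toward smaller total K.

Separability is tested by the likelihood-ratio statistic
−2 log λ = 2(logL_alt − logL_null) between the criterion-best fits. Because
the mixing proportion sits on the boundary under the null, the statistic is
calibrated by a parametric bootstrap: 500 datasets (default) drawn from the
fitted null density, each refitted under both hypotheses. The bootstrap
refits fix the tuning orders already selected on the observed data — the
standard practice for mixture LRTs, and the only variant whose calibration
can be verified at a hundred-replicate scale on one CPU; a full
re-selection per replicate is available (`full_selection=True`). The
closure of the two-component family contains every single density (boundary
mixing proportion), so each replicate's alternative log-likelihood is
floored at its null value, keeping all bootstrap statistics nonnegative.
The p-value is the add-one estimator (1 + #{boot ≥ stat})/(B + 1);
rejection compares the statistic to the empirical (1−α) bootstrap quantile,
α = 0.05 by default. If the test does not reject, the pipeline stops before
classification: the statistics cannot separate the classes and chemical
validation is required instead.

## Classification and error-rate control

With the fitted mixture, protein i's posterior probability of inconsistency
is P(R_i = 1|z_i) = λ̂₁f̂₁(z_i)/(λ̂₀f̂₀(z_i) + λ̂₁f̂₁(z_i)), computed via
log-sum-exp. For a declaration vector δ the estimates are

    FDR̂ = Σ(1 − p_i)δ_i / Σδ_i,    FNR̂ = Σ p_i(1 − δ_i) / Σ(1 − δ_i),

and the cutoff minimizes γ·FDR̂·d/m + (1−γ)·FNR̂·(m−d)/m over every
achievable declared count d (declaring the d largest posteriors is
equivalent to a posterior cutoff, and the d-sweep is exact and finite; cost
ties break toward smaller d). γ defaults to 0.5; a 2:1 penalty of false
discoveries corresponds to γ = 2/3 and is exposed as a named preset. With
known truth (simulations), realized rates are the contingency ratios V/R
and T/(m−R), reported per replicate and averaged across replicates.

## The synthetic-data generators

**Microarray generator.** Per protein, patient abundances follow
log2(μ_jk) = μ + G_j + S_k(j) with G_j ~ U[−1, 1] and S_k(j) ~ N(0,
(0.4v_j)²), v_j ~ U[0.5, 2] (drawn independently per protein — the model is
per-protein and nothing couples probes); observed ratios are
y_ijkl = C + G_j + S_k(j) + δ_ijk + ε_ijkl with
C = −log2(Σ 2^{G_j+S_k(j)}/(J·K)), σ_δ = 0.2, σ_ε = 0.15. The default
design is 2 experiments × 4 groups × 10 patients × 6 replicates × 300
proteins, half of them damaged.

**Inconsistency injection.** Each damaged protein draws once a
between-array sd s_b ~ U[0.05, 0.5] and within-array sd s_w ~ U[0.1, 0.4],
picks a uniformly-random number of arrays between a quarter of the arrays
and all of them, and on each picked array adds one shared N(0, s_b²) shift
to the L replicates plus i.i.d. N(0, s_w²) per replicate. The floor on the
affected-array count is this package's reading of an underdetermined
mechanism: with no floor, about a fifth of "inconsistent" proteins receive
damage below the estimator's detection limit ((A/n)(s_b² + s_w²) ≲ 3
standard errors of z), which contradicts the reported behaviour of the
variance-component statistic (its false non-discovery rate at 160 declared
is a few percent, not ten). A quarter-floor is the minimal choice under
which both the variance-component and the Pearson-correlation reference
error rates are reproduced within the acceptance band; it is exposed as
`NoiseSpec.min_affected_frac` and was fixed once.

**Direct mixture draws.** Nine catalogued two-component SNP mixtures
(`TABLE1_MODELS`) spanning normal, skewed and bimodal shapes at component
separations D = |μ₁−μ₂|/(σ₁+σ₂) of 1 or 2 drive the LRT power study. Two
catalogue entries (models 6 and 8) do not actually sit at their nominal
separation when the exact moments are computed (1.13 and 1.05 instead of
1); the tests pin the exact values and the nominal-separation check is
asserted only where it holds.

**What the generators do not emulate:** spatial array artifacts, intensity-
dependent (nonlinear) normalization residue, missing spots, correlated
probes, non-Gaussian error tails. Passing tests therefore demonstrate
correctness of the estimator and mixture machinery under the stated
generative model, not robustness to real-array pathologies.

## Harness conventions and problem sizes

The Pearson baseline averages the L replicates per (experiment, patient)
cell and correlates the two experiments' 40-point patient profiles; lower
correlation ranks as more inconsistent (replicate-level pairing is
available by flag). Error-rate curves average realized (and optionally
posterior-estimated) FDR/FNR over every declared count; replicates whose
mixture fit fails are excluded from the estimated-rate averages only.

The power study tests each simulated dataset with the bootstrap LRT; by
default one null threshold per grid cell is bootstrapped from the first
replicate's null fit and shared across replicates (per-dataset bootstrap
selectable). Replication sweeps redo simulate → fit → minimum-cost per grid
value of biological (patients) or technical (on-array) replication.

Default problem sizes in the test suite — 100 replicates for error-rate
averages, 20 for estimate-conservatism checks, 50 replicates × B = 100 for
power cells, 100 outer replicates × B = 100 for type-I calibration — were
chosen as the smallest sizes at which the Monte-Carlo error is comfortably
inside the assertion tolerances.

## Known limitations

* The FDR estimate is approximately unbiased rather than conservative in
  our reconstruction: information-criterion selections with skewed or wide
  inconsistent components can push the average estimated FDR slightly
  (≈0.01–0.03) above the realized one at intermediate declared counts. The
  FNR estimate is robustly conservative (upward-biased).
* K > 2 orders and multivariate SNP mixtures are out of scope, as are
  unbalanced designs and normalization itself.
* The bootstrap LRT's default fixed-order refit trades a small amount of
  selection uncertainty for a ~50× runtime reduction; use
  `full_selection=True` when that uncertainty matters more than time.
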