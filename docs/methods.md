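# Methods

## Model and notation

A confirmatory factor model for p observed items and m latent factors
implies the covariance structure Σ(θ) = ΛΨΛ′ + Θ, with Λ (p×m) the
loadings, Ψ (m×m) the factor covariance matrix and Θ (p×p) the residual
covariance matrix. Only the covariance structure is modeled: means are
accepted in input data but centered out, and degrees of freedom are
counted against the p(p+1)/2 covariance moments, df = p(p+1)/2 − q with q
the number of free parameters. No index in scope involves the mean
structure, and the model syntax deliberately rejects regression paths —
the tool is about measurement-model fit.

Two identification conventions are supported and are exchangeable for
everything this package reports: fixing the first loading per factor to 1
(`marker_loading`, the default) or fixing factor variances to 1
(`unit_factor_variance`). The minimized discrepancy and test statistic are
identical under both (a tested invariant); the choice only affects how the
solution's parameters read.

## Estimation

The ML discrepancy F_ML(θ) = ln|Σ(θ)| − ln|S| + tr(SΣ(θ)⁻¹) − p is
minimized over the free parameters by L-BFGS with the analytic gradient
tr[Σ⁻¹(Σ−S)Σ⁻¹ ∂Σ/∂θ_k], followed by a dense-Hessian BFGS polish so the
optimum is reproducible to far below the 1e-6 invariance contracts. Starts
are data-informed (marker-regression slopes for loadings, half the item
variance for residuals, factor correlation .3); on failure the fit
restarts up to four times from increasingly perturbed starts. Convergence
means gradient max-norm < 1e-6 within 500 iterations. The sample
covariance uses the 1/n denominator and the statistic is T = n·F_min,
matching the normal-likelihood convention of mainstream SEM software; an
(n−1) Wishart multiplier is available (`multiplier="n-1"`) and the RMSEA
denominator follows whichever multiplier is chosen, for internal
consistency.

Improper solutions (Heywood cases: negative variances, |factor
correlation| > 1) are flagged, retained in the simulated distributions by
default, and their rate is reported; a config switch (`drop_improper`)
excludes them instead. Dropping silently would bias the distributions;
retaining silently would hide a diagnostic — so the default is retain and
count. Non-converged replicates are always excluded and counted, and a
population with more than 20% nonconvergence aborts the study with
diagnostics rather than producing cutoffs from a censored distribution.

A genuinely structureless sample covariance (no common factor) puts the
one-factor likelihood on a flat ridge (λ → ∞, φ → 0 with λφλ′ constant);
the optimizer correctly reports nonconvergence there rather than a
spurious optimum, and the test suite pins that behavior.

The independence baseline needs no optimizer: its ML solution is diag(S),
so T_b = n(ln|diag S| − ln|S|) and df_b = p(p−1)/2, verified against
numerical optimization.

## Robust (MLR-style) scaling

Under non-normal data the ML χ² is stochastically inflated. The package
computes a Satorra–Bentler-type mean-scaling factor c = tr(UΓ̂)/df, where
Γ̂ is the empirical fourth-moment (asymptotically distribution-free)
covariance matrix of vech(S) and U = W − WΔ(Δ′WΔ)⁻¹Δ′W is the
normal-theory residual weight projection at the solution
(W = ½D′(Σ̂⁻¹⊗Σ̂⁻¹)D, Δ = ∂vech Σ/∂θ′). The scaled statistic is
T/c; the baseline statistic is scaled analogously with its own Σ̂ and Δ.
This is the classic mean-scaled robust statistic, asymptotically
equivalent to (but not numerically identical with) other robust variants
emitted by SEM software under "MLR"; no exact equivalence to any one
implementation is claimed. For df = 0 the factor is undefined and the
operation refuses to scale (T = 0 anyway); a rank-deficient Γ̂ falls back
to c = 1 with a warning and a flag.

Two calibration facts are worth knowing. Under multivariate normal data
c → 1 for the *analysis* model, but the baseline's factor does not
approach 1 unless the independence model is itself true — the scaling
theory evaluates the weight matrix at the fitted (here: misspecified)
model. And at N = 500 with skew-1/excess-kurtosis-3 margins, the raw mean
of T runs ≈ 25% above df while the scaled mean is within Monte Carlo error
of df (both measured by the acceptance script).

## Simulation design

Replicate data are drawn from the population model's implied covariance.
Non-normal margins use Fleishman cubic transforms Y = a + bZ + cZ² + dZ³
(a = −c; coefficients solved to 1e-10 moment tolerance; feasibility
requires excess kurtosis ≥ skew² − 2) applied to correlated normals drawn
at the Vale–Maurelli intermediate correlation, the real root in [−1,1] of
r = ρ(b_i b_j + 3b_i d_j + 3d_i b_j + 9d_i d_j) + 2ρ²c_i c_j + 6ρ³d_i d_j.
With normal margins every transform is the identity and the intermediate
matrix equals the target, so the non-normal code path reproduces the
normal path bit for bit — there is only one sampler to trust.

Seeding is counter-based: replicate (population, rep) draws from
`SeedSequence(master_seed, spawn_key=(crc32(label), rep))`, making streams
reproducible, order-independent, and safe to parallelize. Identical
config + seed ⇒ byte-identical outputs (a tested invariant).

When an empirical dataset is supplied through a config file, the default
margins are the per-item skewness and excess kurtosis estimated from that
dataset, so the simulation matches the observed response distribution;
explicit margins or `normal` override this. Data are simulated as
continuous variables matched on those moments; discretization to Likert
categories is not implemented. This is the main respect in which the
generator idealizes real questionnaire data: passing results say the
method behaves correctly for continuous non-normal responses with the
stated moments, not that coarse 4/5-point scales introduce no additional
distortion (ordinal estimators are out of scope).

## ROC analysis and cutoffs

H1 (misspecified-population) fits are the positives. A replicate counts as
flagged when its index value is strictly on the worse-fit side of a
cutoff; a value exactly at the cutoff passes, consistent with cutoff
statements of the form "χ² ≤ 28.03" / "CFI ≥ .972". Candidate cutoffs are
the observed pooled values (no interpolation); the empirical ROC curve's
trapezoidal area equals pairwise concordance with ties counted ½ (the
Mann–Whitney identity, enforced to 1e-12 against a brute-force oracle).

The Youden-optimal cutoff maximizes sensitivity + specificity − 1 by
exhaustive search over the candidates; ties break toward higher
specificity, then toward the cutoff that accepts more models — paper-silent
choices resolved in favor of preserving H0-acceptance behavior. Reports
carry AUC, cutoff with comparator, sensitivity, specificity, accuracy and
the implied type I (1 − specificity) and type II (1 − sensitivity) rates.
Indices with AUC below the screening threshold (default .80 — a
conventional, not universal, choice; raise it for stricter error control)
are discarded with the reason recorded. An AUC below .5 means the
correctly specified models *look worse* than the misspecified ones — a
pathology to inspect, so the report is flagged and no cutoff is endorsed;
the classifier is never silently re-oriented. Only balanced (Youden)
weighting is implemented; asymmetric utility weightings are a deliberate
non-goal of the default path.

## Decision rule and robustness

With an empirical dataset: accept when every kept index passes its
tailored cutoff, reject when every kept index fails, and otherwise the
best-performing (highest-AUC) kept index decides. If several indices tie
for best and disagree, the verdict is indeterminate with an explicit
statement — the single-best-index rule has no defined extension there.
When no index survives the screen, the verdict is indeterminate and the
report warns that the designed misspecification may be too weak to detect
in this scenario. The report always prints the realized error rates; when
they are too large for the application the researcher can either accept
them explicitly or redefine the H1 population (the report says so rather
than automating that judgment).

Testing approximate rather than exact fit needs no special code path: set
the H0 population to a model that is *slightly* misspecified relative to
the analysis model and run unchanged. Robustness checks run the full
pipeline over several H1 forms and summarize verdict agreement; forms
whose population discrepancies F0 differ by more than a factor of 2 raise
a warning that the degrees of misspecification are not comparable. F0 is
obtained by minimizing F_ML against the population-implied covariance (no
sampling) and is reported as population RMSEA √(F0/df) and a χ²/df
analogue 1 + nF0/df.

## Scenarios and problem sizes

The canned scenarios pin every default the studies use: 500 replications
per population (the standard choice for this class of simulation),
N = 468 / 474 for the two example-like settings, N = 500 with 1000
replications for the two calibration suites. All scenario parameter values
are synthetic stand-ins (loadings within [.5, .8], standardized items,
factor correlation .30 in the two-factor setting) and are labeled as such
in each scenario's provenance note; reproducing any published analysis
requires the actual fitted coefficients, supplied via
`transcribe_paper_models` (which validates completeness and, when given
expected residual covariances, checks r·√(θᵢθⱼ) against them within
rounding). With these stand-ins the split-factor scenario is a strong
misspecification (population RMSEA ≈ .16, all AUCs ≈ 1) while the
residual-correlation scenario is mild (population RMSEA ≈ .03, best AUC
≈ .77 at N = 474) — the pair deliberately brackets the easy and hard
regimes.

A full 500+500 study fits ~1000 models and runs in well under a minute on
one CPU; the whole acceptance script (two studies, a null contrast and two
1000-replication calibration suites) takes a few minutes.

## Known limitations

- Continuous simulation only: no ordinal discretization, no WLSMV/DWLS,
  no missing data.
- The robust statistic is the mean-scaled variant; mean-and-variance
  adjusted or residual-based robust statistics are not implemented, and
  scaled CFI/RMSEA are plain plug-ins of T/c, not the later
  robust-formula versions.
- No standard errors or parameter inference — the fitted solution exists
  to produce test statistics and implied moments.
- AUC is reported without confidence intervals; with 500+500 replicates
  its Monte Carlo standard error under the null is ≈ .013.
- Automatic search over H1 forms (random/extreme population models) is
  out of scope; H1 is always user-designed.
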