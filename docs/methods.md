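# Methods

`emgsynergy` compares four matrix-factorisation methods for muscle-synergy
extraction — non-negative matrix factorisation (NMF), principal component
analysis (PCA), independent component analysis (ICA) and factor analysis
(FA) — on gait-like surface EMG. This note documents the models, the
numerical choices, and what the synthetic data do and do not emulate.

## The decomposition model

Muscle activation patterns are an L×N matrix **x** (L = 10 muscles, N = 200
normalised time points, entries in [0, 1]). Every method approximates

x ≈ W·H (+ per-muscle offset for the centring methods),

with W ∈ ℝ^{L×K} the time-invariant synergy weights and H ∈ ℝ^{K×N} the
time-varying excitation primitives. Methods differ only in their
constraints:

| method | constraint | algorithm |
|---|---|---|
| NMF | W, H ≥ 0 | Lee–Seung multiplicative updates, Euclidean objective |
| PCA | primitives orthogonal | SVD of the row-centred matrix (Eckart–Young optimal) |
| ICA | primitives independent (4th order) | whitening + symmetric fixed-point with kurtosis contrast |
| FA  | loadings = √eigenvalue-scaled eigenvectors | principal-axis factoring, regression scores |

### Shared output conventions

Factorisations are identified only up to permutation, sign and scale.  To
make methods comparable:

* centring methods store the removed per-muscle mean in `offset`, and VAF is
  always computed on the reconstruction with the mean re-added, against the
  original uncentred **x**;
* each primitive's sign is flipped so its skewness is ≥ 0 (activation bursts
  are right-skewed; ECDF comparison is not sign-invariant). Symmetric
  primitives fall back to making the largest-magnitude loading positive;
* every H row is rescaled to peak (max |·|) 1, the compensating scale folded
  into the matching W column. The reconstruction is invariant under this.
  Note this means PCA primitives are mutually *orthogonal* but not unit-norm
  in the returned H; orthonormality holds before the final rescale.

### Numerical choices

* **NMF** initialises W, H uniform in (0, 1] scaled by √(mean(x)/K), runs 10
  restarts (NMF is non-convex) and keeps the lowest final objective;
  denominators in the multiplicative updates are guarded with +1e-12. The
  objective is monotone non-increasing per iteration — asserted in tests.
  Early stop when the relative objective decrease falls below 1e-6.
* **ICA** whitens via SVD to K dimensions (singular values floored at
  √1e-12), uses the plain fourth-moment (kurtosis) contrast by default with
  log-cosh as an option, symmetric decorrelation via (BBᵀ)^{−1/2}B, and at
  most 500 iterations. Non-convergence emits a `RuntimeWarning` and returns
  the best-effort result flagged in `meta['converged']` — this happens
  routinely at K close to L where trailing whitened dimensions are nearly
  noise-free and the contrast has no gradient, and is harmless for
  reconstruction (VAF is still exact at K = L because whitening is
  invertible).
* **FA** is deliberately the plain eigen-decomposition flavour: no varimax
  rotation, no iterative communality refinement. Eigenvalues are floored at
  1e-12 so exactly low-rank covariance matrices are handled; factor scores
  use the regression method through the (pseudo-)inverse covariance. The
  eigenvalue-greater-than-1 rule (`kaiser_criterion_k`) is computed on the
  correlation matrix of standardised rows.

## VAF and the number of synergies

VAF is the global uncentred form 1 − Σ(x−x̂)²/Σx², summed over all L·N
entries (the common synergy-literature convention; a centred or per-muscle
variant would change the absolute numbers). The number of synergies is the
smallest K ∈ {2…6} at which *every* method exceeds 85% VAF; if none does,
the range maximum is returned with a warning.

## Distribution metrics

Each primitive's empirical CDF is compared with each muscle activation
pattern's ECDF via the two-sample Kolmogorov–Smirnov statistic
D = sup|F₁ − F₂|, evaluated over the pooled sample points (exact for step
functions). The p-value is the asymptotic Kolmogorov tail at effective
sample size n₁n₂/(n₁+n₂). Per primitive, D_k is the worst case over
muscles; D_max = max_k D_k is the maximum dissimilarity index. The
*occurrence of agreement* is the percentage of the L×K pairs whose test
fails to reject equality at α = 0.05.

Because two-sample KS is not invariant to an affine transform applied to
one sample only, primitives are min–max normalised to [0, 1] before
comparison (activations already live there); `primitive_prep='raw'`
disables this for sensitivity analysis, and `reduction='min'` provides a
best-matching-muscle variant for exploration. Under the null (primitive and
activation samples drawn from one distribution, n = 200) the agreement rate
sits at ≈ 95%, the nominal level — the asymptotic test is very slightly
conservative at this sample size (≈ 95.3% in 2000-replicate checks).

## Group statistics

Per condition, scores are averaged to subject means (subjects, not trials,
are the repeated units) and compared across methods with a classical
one-way repeated-measures ANOVA (no sphericity correction), followed by
Bonferroni-corrected paired t-tests (corrected p = min(1, m·p_raw)). The
design must be balanced. The fully degenerate case — zero variation between
methods — is reported as F = 0, p = 1 rather than the indeterminate 0/0 of
the F ratio.

## Synthetic data

### Raw trials

One gait cycle per trial; each of the 10 channels is
`envelope(t) · carrier(t)`, normalised to unit RMS:

* **carrier** — iid generalized Gaussian (GGD) with shape β, sampled by
  inverse CDF from per-channel uniform streams. β = 1 is Laplacian (excess
  kurtosis 3), β = 2 Gaussian (0); the family interpolates the documented
  transition of raw-EMG amplitude distributions from heavier-tailed walking
  to more Gaussian fast running.
* **envelope** — tonic baseline 0.5 plus 1–3 Gaussian bursts (sd 10–18% of
  the cycle, amplitude 0.7–1.1, centres uniform in cycle time). Lower-limb
  EMG has tonic background activity; the baseline also keeps the effective
  sample size of the kurtosis estimate reasonable (bare narrow bursts make
  pooled kurtosis both biased and extremely noisy at one-cycle lengths).

β is calibrated per channel so the trial's pooled *sample* excess kurtosis
hits the condition target (walk 1.75, slow run 1.45, moderate run 1.29,
fast run 1.10). Two facts make this nontrivial: (i) enveloping inflates
kurtosis by r = mean(e⁴)/mean(e²)², handled exactly through the closed-form
GGD moments; (ii) the pooled sample kurtosis m₄/m₂² is biased upward for
modulated signals because m₄ and m₂ share the same burst-dominated samples
— corrected with a second-order delta-method expansion of E[m₄/m₂²], solved
in two passes. Cycle durations (1.08/0.78/0.62/0.52 s at 1500 Hz) are
typical stride times at the four speeds.

Seeding: the master seed is split with `SeedSequence.spawn`, one child per
channel, so increasing the channel count appends channels without
reshuffling existing ones, and everything is bit-reproducible.

### Ground-truth synergy datasets

`generate_synergy_dataset` builds x = W_true·H_true + ε directly: H_true
rows are single Gaussian bursts (sd 4–6% of the cycle) spread over the
cycle, peak-normalised; W_true gives each muscle one dominant loading
(0.7–1.0) plus small cross-loadings (< 0.15); ε is Gaussian with the
requested sd, clipped at zero, and rows are peak-normalised to match the
preprocessing contract. The sharp, well-separated bursts make the three
components carry comparable energy, so the 85% VAF rule resolves K = 3
while K = 2 stays below threshold.

### What the generators do not emulate

No electrode placement or cross-talk, no motion artefact, no multiple
strides, no between-participant kurtosis spread (targets are the condition
means only), and envelope shapes are idealised Gaussian bursts. Two
consequences worth knowing:

* applying the K-selection rule to *preprocessed raw trials* (as
  `analysis/03_decompose.py` does) selects K = 2 — the tonic baseline makes
  two synergies sufficient at 85% uncentred VAF. The ground-truth datasets,
  built for factorisation validation, select K = 3.
* the occurrence of agreement on pipeline trials is low in absolute terms
  (the 200-point KS test has high power, and the idealised envelope
  distributions genuinely differ from primitive distributions); the method
  *ordering* — NMF lowest D_max — is the meaningful output. Passing tests
  therefore validate the machinery and relative behaviour, not the absolute
  agreement percentages one would see on real EMG.

## Preprocessing details

Filters are Butterworth order 4 in second-order sections, applied
forward–backward (`sosfiltfilt`, default reflective padding), so the
envelope has zero phase lag and the stated order refers to the designed
filter (attenuation doubles over the two passes). Band-pass 30–400 Hz
requires fs > 800 Hz. Envelope low-pass default 6 Hz, configurable (8 and
10 Hz are exercised in the robustness tests: pooled activation kurtosis
moves by < 0.15 across 6/8/10 Hz). Rectified envelopes are clipped at zero
against low-pass ringing. Time normalisation uses linear interpolation on a
uniform normalised-time grid; amplitude normalisation is per muscle by
default (`per_muscle=False` gives a single global trial peak). Dead
(all-zero) channels are left as zeros and logged, not treated as errors.

## Problem sizes

Defaults used in the drivers and validation: 10 channels at 1500 Hz, one
cycle per trial; the demo study is 4 conditions × 4 subjects × 5 trials;
validation sweeps use 20 seeds of 10×200 ground-truth datasets and
500-replicate KS-level checks. These sizes make every result in this
repository reproducible in minutes on a single core while keeping
Monte-Carlo error well inside the stated tolerances.
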