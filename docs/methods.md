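# Methods

## Model

The package treats a swimming cell's 2D heading angle Θ(t) as the sum of
two independent stochastic processes: rotational Brownian motion (Gaussian
increments of variance 2·D_rot·Δt over a lag Δt) and a shot-noise tumble
process (Poisson events at rate λ, each adding a signed angle ±|β| with the
magnitude drawn from a density P(|β|) on [0, π] and the sign fair). Speed
is irrelevant to the method and is held constant in the simulator. Tumbles
are instantaneous; data in which cells tumble for extended periods should
be removed upstream (the curvature filter exists for that purpose).

Two magnitude families are implemented:

* **Truncated gamma** γ(σ, k): gamma density restricted and renormalized to
  [0, π]; mode at (k−1)σ for k > 1; moments in closed form through the
  regularized lower incomplete gamma function,
  ⟨|β|ⁿ⟩ = σⁿ γinc(k+n, π/σ)/γinc(k, π/σ). Suited to run-and-tumble
  swimmers with broad mid-range turn angles.
* **Reversal family**: exp(−(π−|β|)/Δβ) plus a flat offset C, normalized on
  [0, π]; describes reversal-dominated swimmers. Moments have a closed form
  (binomial expansion into incomplete-gamma terms) that is validated in the
  tests against adaptive quadrature; quadrature is the normative
  definition.

All angles are radians internally; degrees appear only at the I/O surface.
Signed angular differences are reduced to (−π, π], turning magnitudes to
[0, π] via |α|_a = min(|α|, 2π − |α|).

## Conditional moments and their accuracy

The n-th absolute conditional moment m^n = ⟨|ΔΘ|_a^n⟩/Δt has closed forms
for n ∈ {1, 2, 3, 4, 6, 8} that are *leading order* in the two small
parameters λΔt (at most one tumble per lag) and D_rotΔt (thermal step small
against π). m² is exact in this expansion; m⁴, m⁶, m⁸ keep only terms
linear in D_rotΔt; the odd orders additionally assume the tumble angle
dominates the thermal step within a lag. The pure-Brownian part of the odd
moments uses the half-normal absolute moments
⟨|dB|^k⟩ = (2D_rotΔt)^{k/2}(k−1)!!·√(2/π) (odd k), with the integration
limit extended to infinity — accepted while 2·D_rotΔt < (π/4)²; a warning
is emitted beyond that.

Quantitatively (measured against sub-stepped Monte-Carlo simulation of the
full process): at λΔt ≈ 0.2, D_rotΔt ≈ 0.03 — e.g. λ = 0.39 s⁻¹ with the
conventional lag Δt = 0.5 s — the truncated terms bias the moments by −3%
(n = 1) to −16% (n = 8). Two mechanisms dominate: wrap-around of |ΔΘ| at π
(mass of P(|β|) near π reflected by the thermal step, scaling with
D_rotΔt), and O((λΔt)²) multi-tumble events whose wrapped two-angle sums are
not in the formulas. At λΔt ≤ 0.04 and D_rotΔt ≤ 1e−3 the residuals are
below ~0.5% for all orders; the Monte-Carlo/analytic equivalence check in
the test suite runs there (λ = 0.04 s⁻¹, D_rot = 0.001 rad²/s, Δt = 0.5 s,
10⁶ non-overlapping lag increments).

## Estimator

Headings are taken from single-frame displacements of the *raw* positions
(Savitzky–Golay smoothing is available but used only for the curvature
filter and the heuristic recognizer — smoothing rounds off the sharp
corners that carry the tumble signal and shifts the inferred angle
distribution toward smaller angles). Zero-displacement frames are flagged
invalid and excluded. The kernel-weighted estimator accumulates every frame
once as a left endpoint (all lag shifts); conditioning uses a Gaussian
kernel of width Δθ = 0.125π on the *wrapped* heading difference, so
conditioning near ±π is unbiased. Estimates whose effective kernel weight
Z_K falls below a floor (default 10) are flagged low-confidence.

Track filters (defaults for 20 Hz data, applied in order): trim 0.5 s from
each end; drop tracks longer than 10 s or with net displacement below
10 µm; drop the 20% of tracks with the highest median curvature (median of
|turn angle| per unit path length on smoothed tracks — the exact curvature
definition is a documented stand-in, the upstream literature does not print
one); require 3 s duration for CM eligibility.

## Fitting choices

* **Weights.** Residuals are relative (each scaled by the empirical
  moment): raw CMs span orders of magnitude across n and unweighted least
  squares would be dominated by m⁸.
* **Fit orders.** The fit uses n ∈ {1, 2, 3, 4} by default. The truncation
  error of the closed forms grows steeply with n (the n-th moment weights
  exactly the near-π region where the expansion fails), and a four-parameter
  family is flexible enough to absorb that deformation: on simulated data at
  Δt = 0.5 s, fitting all of {1,2,3,4,6,8} roughly triples the parameter
  bias (λ low by ~39% instead of ~15%) because the *global* least-squares
  optimum of the deformed moment vector sits far from the generating
  parameters, at a near-zero objective. Orders 6 and 8 remain central to
  the ratio diagnostic, where the deformation largely cancels.
* **Lag.** The default analysis lag is Δt = 0.5 s (every tenth frame at
  20 Hz) for real data, where the lag must also exceed the finite tumble
  duration. For synthetic validation, where tumbles are instantaneous, the
  recovery tests use Δt = 0.1 s (λΔt ≈ 0.04), keeping the leading-order
  truncation bias (~−3% on λ) well inside the tolerance; at Δt = 0.5 s even
  the best order subset carries a ~−15% λ bias and recovery at 10% is not
  attainable.
* **Optimization.** `scipy.optimize.least_squares` (trf, box bounds:
  λ ∈ [0, 1/Δt), D_rot ∈ [0, 10], σ ∈ (0, π], k ∈ (0, 20], Δβ ∈ (0, π],
  C ∈ [0, 10]) with multi-start on a coarse 3×3×3×3 grid; ties broken by
  objective then by lower λ. Warm starts are reused for per-angle and
  bootstrap refits.
* **Degeneracy.** σ and k trade off along a ridge of nearly constant mean
  angle; ⟨|β|⟩ is the robust combination and is what the profile reports.
  Across conditioning angles D_rot is held at the pooled estimate (thermal
  diffusion cannot depend on swimming direction); freeing it inflates the
  per-angle λ noise by ~1.5× through the λ–σ–k degeneracy.

## Chemotaxis analysis

The gradient convention is: gradient along −x, so θ = π is up-gradient.
`infer_vs_theta` fits per conditioning angle on a 16-point grid (spacing
π/8, matching the kernel width) and summarizes the rate profile by OLS of
λ(θ) on [1, cos θ]. The Gaussian kernel attenuates the first circular
harmonic by exactly exp(−Δθ²/2) ≈ 0.926; the reported a₂ is corrected by
that factor, so it estimates the true modulation amplitude (a₁, the mean
level, is unaffected).

The strategy diagnostic tabulates m̂ⁿ(θ)/m̂ⁿ(π) versus n. A pure rate bias
multiplies all orders equally (ratio flat at λ(θ)/λ(π)); a smaller mean
tumble angle up-gradient makes the ratio grow with n. The verdict is a
studentized trajectory bootstrap: slope of log-ratio versus n over
n ∈ {4…8}, called "angle bias" when slope/SE exceeds the one-sided normal
quantile at α = 0.025. This operating point was chosen over a plain
percentile interval because the percentile test is anti-conservative on
these heavy-tailed statistics (measured 10% false-positive rate versus ≤5%
required; the studentized version measures ~1% over 100 classical
ensembles at its default power setting of ~400 tracks × 10 s).

Parameter uncertainties use the trajectory bootstrap (resampling whole
tracks with replacement, rerunning the full estimation; deterministic given
the seed).

## Systematic tumble recognizer

With the inferred P(|β|) and thermal density N (folded normal of variance
2·D_rotΔt), the likelihood ratio R(dΘ) = 2N(dΘ)/P(|dΘ|) yields a
Neyman–Pearson test: tumble iff |ΔΘ|_a > dΘ_crit, where dΘ_crit is the α₁
quantile of P. The type-II error α₂ is the folded-normal mass between
dΘ_crit and π (mass beyond π is ignored; negligible for D_rotΔt ≪ 1). Ties
at the threshold are classified as runs. At the standard operating point —
γ(0.64, 2.73), α₁ = 0.05, Δt = 0.5 s, D_rot = 0.05 rad²/s — this gives
dΘ_crit = 24°, r_crit = 2.3, α₂ = 0.06. The D_rot here is the lower edge of
the inferred 0.06 ± 0.01 rad²/s band: only that edge reproduces the
operating point consistently (0.06 rad²/s would give α₂ ≈ 0.09).

The heuristic recognizer (comparison baseline) subsamples to every third
frame, smooths with a 5-point second-order Savitzky–Golay filter, and marks
local speed minima below a fraction (default 0.5) of the track's median
speed or turn-rate maxima above a threshold (default 3 rad/s). Both
thresholds are configuration knobs tuned on injected-event fixtures, not
model quantities.

## What the simulator does and does not emulate

The simulator draws per-frame Bernoulli tumbles (probability Δt_frame·λ(θ),
with λ(θ) = λ₀ + a₂cos θ evaluated at the instantaneous heading), adds
per-frame Gaussian rotational noise, and advances positions at constant
speed (default 20 µm/s, 20 Hz frames). Angle bias modulates the scale
parameter of the gamma family by (1 + amp·cos θ). A gamma run-time mode
(shape s, mean matched to 1/λ₀) probes robustness to non-exponential runs.
Ensembles are bit-reproducible given the seed.

Not emulated: localization noise on positions, finite tumble duration,
speed fluctuations, cell-to-cell parameter variability, track
fragmentation and out-of-focus loss, and memory in the chemotactic
response (the rate responds to the instantaneous heading only). Passing
the validation suite therefore demonstrates correctness of the estimator
chain on the model's own terms — not that real-data biases from these
effects are small. On real tracks the finite tumble duration forces a
larger lag (hence the 0.5 s default), which re-introduces the truncation
biases quantified above; inferred absolute rates at such lags should be
read with a ~10–15% systematic allowance, while comparisons across
conditions (the chemotactic modulation) are much less affected.

## Known limitations

* The closed-form CMs are first order in λΔt and D_rotΔt; all quantitative
  statements above about their bias at the conventional lag follow from
  the package's own Monte-Carlo measurements.
* With very large ensembles (~10⁴ tracks) the strategy verdict resolves a
  small positive log-ratio slope (~+0.013 per order at Δt = 0.5 s) on pure
  rate-bias data — wrapped two-tumble sums inflate high moments slightly
  more where λ is larger. The verdict is calibrated at its default power
  setting; at much higher statistics, shorten the lag or read the slope
  magnitude rather than its significance.
* The angle-only recognizer cannot see zero-angle "stopping" events; a
  speed-aware extension is out of scope.
* The reversal family supports no angle-bias modulation (no mechanism is
  established for reversal swimmers).
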