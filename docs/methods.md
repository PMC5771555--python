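# Methods

This note documents the models, numerical choices and known limitations of
`canopyflow`. Units throughout: velocities m s⁻¹, elevations cmab
(centimetres above the seabed), angles degrees, dissipation m² s⁻³.

## ADV burst model and synthesis

A burst is a 25 Hz, 4-minute record of the velocity triplet (u, v, w) at one
elevation, with u streamwise, v transverse, and w positive away from the
seabed. The generator builds each fluctuating component by random-phase
spectral synthesis against the inertial-subrange model

E_u(k) = E_v(k) = (9/55) α₁ ε^{2/3} k^{-5/3},  E_w(k) = (4/3) E_u(k),  α₁ = 1.5,

mapped to frequency at the prescribed advection speed U (k = 2πf/U,
E(f) = E(k)·2π/U) and truncated to zero below `spectrum_floor_hz`
(default 0.1 Hz) so that turbulence and any low-frequency wave oscillation
remain separable across the decomposition cutoff. Spectral amplitudes are
set deterministically from the model (so the realized variance equals the
band integral exactly, by Parseval) and phases are i.i.d. uniform per bin
and component. On top of the turbulence the generator adds, in order: the
mean current and an optional wave-band sinusoid on u; white instrument
noise per component; isolated single-sample spikes of ±`spike_amplitude`
fluctuation SDs at recorded indices; and finally a rigid rotation of the
whole triplet by the misalignment angles.

Two generator properties matter for testing:

* The transverse/vertical pair is exactly orthogonalized (a principal-axis
  roll removes the sampling covariance of v′ and w′) before the
  misalignment is applied, so the aligned frame is an *exact* ground truth
  and angle-recovery tolerances of hundredths of a degree are meaningful.
* The misalignment rotation is built as the inverse composition of the
  streamline rotation, so the estimated streamline angles equal the negated
  misalignment angles to machine precision on noise-free bursts.

Default study conditions: ε = 1e-5 m² s⁻³ and U = 0.2 m s⁻¹ (a typical
tidal sand-flat current), giving w′ SD ≈ 1 cm s⁻¹. The white-noise SDs
default to (2, 2, 0.5) mm s⁻¹ — ADV geometry gives the vertical beam a
noise floor several times below the horizontals — and spikes default to
0.5% of samples at 8σ. These defaults were fixed once as field-realistic
values and are fully configurable.

What the generator does **not** emulate: spatially structured canopy
wakes, wave–turbulence interaction, anisotropy beyond the 4/3 factor,
correlated multi-sample spike bursts, or velocity-dependent noise. Passing
recovery tests therefore demonstrate the correctness of the processing
chain under the stated stochastic model, not robustness to every field
pathology.

## Mean/fluctuation decomposition

The time-varying mean of each component is its zero-phase low-pass
(4th-order Butterworth, forward–backward via `sosfiltfilt`) at a
configurable cutoff, default 0.1 Hz — below the turbulence band at these
Reynolds numbers, above tidal/wave motion. The fluctuation is defined as
the residual, so mean + fluctuation reconstructs the input to a rounding
ulp, and zero-phase filtering guarantees no phase shift between the two
parts. Bursts shorter than ten filter time constants (10/(2π·cutoff)
seconds) are rejected.

Because the synthesis floor and the decomposition cutoff coincide at
0.1 Hz by default, a few percent of synthesized turbulent variance near the
cutoff is absorbed into the mean series; tests that predict the fluctuation
variance account for the filter's high-pass power response (1 − |H|²)².

## Despiking

Spikes are detected with phase-space thresholding on each fluctuating
series: build (x, Δx, Δ²x) with central differences, estimate a robust SD
per axis (MAD × 1.4826, immune to the spikes themselves), and flag points
outside the ellipse with semi-axes λ·SD in any of the three 2-d
projections, λ = √(2 ln n) (the x–Δ²x projection is rotated by its
principal angle). Flagged points are replaced by linear interpolation
across good neighbours (nearest good value at the edges) and the
detect/replace cycle iterates until no new spikes appear or the good-point
count is constant.

Two refinements are this package's own:

* **Attribution re-validation.** The central-difference coordinates of a
  point do not depend on the point's own value, so a large spike casts
  collateral flags onto its good neighbours, and a good sample sitting
  between two sharply differing neighbours can violate the threshold no
  matter what value it holds. After convergence, each flagged sample is
  kept only if its raw amplitude alone exceeds λ·SD or if restoring it into
  the cleaned series creates a violation the cleaned series does not
  already have; otherwise it is restored and exempted. This cuts the
  false-positive rate by an order of magnitude (measured ≲0.05% at 1%
  spike contamination) without costing sensitivity, since any sample ≥6σ
  is convicted by amplitude alone.
* **Idempotence by construction.** Detection and re-validation alternate to
  a fixpoint, and the detector is then re-run on the cleaned output,
  absorbing residual borderline flags, until a second full pass would flag
  nothing. The loop terminates because each sample can be flagged and
  exempted at most once per pass (a hard iteration guard backs this up).

With the ellipse criterion the false-flag rate on clean Gaussian data is
~3 points per series irrespective of n — each projection has 2-d tail mass
P(χ²₂ > 2 ln n) = 1/n — which is well inside the 0.5% false-positive
budget.

## Streamline rotation

Three plane rotations align the frame with the flow: θ_xy zeroes the
burst-mean transverse velocity, θ_xz then zeroes the burst-mean vertical
velocity, and a roll about the streamwise axis,
θ_cross = ½·atan2(2·cov(v,w), var v − var w) wrapped into (−45°, 45°],
zeroes the v′w′ covariance. A literal third rotation "in the x–z plane"
cannot zero v′w′ in general, so the covariance-zeroing roll is implemented;
the wrap picks the solution nearest zero rather than the axis-swapping
alternative 90° away. Angles and covariance are computed from
burst-demeaned totals (mean series + fluctuations): a static rotation
commutes with the linear low-pass filter, so this makes the post-rotation
contract (v̄, w̄, v′w′ all ≤ 1e-10) exact rather than approximate, and on
noise-free synthetic bursts the misalignment recovery is exact to machine
precision.

Following the assumption that the flow is two-dimensional well above the
bed, profile processing estimates the angles only at the two highest
elevations, averages them arithmetically per angle (angles are small, no
wraparound), and applies the averaged rotation to every elevation of the
profile (rigid sensor frame). Bursts with mean horizontal speed below a
configurable floor (default 0.1 mm s⁻¹) are rejected as directionally
indeterminate.

## Spectra and dissipation

Spectra are Welch estimates: Hann-tapered segments of 2¹⁰ samples with 50%
overlap, constant detrend, one-sided, zero-frequency bin dropped. At 25 Hz
this resolves ~0.024–12.5 Hz, bracketing the inertial band at U ≈ 0.2 m s⁻¹.
The Taylor conversion k = 2πf/U, E(k) = E(f)·U/(2π) preserves the
integrated variance exactly (linear change of variables, bin by bin).

**Parseval caveat.** The Welch integral equals the sample variance in
expectation, and to well under 1% per realization for broadband series.
For the strongly red k^{-5/3} burst spectrum, however, roughly half the
variance is carried by the ~15 lowest resolvable Fourier modes, and the
integral of any segment-averaged estimate scatters around the per-burst
sample variance by several percent (measured ±4–8% across seeds, unbiased:
mean ratio 0.997 over 300 bursts). This is sampling scatter of the
estimator, not an energy-accounting error, and no segment length, taper or
overlap removes it at 4-minute burst length; the test suite asserts the 1%
equality per realization on long broadband series and in expectation over
burst realizations.

Dissipation is estimated from the vertical component (lowest noise floor)
by the compensated average over the fit band:
ε = (mean[E_w(k)·k^{5/3}] / C_w)^{3/2} with C_w = (4/3)(9/55)α₁. The
compensated mean is unbiased under multiplicative spectral scatter, unlike
a log-log regression, whose slope is still reported as a diagnostic
together with the RMS log-residual of the −5/3 line. The default fit band
is 1–8 Hz mapped to wavenumber at the burst's advection speed — above the
wave band, below the noise-floor flattening and the top octave near
Nyquist — and is configurable and recorded in every estimate. An optional
constant noise-floor subtraction (estimated from the top decile of
wavenumbers) is available but off by default. With the default vertical
noise floor, the residual upward bias at the smallest study dissipation
(1e-6 m² s⁻³) is ~10%, well inside the ±30% recovery target; at 1e-5 and
above it is negligible.

## Count tables and GLMs

The count generator mirrors the camera design: `n_asu` replicate ASUs
(default 10), each filmed once from four positions (down-current 1 m,
down-current edge, up-current edge, up-current 1 m) for
`minutes_per_deployment` observed minutes (default 23, one scored minute
per ten of footage over ~4 h), tide direction fixed per deployment
(default 6 flood / 4 ebb). Per series, a latent AR(1) term (marginal SD
`sigma_ar`, default 0.4; coefficient `phi_ar`, default 0.6) enters the
log-intensity along with position and tide effects; abundance is a
gamma-mixed Poisson with variance = dispersion × mean (the quasi-Poisson
variance function; default dispersion 2), and the water-column count is
binomial out of abundance with logit-linear position and tide effects.
`sigma_ar` is a generator parameter the design needed but the field list
above does not pin down; the default was chosen so count autocorrelation
decays into the white-noise band around lag 4–5, matching the thinning
behaviour of the field data. Default effect directions (abundance highest
down-current, water-column proportion highest up-current and on flood)
follow the observed field pattern at moderate sizes.

The thinning rule returns L + 1 for the smallest lag L whose sample ACF at
L and every in-range multiple of L lies inside ±1.96/√n; thinning retains
group positions 0, L+1, 2(L+1), … of each time-ordered (ASU, position)
series (offset 0, configurable). Records failing the visibility screen are
dropped before thinning. Note that for any series with nonzero short-lag
correlation the white-noise band undercovers the sample ACF at the
"clean" lags (Bartlett inflation), so on stochastic inputs the selected
interval is itself a random variable; the rule is exact on the ACF it is
given.

Exploratory velocity relationships use a single global quadratic through
the conditional median (check-loss minimization via iteratively reweighted
least squares); no interior knots are used by default, as the simplest
curve consistent with a "second-order polynomial through the 50th
percentile".

The abundance model is a Poisson-family GLM read as quasi-Poisson:
dispersion φ̂ = Pearson χ²/df of the full model, coefficient SEs scaled by
√φ̂, and term tests from the analysis of deviance as F = (Δdev/Δdf)/φ̂ on
(Δdf, residual df). The proportion model is a two-column binomial GLM
(rows with zero abundance carry no information and are dropped; extreme
logit coefficients raise a separation warning) with χ² = Δdev term tests.
Terms are tested sequentially (tide, then position, then interaction) by
default; marginal (Type III) tests — each term's columns dropped from the
full sum-to-zero-coded design — are available via `tests="marginal"`. The
interaction is always retained and its p-value reported.

Tukey HSD contrasts are computed on the linear-predictor scale between
equally weighted cell means (each level's design row averages the full
factorial grid at that level), with adjusted p-values from the studentized
range distribution, q = √2·|t|, k levels, residual df (a two-level factor
reduces to an ordinary two-sided t test). Simulation checks show the
family-wise error under the null is controlled at ~5% and both term tests
are calibrated (type-I error within [0.025, 0.075] at study-like n).

## Problem sizes used in the checks

The packaged checks run at the study's native burst geometry (25 Hz ×
240 s; 20 seeds per dissipation decade), 500 null simulations for GLM
calibration at 10 ASUs × 4 positions × 5 retained minutes, 300 bursts for
the expectation-level Parseval check, and 150–200 replicates for power and
family-wise-error simulations — sizes chosen to make Monte-Carlo error
comfortably smaller than the tolerance being asserted.

## Known limitations

* No correlation/SNR-based ADV quality screening, wave–turbulence
  cospectral separation, structure-function ε estimators, or anisotropy
  corrections beyond the 4/3 factor.
* The quasi-Poisson/binomial GLMs treat thinned records as independent;
  no mixed-effects or GEE alternative is provided, so residual
  within-deployment correlation beyond what thinning removes inflates the
  nominal test levels.
* The deposited-data reader is mapping-driven because field layouts vary;
  it validates labels and count consistency but cannot guess column
  semantics.
* Taylor's hypothesis degrades as turbulence intensity approaches the mean
  speed; the generator and estimator both assume u′/U ≪ 1.
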