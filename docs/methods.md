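# Methods

This note documents the models, numerical choices and limitations of
phasorca in one place.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Sensor model

The calcium sensor is treated as a two-state system: a calcium-free state
with unquenched donor lifetime τ_free and a calcium-saturated, fully
FRET-quenched state with lifetime τ_FRET.  Binding is summarized by an
effective Hill equilibrium; the microscopic four-site binding of the
troponin C linker is deliberately *not* modelled — K_d and the Hill slope
are apparent constants of the lifetime titration, which is how they were
measured.  The titration sigmoid and its closed-form inverse are

    τ(c) = τ_FRET + (τ_free − τ_FRET) / (1 + 10^(−(log₁₀ c − log₁₀ K_d)·h)),
    log₁₀ c = log₁₀ K_d − log₁₀((τ_free − τ_FRET)/(τ − τ_FRET) − 1) / h,

with defaults K_d = 475 nM, h = −1.43, τ_free = 2312 ps, τ_FRET = 744 ps.
Inversion of lifetimes at or beyond the endpoints returns 0 nM / ∞ with a
saturation flag rather than raising: saturated pixels are data, not errors.

Donor lifetime also depends weakly on refractive index, pH, ionic strength
and temperature; these are assumed constant between calibration and
measurement (cytosolic conditions) and are not corrected for.

## Phasor transform

Per decay, g = Σc·cos(ωt)/Σc and s = Σc·sin(ωt)/Σc at
ω = 2π·harmonic·f_rep, bin centers t_k = (k + ½)·Δt, time zero at the first
bin edge.  ω uses the laser repetition rate (12.5 ns period at 80 MHz), not
the 12.375 ns acquisition window; the ≤0.5% truncation bias from the
unobserved sliver of the period cancels between calibration and measurement
because both use identical binning, so no sinc/discretization or IRF
correction is applied.  Under periodic excitation the wrapped
monoexponential decay stays proportional to exp(−t/τ) within the period, so
the discrete phasor matches the continuous closed form
g = 1/(1+(ωτ)²), s = ωτ/(1+(ωτ)²) — to better than 1% per coordinate for
τ ≤ 3 ns and within 0.01 absolute out to 5 ns, where window truncation
becomes visible.  Lifetimes read off a phasor (τ = s/(gω)) are flagged
unreliable beyond 0.05 from the semicircle.

## Calibration

**Time domain.**  Monoexponential fits F(t) = y₀ + A·exp(−t/τ) use
Levenberg–Marquardt least squares, initialized by log-linear regression of
the background-subtracted tail.  The fit is unweighted by default (Poisson
weighting behind a flag); degenerate results (τ ≤ 0 or τ > 5× the window)
are flagged non-converged, never clamped.  At realistic photon budgets
(10⁶) the lifetime is determined to <1%, but a small uniform background
(~5 counts/bin) trades off strongly against the decay tail and is only
determined as an average over repeats — tests check its unbiasedness, not
single-fit precision.  The Hill fit fixes τ_free/τ_FRET from the 0 nM and
saturating anchors and estimates only (K_d, h) from the intermediate
levels, which stabilizes the two-parameter problem; standard errors come
from the fit covariance (delta method for K_d).

**Phase domain.**  Endpoints p_free/p_FRET are the mean (or median,
selectable; distributions are symmetric) of the noise-gated anchor clouds;
endpoint clouds closer than 3× their spread raise an error.  The relative
donor brightness of the two states is ε_free/ε_FRET = τ_free/τ_FRET (equal
radiative rates and absorption cross sections — the common prefactors
cancel in every inversion).  Three phasor→calcium inversions are provided:

- **empirical** (default): a Hill curve is fitted to the segment fraction
  w (orthogonal projection onto p_free→p_FRET, clamped to [0, 1]) versus
  the titration concentrations, then inverted.  This calibrates the phasor
  axis against the *same* titration as the time-domain sigmoid and is the
  only mode under which the two pathways agree to a few percent across the
  linear range.
- **literal_eq11**: c = K_d·(ε_free/ε_FRET)·|p − p_free|/|p_FRET − p| — the
  distance-ratio formula kept verbatim.  It is consistent with the sigmoid
  only for h = −1 and is retained for fidelity and comparison.
- **hill_generalized**: c = K_d·[(ε_free/ε_FRET)·d_free/d_FRET]^(−1/h),
  which reduces to the literal formula at h = −1.

All modes are strictly increasing along the segment (property-tested).
Concentrations are reported unclamped with flags: outside the dynamic range
(100 nM – 4 µM, kept as configuration constants; their defining saturation
convention is not derivable from the other calibration numbers) and outside
the linear range.  The linear range is defined as the concentrations at
30%/70% sensor saturation, c = K_d·(f/(1−f))^(1/|h|), which reproduces the
published 265/857 nM from the published constants to ~1%; the 30/70%
convention is an inference documented here.  The noise-gate radius is
0.75·FWHM of Gaussian fits to the g/s marginals of a pure-noise
measurement (0.3 by default); exclusion is the open disk |p| < r.

**Cross-pathway validation** inverts each decay through both pathways and
reports the maximum relative deviation.  Decays that invert outside the
dynamic range (anchors, gated phasors) carry no comparable concentration
and are excluded.  When both calibrations are built from one simulated
titration, the deviation across the linear range is a few percent; a ~1.6%
structural floor remains because the Hill form only approximates the
apparent-lifetime curve of monoexponentially fitted mixtures.

## Image quantification

FLIM stacks are (row, col, time-bin) count arrays, row-major, origin
top-left; masks use 0 = background, labels ≥ 1.  Pixels below the photon
threshold (default 50; the choice balances shot-noise-limited pixel phasors
against coverage) are reported `low_photon`, gated pixels `gated`; both
carry no concentration.  Objects are quantified from the **summed member
histogram** — equivalently the photon-weighted mean of member-pixel phasors
(identical by linearity, asserted to 1e-9 in tests) — because phasors, not
concentrations, combine linearly.  All member photons are aggregated
regardless of per-pixel gating; the gate is then applied at object level.
Track tables join records by (frame, label); missing frames are explicit
gaps, never interpolated.

Uniform detector background mixed into member pixels pulls object phasors
toward the origin and biases concentrations low by roughly the background
photon fraction amplified through the segment geometry; no background
subtraction is applied (the gate only removes background-*dominated*
pixels).  Quantitative work should keep the in-object background fraction
below a few percent.

## Ratiometric traces and colocalization

R is either the simple acceptor/donor ratio ch2/ch1 (in vitro confocal
convention) or the spectral-overlap-corrected percentage
1.2·ch2/(2.7·ch1 + 2.5·ch2)·100 (two-photon in vivo convention, bounded in
(0, 48]); the baseline mode must be chosen explicitly per dataset
(pre-stimulus mean or trace minimum).  A cell is a responder when max ΔR/R
≥ 20%.  The correction coefficients fold in measured bleed-through
(0.52/0.48) and detector sensitivities (0.37/0.40) and are stored as
configurable constants — their algebraic derivation is not reproduced here.

Colocalization histograms (bin width 20 AU) are fitted with
f(x) = a₁·e^(−x/λ₁) + a₂·e^(−x/λ₂) (nonnegativity-bounded least squares,
two-stage log-linear initialization); the contact threshold is the smallest
x with f(x)/f(0) ≤ 10%, found by bracketed root-finding on [0, 10·max λ].
The 10%-of-f(0) reading of the decay criterion is a documented choice.
Contact classes: < 1 AU none, 1–150 AU transient (inclusive), > 150 strong;
the upper bound may be replaced by the fitted threshold.

## Synthetic data

The generator emulates the acquisition geometry (80 MHz, 55 ps bins, 225
bins) in the periodic steady state, with exact per-bin integrals of the
wrapped exponential, Poisson photon noise, optional uniform background and
an optional circular Gaussian IRF (FWHM 80 ps).  The IRF is centered at the
wrap point by default: a symmetric center leaves the phasor phase untouched
(pure demodulation < 0.1%), consistent with an analysis that applies no IRF
correction; the center is configurable for asymmetric-IRF studies.  Whether
a real instrument response is better modelled as Gaussian or exponential is
left open; the width is configurable.

Two decay modes: `monoexp` emits a single apparent lifetime τ(c) — the
time-domain titration's model — and `biexp` emits the two-species mixture
whose FRET intensity fraction w(c) = (c/K_d)^|h| / (1 + (c/K_d)^|h|) makes
the intensity-weighted mean lifetime follow the sigmoid exactly (the
species-concentration weighting of the mixture rule is absorbed into the
apparent constants).  Titration anchors emit the *pure* endpoint states,
matching their operational definition; the generic simulator keeps the Hill
fraction at any finite concentration (w(39 µM) = 0.998).

Image scenes are disjoint ellipses with uniform per-cell photon budgets
(defaults 10⁵–10⁶ photons/object keep shot-noise-limited concentration
errors within the test tolerances) over a uniform background.  Not
emulated: optical blur, depth-dependent scattering, cell motion and
deformation, autofluorescence spectra, multiexponential donor photophysics
beyond two states.  Passing tests therefore demonstrate correctness of the
transforms, calibrations and inversions under the stated noise model — not
robustness to the full complexity of intravital data.

## Problem sizes

Test and acceptance runs use 13-level titrations (11 log-spaced levels,
50 nM–10 µM, plus anchors) at 10⁶ photons per decay with 60 replicates per
level for phasor clouds; 20 fresh cross-validation decays log-spaced over
the linear range; 64×64-pixel scenes with ~2·10⁵ photons per cell; and
6869-object colocalization histograms.  These sizes were chosen so every
statistical tolerance is met with margin while the whole suite runs in
seconds on one CPU.
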