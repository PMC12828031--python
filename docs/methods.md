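# Methods

This note documents the models, conventions and numerical choices behind
`cascadeflim`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Measurement model

TCSPC under pulsed excitation bins photon arrival times over one repetition
period T. Defaults: T = 12.5 ns (80 MHz Ti:Sapphire excitation) and 256
bins (typical TCSPC ADC resolution); both are configurable. Because
lifetimes of ~4 ns are a large fraction of T, the decay does not complete
between pulses; the simulator and the fitter both use the period-wrapped,
bin-integrated model

    E[counts in bin k]  ∝  (e^{−t_k/τ} − e^{−t_{k+1}/τ}) / (1 − e^{−T/τ})

summed over components, which conserves the photon budget exactly for any
τ/T. Ignoring wrap-around would bias tail fits of long lifetimes low.

The instrument response (IRF) is modelled as a Gaussian of configurable σ,
default 0 (no published IRF to match). When σ > 0 the wrapped decay is
convolved circularly on a 10× oversampled grid and re-binned. Background is
uniform (counts/bin); detector afterpulsing, pile-up and spectral
bleed-through are out of scope.

## Decay fitting

Model: wrapped mono- or bi-exponential plus constant baseline, over a fit
window; bounded Levenberg–Marquardt (lmfit), lifetimes constrained to
[0.05, 20] ns. The window defaults to a tail fit from (peak bin + 2),
avoiding explicit IRF deconvolution; declaring an IRF σ switches to
reconvolution fitting. Initialisation: τ from the log-linear tail slope
(bi-exponential: ×0.5 and ×1.5), amplitudes from a non-negative linear
solve; a small set of perturbed restarts guards against local minima and
the best final objective wins.

Objective. Two choices are exposed:

- `"mle"` (default) — Poisson maximum likelihood, implemented as least
  squares on signed square-root deviance residuals. On simulated data this
  is unbiased to within ~0.1% down to 2×10⁴ photons per decay.
- `"neyman"` — classic weighted least squares with observed-count variances
  max(counts, 1). Retained for comparability with legacy TCSPC packages,
  but measurably biased low (≈ −0.3% at 10⁵ photons, ≈ −1.7% at 2×10⁴)
  because downward-fluctuating bins receive the largest weights.

Baseline handling. With zero true background, a free non-negative baseline
can only trade against the slowly varying wrapped tail and one-sidedly
biases τ low (≈ −0.2 to −0.5% depending on budget). Default `"auto"`
therefore fits both variants and keeps the baseline only when a
likelihood-ratio test at the 1% level supports it; the baseline can also be
forced on or off.

Goodness of fit is reported as the Neyman reduced chi-square (weighted
residual sum over bins minus parameters), which concentrates near 1 on
correctly specified simulations.

Mean lifetimes: per-pixel values are intensity-weighted, Σaᵢτᵢ²/Σaᵢτᵢ with
pre-exponential amplitudes aᵢ (equal to τ₁ for mono-exponential fits);
cells average their pixels weighted by photon count; conditions average
their cells with equal weights (mean ± SEM). Pixels under 300 photons
(configurable) are fitted on their 3×3 neighbourhood sum, the usual
low-count FLIM convention. Model order (1 vs 2 components) is
caller-specified, never automatic.

## Cascade rate algebra

Rates live in ns⁻¹ internally; s⁻¹ appears only in output tables (explicit
unit suffixes such as `rate_per_s`, `tau_ns`, `F_pN` avoid ambiguity). A
transfer rate that comes out negative (τ_DA > τ_D, possible in noisy
per-cell data) clamps to 0 with a warning rather than erroring. Efficiency
aggregation order matters slightly — efficiencies computed from mean
lifetimes differ from per-cell-averaged efficiencies by a few tenths of a
percentage point — and both orders are available, per-cell-first being the
pipeline default. The reciprocal of a transfer rate is reported as a
"transfer time", not a physical fluorescence lifetime.

Förster radii are configuration data keyed by pair name (κ² = 2/3 is
carried as metadata only; no spectral-overlap computation). The bystander
correction subtracts a known third-fluorophore transfer rate from a total
decay rate before converting to efficiency/separation; a remainder below 0
clamps with a warning, and a total rate below the intrinsic rate is an
error.

## Geometry

Three points are always coplanar, so the triangle is planar by
construction; angles come from the law of cosines with an exact 180°
closure normalisation. Separations are treated as chromophore-to-chromophore
point distances (barrel radii are not added). A triangle-inequality
violation — expected when FRET distances are noisy — raises an error naming
the offending side; collinear inputs yield a flagged degenerate triangle.
Reference coordinates for comparison (e.g. structural-model barrel
centroids) are user-supplied.

## Force mapping

The linker calibration coefficient is 0.01196·N + 0.0001255 with N the
number of linker residues; at N = 40 this is 0.4785. The calibration
equation is implemented multiplicatively as printed,
⟨F⟩ = (⟨R_TS⟩ − ⟨R_TL⟩)·coefficient, although the same value is described
in the literature as a *compliance* in nm·pN⁻¹, which would imply division;
the two conventions are not reconcilable from the published wording, so
both are exposed (`force_model="printed"` default, `"compliance"`
alternative). Both directions of the pipeline (scene generation and force
mapping) use the same convention, so round trips are self-consistent under
either. ⟨R_TL⟩ is always measured from a TL-condition analysis through the
same chain, never hard-coded.

Per-pixel chain: lifetime → total rate → optional bystander subtraction →
efficiency → separation → force. Pixels with no remaining FRET map to a NaN
sentinel and are excluded from histograms; negative forces (compression is
not modelled) clamp to 0 and are counted. Per-pixel force histograms use
mono-exponential lifetimes by default.

Bimodal fits minimise least squares of A₁e^{−(x−x₁)²/2σ₁²} +
A₂e^{−(x−x₂)²/2σ₂²} against the Freedman–Diaconis-binned density (density,
not counts, so the bin choice is second-order). Multi-start initialisation:
25th/75th quantile pair, a 1-D two-means split, and a perturbed single
Gaussian; best residual wins. Components are ordered by mean (ties: smaller
σ first); a single-Gaussian fit is reported alongside, and fits whose
components coincide or where one carries <5% of the area are flagged
effectively unimodal. Published bimodal amplitudes are of unnormalised
Gaussians and do not sum to 1; where occupancy weights are needed (mixture
sampling) they are taken proportional to component area A·σ — a documented
convention, not something the published parameters determine.

## Synthetic data

The generator emulates: multi-exponential photon kinetics with Poisson shot
noise at stated photon budgets; wrap-around; optional Gaussian IRF; FLIM
scenes with elliptical focal-adhesion-like patches near the cell border on
a dim (5% photon budget) cytoplasm background; and two-population tension
mixtures using the published vincTS parameters (`VINCTS_FORCE_BIMODAL`) with
negative draws rejected and resampled (forces are tensile). Per-pixel
random streams are split counter-style from one root seed
(`SeedSequence` spawn keys on pixel coordinates), so identical seeds give
bit-identical scenes and changing the image size never reshuffles an
unrelated pixel.

The tension-sensor donor pair of the scenes is synthetic but
field-realistic (mTFP1–mVenus: τ_D = 3.2 ns, R₀ = 6.0 nm, R_TL = 4.2 nm);
these values are not published measurements. Under the printed
(multiplicative) calibration, 3 pN implies ΔR ≈ 6.27 nm, which pushes the
TL-equivalent lifetime to ~0.34 ns; the defaults were chosen once so that
both TS and TL lifetimes remain resolvable at 256 bins over 12.5 ns.

What passing tests show — and don't. Round-trip recovery demonstrates that
the analysis chain exactly inverts the generative model and is robust to
shot noise at the stated budgets. It does not validate the model against
real instruments: no IRF mismatch, detector artefacts, autofluorescence,
spectral bleed-through, acceptor photophysics or cell-to-cell biological
variability are simulated, and published per-cell FRET efficiencies from
live-cell experiments are not reproducible without the raw data.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script:
scenes of 24–28 px squared (~150–250 adhesion pixels) at 10⁵
photons/pixel; bulk decays at 10⁵–10⁶ photons; bimodal recovery at 10⁴
draws × 25 seeds. These sizes were chosen as the smallest at which the
statistical claims (bias, round-trip tolerance) are meaningfully testable.

## Known limitations

- No phasor analysis, global multi-pixel fitting, or reproduction of any
  specific legacy software's numerics.
- No traction-force microscopy, substrate-stiffness modelling, or
  per-adhesion segmentation/tracking.
- Mono/bi-exponential models only; no stretched or distributed lifetimes.
- The compliance-vs-coefficient ambiguity of the force calibration is
  exposed, not resolved.
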