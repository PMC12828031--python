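"""Simulate a TCSPC decay histogram and fit its lifetime back.

The simulator draws Poisson photon counts from a period-wrapped exponential
decay under 80 MHz excitation (12.5 ns period, 256 bins); the fitter runs a
bounded Levenberg-Marquardt tail fit with a Poisson likelihood objective.
"""

from cascadeflim import KineticsSpec, fit_decay, simulate_decay

spec = KineticsSpec.mono(4.178)  # a long-lived cyan donor
hist = simulate_decay(spec, total_photons=1e6, seed=42)
fit = fit_decay(hist)

print(f"simulated {hist.total_counts:.0f} photons over {hist.n_bins} bins")
print(f"fitted lifetime {fit.tau_intensity_weighted:.4f} ns (truth 4.1780 ns)")
print(f"reduced chi-square {fit.chi2_per_dof:.3f}")
# chi2/dof near 1 says the Poisson noise model describes the residuals;
# the lifetime should land within ~0.3% of truth at this photon budget.
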