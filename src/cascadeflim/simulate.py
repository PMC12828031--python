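"""Synthetic TCSPC data: decay histograms, cascade ensembles and FLIM tension
scenes with known ground truth.

The generator emulates the measurement model of a multiphoton TCSPC-FLIM
system: 80 MHz pulsed excitation (12.5 ns repetition period), photon arrivals
binned over one period (256 bins by default), incomplete-decay wrap-around
from preceding pulses, optional Gaussian instrument response, uniform
background, and Poisson shot noise at a stated photon budget.

Tension scenes draw per-pixel ground-truth forces from a two-Gaussian mixture
(as fitted to tension-sensor force histograms), invert the exact force ->
separation -> transfer-rate -> lifetime chain of the force-mapping module, and
emit a per-pixel decay stack.  Per-pixel random streams are derived from the
root seed by counter-based splitting (``SeedSequence`` spawn keys), so a
change of image size never reshuffles unrelated pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import cascade as _cascade
from .cascade import FluorophorePair
from .decay import DecayHistogram, bin_edges, expected_bin_fractions
from .errors import ConfigurationError, InvalidParameterError
from .forces import ForceCalibration, area_weights, lifetime_from_force

__all__ = [
    "KineticsSpec",
    "TensionScene",
    "simulate_decay",
    "simulate_cascade_ensemble",
    "simulate_tension_scene",
    "make_adhesion_mask",
]

DEFAULT_PERIOD_NS = 12.5  # 80 MHz repetition rate
DEFAULT_N_BINS = 256  # typical TCSPC ADC resolution

# Published two-population Gaussian fit parameters of vinculin tension-sensor
# (vincTS) force histograms: x = mean (pN), sigma = sd, A = amplitude of the
# unnormalised Gaussian.  Occupancy weights are proportional to A * sigma.
VINCTS_FORCE_BIMODAL = {
    "x1": 2.737, "sigma1": 0.413, "A1": 0.678,
    "x2": 3.172, "sigma2": 0.161, "A2": 0.686,
}
VINCTS_RIAM_FORCE_BIMODAL = {
    "x1": 3.067, "sigma1": 0.409, "A1": 0.784,
    "x2": 3.454, "sigma2": 0.114, "A2": 0.633,
}

# Synthetic (not experimentally published) tension-sensor donor pair and
# no-tension reference used as scene defaults; values are field-realistic for
# an mTFP1-mVenus TSMod and chosen so both TS and TL lifetimes stay within
# the fittable range at 256 bins over a 12.5 ns period.  See docs/methods.md.
DEFAULT_TS_PAIR = FluorophorePair("mTFP1", "mVenus", tau_D_ns=3.2, R0_nm=6.0)
DEFAULT_TS_R_TL_NM = 4.2


@dataclass(frozen=True)
class KineticsSpec:
    """Multi-exponential decay kinetics plus acquisition parameters.

    ``components`` are (amplitude_fraction, lifetime_ns) pairs; amplitude
    fractions are pre-exponential and must sum to 1.  ``background_rate`` is
    expected counts per bin of uniform (uncorrelated) background.
    """

    components: tuple[tuple[float, float], ...]
    repetition_period_ns: float = DEFAULT_PERIOD_NS
    n_bins: int = DEFAULT_N_BINS
    irf_sigma_ns: float = 0.0
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(t)) for a, t in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise InvalidParameterError("at least one decay component required")
        fractions = np.array([a for a, _ in comps])
        taus = np.array([t for _, t in comps])
        if np.any(fractions <= 0) or np.any(fractions > 1):
            raise InvalidParameterError("amplitude fractions must lie in (0, 1]")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise InvalidParameterError(f"amplitude fractions must sum to 1, got {fractions.sum()}")
        if np.any(taus <= 0):
            raise InvalidParameterError("all lifetimes must be positive")
        if self.repetition_period_ns <= 0:
            raise InvalidParameterError("repetition period must be positive")
        if self.n_bins < 16:
            raise InvalidParameterError("n_bins must be >= 16")
        if self.irf_sigma_ns < 0 or self.background_rate < 0:
            raise InvalidParameterError("irf_sigma and background_rate must be >= 0")

    @classmethod
    def mono(cls, tau_ns: float, **kwargs) -> "KineticsSpec":
        return cls(components=((1.0, tau_ns),), **kwargs)

    def expected_fractions(self) -> np.ndarray:
        edges = bin_edges(self.repetition_period_ns, self.n_bins)
        return expected_bin_fractions(
            [a for a, _ in self.components],
            [t for _, t in self.components],
            edges,
            self.repetition_period_ns,
            self.irf_sigma_ns,
        )


def simulate_decay(
    spec: KineticsSpec,
    total_photons: float,
    seed,
    expectation: bool = False,
) -> DecayHistogram:
    """Simulate one TCSPC decay histogram.

    Expected bin contents are the period-wrapped, IRF-convolved
    multi-exponential model integrated per bin, scaled to ``total_photons``,
    plus uniform background; counts are Poisson draws reproducible under
    ``seed``.  ``expectation=True`` skips the Poisson step and returns the
    (float) expectations, which is the noiseless reference used by exact
    round-trip tests.
    """
    if total_photons < 0:
        raise InvalidParameterError("total_photons must be >= 0")
    edges = bin_edges(spec.repetition_period_ns, spec.n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu = total_photons * spec.expected_fractions() + spec.background_rate
    if expectation:
        counts = mu
    else:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(mu)
    return DecayHistogram(
        bin_centers=centers,
        counts=counts,
        period_ns=spec.repetition_period_ns,
        is_expectation=expectation,
    )


def simulate_cascade_ensemble(
    pairs: Mapping[tuple[str, str], FluorophorePair] | Sequence[FluorophorePair],
    distances_nm: Mapping[tuple[str, str], float],
    seed,
    total_photons: float = 1_000_000,
    period_ns: float = DEFAULT_PERIOD_NS,
    n_bins: int = DEFAULT_N_BINS,
    irf_sigma_ns: float = 0.0,
    background_rate: float = 0.0,
    expectation: bool = False,
) -> dict[str, DecayHistogram]:
    """Simulate the full construct ensemble of a three-colour FRET cascade.

    ``pairs`` supplies tau_D and R0 for each (donor, acceptor); ``distances_nm``
    the pairwise separations.  The cascade donor is the fluorophore that
    donates to two acceptors.  Emitted constructs (labels in parentheses):

    - donor alone (``"D"``),
    - each pairwise construct (``"D-A"``),
    - the dark-intermediate construct, with the transfer to the intermediate
      removed (``"D-dark(B)-C"``),
    - the full three-colour construct (``"D-B-C"``).

    Each construct's donor lifetime is 1/(1/tau_D + sum of its transfer
    rates) with Gamma = (1/tau_D)(R0/r)^6.
    """
    if not isinstance(pairs, Mapping):
        pairs = {p.key: p for p in pairs}
    for key in distances_nm:
        if key not in pairs:
            raise ConfigurationError(f"no FluorophorePair parameters for {key}")
        if distances_nm[key] <= 0:
            raise InvalidParameterError(f"distance for {key} must be positive")

    by_donor: dict[str, list[str]] = {}
    for d, a in distances_nm:
        by_donor.setdefault(d, []).append(a)
    cascade_donor = next((d for d, accs in by_donor.items() if len(accs) >= 2), None)

    def gamma(d: str, a: str) -> float:
        p = pairs[(d, a)]
        return _cascade.rate_from_separation(distances_nm[(d, a)], p.tau_D_ns, p.R0_nm)

    lifetimes: dict[str, float] = {}
    donors = sorted(by_donor)
    for d in donors:
        tau_d = pairs[(d, by_donor[d][0])].tau_D_ns
        lifetimes[d] = tau_d
        for a in sorted(by_donor[d]):
            lifetimes[f"{d}-{a}"] = _cascade.lifetime_from_rates(tau_d, [gamma(d, a)])
    if cascade_donor is not None:
        d = cascade_donor
        tau_d = pairs[(d, by_donor[d][0])].tau_D_ns
        accs = sorted(by_donor[d])[:2]
        # the intermediate is the acceptor that itself donates onward
        onward = [a for a in accs if a in by_donor]
        if onward:
            b = onward[0]
            c = next(a for a in accs if a != b)
        else:
            b, c = accs
        lifetimes[f"{d}-dark({b})-{c}"] = _cascade.lifetime_from_rates(tau_d, [gamma(d, c)])
        lifetimes[f"{d}-{b}-{c}"] = _cascade.lifetime_from_rates(tau_d, [gamma(d, b), gamma(d, c)])

    root = np.random.SeedSequence(seed)
    out: dict[str, DecayHistogram] = {}
    for i, (name, tau) in enumerate(sorted(lifetimes.items())):
        spec = KineticsSpec.mono(
            tau,
            repetition_period_ns=period_ns,
            n_bins=n_bins,
            irf_sigma_ns=irf_sigma_ns,
            background_rate=background_rate,
        )
        out[name] = simulate_decay(
            spec, total_photons, np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,)),
            expectation=expectation,
        )
    return out


@dataclass
class TensionScene:
    """A synthetic FLIM tension scene with full ground truth.

    ``force_truth_pN`` and ``lifetime_truth_ns`` are NaN outside the adhesion
    mask; ``population_label`` is 1 or 2 inside the mask, 0 outside.
    """

    image_shape: tuple[int, int]
    adhesion_mask: np.ndarray
    population_label: np.ndarray
    force_truth_pN: np.ndarray
    lifetime_truth_ns: np.ndarray
    photons_per_pixel: float
    seed: int

    def __post_init__(self) -> None:
        inside = self.adhesion_mask
        if np.any(self.force_truth_pN[inside] < 0):
            raise InvalidParameterError("ground-truth forces must be >= 0 inside the mask")
        if np.any(self.population_label[inside] < 1):
            raise InvalidParameterError("population labels must be 1 or 2 inside the mask")


def make_adhesion_mask(
    image_shape: tuple[int, int],
    rng: np.random.Generator,
    n_patches: int = 6,
    radius_px: tuple[float, float] = (3.0, 7.0),
    border_frac: float = 0.25,
) -> np.ndarray:
    """Elliptical focal-adhesion-like patches near the image border.

    Purely cosmetic layout: adhesions sit in a peripheral band, as they do at
    the spread edge of a fibroblast.
    """
    rows, cols = image_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = np.zeros(image_shape, dtype=bool)
    for _ in range(n_patches):
        # pick a centre in the border band
        side = rng.integers(4)
        band_r = max(1, int(border_frac * rows))
        band_c = max(1, int(border_frac * cols))
        if side == 0:
            cy, cx = rng.integers(0, band_r), rng.integers(0, cols)
        elif side == 1:
            cy, cx = rng.integers(rows - band_r, rows), rng.integers(0, cols)
        elif side == 2:
            cy, cx = rng.integers(0, rows), rng.integers(0, band_c)
        else:
            cy, cx = rng.integers(0, rows), rng.integers(cols - band_c, cols)
        a = rng.uniform(*radius_px)
        b = rng.uniform(radius_px[0] / 2, a)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        w = -(xx - cx) * st + (yy - cy) * ct
        mask |= (u / a) ** 2 + (w / b) ** 2 <= 1.0
    return mask


def _pixel_rng(seed: int, row: int, col: int) -> np.random.Generator:
    """Counter-based per-pixel stream: independent of image size.

    Pixel coordinates key the spawn counter (offset by 1 so that (-1, -1) is a
    reserved layout stream), so a change of image size never reshuffles the
    stream of an unrelated pixel.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(row + 1, col + 1))
    )


def _draw_mixture_force(
    rng: np.random.Generator,
    means: np.ndarray,
    sds: np.ndarray,
    weights: np.ndarray,
    max_resample: int = 1000,
) -> tuple[float, int]:
    """One non-negative draw; negatives rejected and resampled (tensile forces)."""
    comp = int(rng.choice(len(weights), p=weights))
    for _ in range(max_resample):
        f = rng.normal(means[comp], sds[comp]) if sds[comp] > 0 else means[comp]
        if f >= 0:
            return f, comp + 1
    raise InvalidParameterError(
        f"mixture component {comp + 1} (mean {means[comp]}, sd {sds[comp]}) "
        "almost never yields a non-negative force"
    )


def simulate_tension_scene(
    pop1: tuple[float, float, float],
    pop2: tuple[float, float, float],
    pair: FluorophorePair,
    calibration: ForceCalibration,
    image_shape: tuple[int, int] = (48, 48),
    photons_per_pixel: float = 10_000,
    seed: int = 0,
    bystander_gamma_ns: float = 0.0,
    mask: np.ndarray | None = None,
    period_ns: float = DEFAULT_PERIOD_NS,
    n_bins: int = DEFAULT_N_BINS,
    background_rate: float = 0.0,
    cytoplasm_photon_frac: float = 0.05,
    expectation: bool = False,
) -> tuple[TensionScene, np.ndarray]:
    """Simulate a FLIM stack of a cell whose adhesions hold a two-population
    tension mixture.

    ``pop1`` / ``pop2`` are (mean_pN, sd_pN, weight).  Per in-mask pixel a
    force is drawn from the mixture (negative draws resampled), converted to a
    donor lifetime through the exact inverse of the force-mapping chain
    (optionally including a bystander transfer rate), and a decay histogram is
    simulated.  Out-of-mask pixels are dim cytoplasm at the no-tension (TL)
    lifetime.  Returns ``(TensionScene, stack)`` with stack shaped
    ``(n_bins, rows, cols)``.
    """
    m1, s1, w1 = pop1
    m2, s2, w2 = pop2
    if w1 <= 0 or w2 <= 0:
        raise InvalidParameterError("mixture weights must be positive")
    if s1 < 0 or s2 < 0:
        raise InvalidParameterError("mixture sds must be >= 0")
    means = np.array([m1, m2])
    sds = np.array([s1, s2])
    weights = np.array([w1, w2]) / (w1 + w2)
    if calibration.r_TL_nm is None:
        raise ConfigurationError("calibration.r_TL_nm (no-tension reference separation) is required")

    rows, cols = image_shape
    scene_rng = _pixel_rng(seed, -1, -1)  # reserved stream for layout
    if mask is None:
        mask = make_adhesion_mask(image_shape, scene_rng)
    mask = np.asarray(mask, dtype=bool)

    tau_tl = lifetime_from_force(0.0, pair, calibration, bystander_gamma_ns)
    force_truth = np.full(image_shape, np.nan)
    lifetime_truth = np.full(image_shape, np.nan)
    label = np.zeros(image_shape, dtype=np.int8)
    stack = np.zeros((n_bins, rows, cols), dtype=float if expectation else np.int64)

    for r in range(rows):
        for c in range(cols):
            rng = _pixel_rng(seed, r, c)
            if mask[r, c]:
                try:
                    f, lab = _draw_mixture_force(rng, means, sds, weights)
                    tau = lifetime_from_force(f, pair, calibration, bystander_gamma_ns)
                except InvalidParameterError as exc:
                    raise InvalidParameterError(f"pixel ({r}, {c}): {exc}") from exc
                force_truth[r, c] = f
                lifetime_truth[r, c] = tau
                label[r, c] = lab
                budget = photons_per_pixel
            else:
                tau = tau_tl
                budget = cytoplasm_photon_frac * photons_per_pixel
            spec = KineticsSpec.mono(
                tau, repetition_period_ns=period_ns, n_bins=n_bins,
                background_rate=background_rate,
            )
            hist = simulate_decay(spec, budget, rng, expectation=expectation)
            stack[:, r, c] = hist.counts

    scene = TensionScene(
        image_shape=image_shape,
        adhesion_mask=mask,
        population_label=label,
        force_truth_pN=force_truth,
        lifetime_truth_ns=lifetime_truth,
        photons_per_pixel=photons_per_pixel,
        seed=seed,
    )
    return scene, stack


def table_mixture(
    x1: float, sigma1: float, A1: float, x2: float, sigma2: float, A2: float
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Turn published bimodal-fit parameters into (mean, sd, weight) pops,
    with weights proportional to component area A * sigma."""
    w1, w2 = area_weights(A1, sigma1, A2, sigma2)
    return (x1, sigma1, w1), (x2, sigma2, w2)
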