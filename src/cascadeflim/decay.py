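"""Time-correlated single-photon-counting decay histograms and the wrapped
multi-exponential decay model.

A TCSPC measurement under pulsed excitation with repetition period ``T`` bins
photon arrival times into one period.  Because fluorescence lifetimes of a few
nanoseconds are a sizeable fraction of the 12.5 ns period of an 80 MHz laser,
the decay does not complete between pulses: the observed histogram is the sum
over all preceding pulses.  For a single exponential with lifetime ``tau`` the
wrapped intensity on ``[0, T)`` is

    I(t) = exp(-t/tau) / (1 - exp(-T/tau))          (up to normalisation)

and the expected photon fraction in bin ``[t0, t1]`` is

    (exp(-t0/tau) - exp(-t1/tau)) / (1 - exp(-T/tau))

which sums to exactly 1 over a full period.  Both the simulator and the decay
fitter use this same integrated-bin model, optionally convolved with a
Gaussian instrument response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "DecayHistogram",
    "bin_edges",
    "component_bin_fractions",
    "expected_bin_fractions",
]

_SPACING_TOL = 1e-9


@dataclass(frozen=True)
class DecayHistogram:
    """Binned photon arrival counts over one excitation period.

    Parameters
    ----------
    bin_centers : array of float
        Bin centre times in ns, strictly increasing, uniformly spaced.
    counts : array
        Photon counts per bin.  Integral and non-negative for measured /
        simulated data; `is_expectation=True` relaxes the integrality
        requirement for noiseless model expectations.
    period_ns : float
        Excitation repetition period in ns.
    origin_ns : float
        Time of the leading edge of the first bin.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    period_ns: float
    origin_ns: float = 0.0
    is_expectation: bool = False

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "counts", counts)
        if centers.ndim != 1 or counts.ndim != 1 or len(centers) != len(counts):
            raise InvalidParameterError("bin_centers and counts must be equal-length 1-D arrays")
        if len(centers) < 2:
            raise InvalidParameterError("a decay histogram needs at least two bins")
        diffs = np.diff(centers)
        if np.any(diffs <= 0) or np.ptp(diffs) > _SPACING_TOL:
            raise InvalidParameterError("bin centres must be strictly increasing and uniformly spaced")
        if self.period_ns <= 0:
            raise InvalidParameterError("period_ns must be positive")
        if np.any(counts < 0):
            raise InvalidParameterError("counts must be non-negative")
        if not self.is_expectation and np.any(np.abs(counts - np.round(counts)) > 1e-6):
            raise InvalidParameterError("measured counts must be integral")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_width_ns(self) -> float:
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def edges_ns(self) -> np.ndarray:
        """Bin edges (length n_bins + 1) in ns."""
        w = self.bin_width_ns
        return np.concatenate([self.bin_centers - w / 2.0, [self.bin_centers[-1] + w / 2.0]])


def bin_edges(period_ns: float, n_bins: int, origin_ns: float = 0.0) -> np.ndarray:
    """Uniform bin edges spanning one repetition period."""
    if period_ns <= 0 or n_bins < 2:
        raise InvalidParameterError("period_ns must be > 0 and n_bins >= 2")
    return origin_ns + np.linspace(0.0, period_ns, n_bins + 1)


def component_bin_fractions(
    tau_ns: float,
    edges_ns: np.ndarray,
    period_ns: float,
    irf_sigma_ns: float = 0.0,
    oversample: int = 10,
) -> np.ndarray:
    """Expected per-bin photon fraction of a unit-mass wrapped exponential.

    With ``irf_sigma_ns == 0`` the result is analytic; otherwise the wrapped
    decay is convolved circularly with a Gaussian IRF on an `oversample`-times
    finer grid, then re-binned.  Sums to 1 over a full period in either case.
    """
    if tau_ns <= 0:
        raise InvalidParameterError(f"lifetime must be positive, got {tau_ns}")
    edges = np.asarray(edges_ns, dtype=float) - edges_ns[0]
    if irf_sigma_ns < 0:
        raise InvalidParameterError("irf_sigma_ns must be >= 0")
    if irf_sigma_ns == 0:
        norm = 1.0 - np.exp(-period_ns / tau_ns)
        return np.diff(-np.exp(-edges / tau_ns)) / norm

    # Convolve on an oversampled grid covering the full period (circular,
    # because the IRF also wraps photon arrivals across the period boundary).
    n_fine = (len(edges) - 1) * oversample
    fine_edges = np.linspace(0.0, period_ns, n_fine + 1)
    norm = 1.0 - np.exp(-period_ns / tau_ns)
    fine = np.diff(-np.exp(-fine_edges / tau_ns)) / norm
    dt = period_ns / n_fine
    # Gaussian kernel on the circular grid, centred at 0.
    k = np.arange(n_fine)
    offset = np.minimum(k, n_fine - k) * dt
    kernel = np.exp(-0.5 * (offset / irf_sigma_ns) ** 2)
    kernel /= kernel.sum()
    conv = np.real(np.fft.ifft(np.fft.fft(fine) * np.fft.fft(kernel)))
    conv = np.clip(conv, 0.0, None)
    return conv.reshape(-1, oversample).sum(axis=1)


def expected_bin_fractions(
    amplitude_fractions: np.ndarray,
    lifetimes_ns: np.ndarray,
    edges_ns: np.ndarray,
    period_ns: float,
    irf_sigma_ns: float = 0.0,
) -> np.ndarray:
    """Per-bin photon fractions of a multi-exponential wrapped decay.

    `amplitude_fractions` are pre-exponential fractions a_i (summing to 1);
    the photon (intensity) fraction of component i is a_i tau_i / sum(a_j tau_j),
    since a decaying exponential of amplitude a and lifetime tau carries a*tau
    photons.  Output sums to 1 over a full period.
    """
    a = np.asarray(amplitude_fractions, dtype=float)
    taus = np.asarray(lifetimes_ns, dtype=float)
    if np.any(taus <= 0):
        raise InvalidParameterError("all lifetimes must be positive")
    if np.any(a < 0):
        raise InvalidParameterError("amplitude fractions must be non-negative")
    photon_weights = a * taus
    total = photon_weights.sum()
    if total <= 0:
        raise InvalidParameterError("at least one component must have positive amplitude")
    photon_weights = photon_weights / total
    out = np.zeros(len(edges_ns) - 1)
    for w, tau in zip(photon_weights, taus):
        out += w * component_bin_fractions(tau, edges_ns, period_ns, irf_sigma_ns)
    return out
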