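"""Mono- and bi-exponential lifetime fitting of TCSPC decay histograms.

The model is the same period-wrapped, bin-integrated multi-exponential used
by the simulator, plus a constant baseline, fitted over a window with
Levenberg-Marquardt with bounds (via lmfit).  Two objectives are available:

- ``"mle"`` (default): Poisson maximum likelihood, implemented as least
  squares on signed square-root deviance residuals.  At photon-counting
  statistics this is essentially unbiased down to tens of counts per bin.
- ``"neyman"``: classic weighted least squares with observed-count variances
  (``max(counts, 1)``).  Provided for comparability with legacy TCSPC
  software; biases lifetimes low by ~0.3-2% at typical per-pixel budgets
  because downward count fluctuations receive the largest weights.

The constant baseline is included only when the data support it
(``baseline="auto"``): both variants are fitted and a likelihood-ratio test
at the 1% level decides, because with zero true background a free,
non-negative baseline can only steal counts from the slowly-varying wrapped
tail and bias the lifetime low.

By default the window is a tail fit starting two bins after the histogram
peak, which avoids explicit IRF deconvolution; when an IRF width is declared
in the options the convolved model is used instead (reconvolution fitting).

Aggregation follows the FLIM convention: an intensity-weighted mean lifetime
per pixel, a photon-count-weighted mean over the pixels of a cell, and an
unweighted mean (each cell weighted equally) with SEM across cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lmfit import Parameters, minimize
from scipy.optimize import nnls

from .decay import DecayHistogram, component_bin_fractions
from .errors import InsufficientDataError, InvalidParameterError, UndefinedLifetimeError

__all__ = [
    "FitOptions",
    "LifetimeFit",
    "CellAggregate",
    "ConditionSummary",
    "StackFitResult",
    "fit_decay",
    "intensity_weighted_lifetime",
    "amplitude_weighted_lifetime",
    "aggregate_cell",
    "aggregate_condition",
    "fit_stack",
]

TAU_MIN_NS = 0.05
TAU_MAX_NS = 20.0


@dataclass(frozen=True)
class FitOptions:
    """Options controlling :func:`fit_decay`.

    ``fit_window_ns``: explicit (start, end) window in ns; default is a tail
    fit from (peak bin + `tail_offset_bins`) to the end of the period.
    ``irf_sigma_ns`` > 0 switches to reconvolution fitting with a Gaussian IRF.
    ``max_restarts`` bounds the number of perturbed re-initialisations tried
    before a fit is reported as failed.
    """

    fit_window_ns: tuple[float, float] | None = None
    tail_offset_bins: int = 2
    irf_sigma_ns: float = 0.0
    min_counts: int = 100
    max_restarts: int = 3
    objective: str = "mle"  # or "neyman"
    baseline: str | bool = "auto"  # True: always fit; False: fix at 0
    baseline_lrt_threshold: float = 6.63  # chi2(1 dof) at the 1% level


@dataclass(frozen=True)
class LifetimeFit:
    """Fitted multi-exponential components and derived mean lifetimes.

    ``components`` are (amplitude, lifetime_ns) with pre-exponential
    amplitudes (counts/ns scale), lifetimes in increasing order for
    bi-exponential fits.
    """

    components: tuple[tuple[float, float], ...]
    baseline: float
    chi2_per_dof: float
    n_components: int
    fit_window_ns: tuple[float, float]
    converged: bool
    message: str = ""
    n_photons_window: float = 0.0

    @property
    def tau_amplitude_weighted(self) -> float:
        a = np.array([c[0] for c in self.components])
        t = np.array([c[1] for c in self.components])
        if a.sum() <= 0:
            raise UndefinedLifetimeError("all fitted amplitudes are zero")
        return float((a * t).sum() / a.sum())

    @property
    def tau_intensity_weighted(self) -> float:
        return intensity_weighted_lifetime(self)

    @property
    def tau_ns(self) -> float:
        """The per-pixel lifetime used downstream (intensity-weighted)."""
        return self.tau_intensity_weighted


def intensity_weighted_lifetime(fit: LifetimeFit) -> float:
    """Intensity-weighted mean lifetime sum(a_i tau_i^2) / sum(a_i tau_i).

    Weights each component by its photon contribution a_i tau_i; reduces to
    tau_1 for a mono-exponential fit.
    """
    a = np.array([c[0] for c in fit.components])
    t = np.array([c[1] for c in fit.components])
    denom = (a * t).sum()
    if denom <= 0:
        raise UndefinedLifetimeError("all fitted amplitudes are zero")
    return float((a * t * t).sum() / denom)


def amplitude_weighted_lifetime(fit: LifetimeFit) -> float:
    """Amplitude-weighted mean lifetime sum(a_i tau_i) / sum(a_i)."""
    return fit.tau_amplitude_weighted


def _model_matrix(taus, window_edges, period_ns, irf_sigma_ns) -> np.ndarray:
    """Columns = per-bin expected counts of a unit-amplitude (a=1) component."""
    cols = []
    for tau in taus:
        frac = component_bin_fractions(tau, window_edges, period_ns, irf_sigma_ns)
        cols.append(tau * frac)
    return np.column_stack(cols)


def fit_decay(
    hist: DecayHistogram,
    n_components: int = 1,
    options: FitOptions = FitOptions(),
) -> LifetimeFit:
    """Fit a wrapped mono- or bi-exponential + baseline to a decay histogram.

    Returns a :class:`LifetimeFit`; non-convergence after bounded restarts
    yields a result with ``converged=False`` and diagnostics in ``message``
    rather than an exception.  Fewer than ``options.min_counts`` counts in the
    fit window raises :class:`InsufficientDataError`.
    """
    if n_components not in (1, 2):
        raise InvalidParameterError("n_components must be 1 or 2")
    counts = hist.counts
    edges = hist.edges_ns - hist.origin_ns
    centers = hist.bin_centers - hist.origin_ns

    if options.fit_window_ns is not None:
        lo, hi = options.fit_window_ns
        sel = (centers >= lo) & (centers <= hi)
        if sel.sum() < n_components * 2 + 2:
            raise InsufficientDataError("fit window contains too few bins")
        start = int(np.argmax(sel))
        stop = int(len(sel) - np.argmax(sel[::-1]))
    else:
        peak = int(np.argmax(counts))  # argmax takes the earliest bin on ties
        start = min(peak + options.tail_offset_bins, len(counts) - (n_components * 2 + 2))
        stop = len(counts)
    w_counts = counts[start:stop]
    w_edges = edges[start : stop + 1]
    window = (float(centers[start]), float(centers[stop - 1]))
    if w_counts.sum() < options.min_counts:
        raise InsufficientDataError(
            f"only {w_counts.sum():.0f} counts in fit window; need >= {options.min_counts}"
        )

    period = hist.period_ns
    irf = options.irf_sigma_ns
    ney_w = 1.0 / np.sqrt(np.maximum(w_counts, 1.0))
    if options.objective not in ("mle", "neyman"):
        raise InvalidParameterError(f"unknown objective {options.objective!r}")

    # initial tau from the log-linear slope of the tail
    pos = w_counts > 0
    t_pos = 0.5 * (w_edges[:-1] + w_edges[1:])[pos]
    c_pos = w_counts[pos]
    if pos.sum() >= 3:
        slope = np.polyfit(t_pos, np.log(c_pos), 1, w=np.sqrt(c_pos))[0]
        tau0 = -1.0 / slope if slope < 0 else 2.0
    else:
        tau0 = 2.0
    tau0 = float(np.clip(tau0, TAU_MIN_NS * 2, TAU_MAX_NS / 2))

    def model_counts(params):
        taus = [params[f"tau{i}"].value for i in range(n_components)]
        amps = [params[f"amp{i}"].value for i in range(n_components)]
        return (
            _model_matrix(taus, w_edges, period, irf) @ np.asarray(amps)
            + params["baseline"].value
        )

    def deviance_residuals(mu):
        mu = np.maximum(mu, 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            lg = np.where(w_counts > 0, w_counts * np.log(w_counts / mu), 0.0)
        d = 2.0 * ((mu - w_counts) + lg)
        return np.sign(w_counts - mu) * np.sqrt(np.maximum(d, 0.0))

    def residual(params):
        mu = model_counts(params)
        if options.objective == "neyman":
            return (mu - w_counts) * ney_w
        return deviance_residuals(mu)

    def init_params(tau_guesses, with_baseline):
        M = _model_matrix(tau_guesses, w_edges, period, irf)
        A = np.column_stack([M, np.ones(len(w_counts))]) * ney_w[:, None]
        sol, _ = nnls(A, w_counts * ney_w)
        params = Parameters()
        for i, tau in enumerate(tau_guesses):
            params.add(f"tau{i}", value=tau, min=TAU_MIN_NS, max=TAU_MAX_NS)
            params.add(f"amp{i}", value=max(sol[i], 1e-12), min=0.0)
        params.add(
            "baseline",
            value=max(sol[-1], 0.0) if with_baseline else 0.0,
            min=0.0,
            vary=with_baseline,
        )
        return params

    if n_components == 1:
        guesses = [[tau0], [0.7 * tau0], [1.4 * tau0]]
    else:
        guesses = [[0.5 * tau0, 1.5 * tau0], [0.3 * tau0, 1.2 * tau0], [0.7 * tau0, 2.0 * tau0]]
    guesses = guesses[: options.max_restarts + 1]

    def fit_variant(with_baseline):
        best, message = None, ""
        for g in guesses:
            g = [float(np.clip(t, TAU_MIN_NS, TAU_MAX_NS)) for t in g]
            try:
                res = minimize(residual, init_params(g, with_baseline), method="leastsq")
            except Exception as exc:
                message = str(exc)
                continue
            if best is None or res.chisqr < best.chisqr:
                best = res
        return best, message

    if options.baseline == "auto":
        variants = [False, True]
    else:
        variants = [bool(options.baseline)]
    fits = {}
    message = ""
    for wb in variants:
        res, msg = fit_variant(wb)
        message = message or msg
        if res is not None:
            fits[wb] = res

    if not fits:
        return LifetimeFit(
            components=tuple((0.0, 1.0) for _ in range(n_components)),
            baseline=0.0, chi2_per_dof=math.inf, n_components=n_components,
            fit_window_ns=window, converged=False,
            message=message or "all restarts failed", n_photons_window=float(w_counts.sum()),
        )

    def deviance(res):
        return float((deviance_residuals(model_counts(res.params)) ** 2).sum())

    if len(fits) == 2:
        # keep the baseline only if the likelihood-ratio test supports it
        gain = deviance(fits[False]) - deviance(fits[True])
        with_baseline = gain > options.baseline_lrt_threshold
    else:
        with_baseline = next(iter(fits))
    best = fits[with_baseline]

    p = best.params
    mu = model_counts(p)
    n_params = 2 * n_components + (1 if with_baseline else 0)
    dof = max(len(w_counts) - n_params, 1)
    ney_chi2 = float((((mu - w_counts) * ney_w) ** 2).sum() / dof)
    comps = sorted(
        ((float(p[f"amp{i}"].value), float(p[f"tau{i}"].value)) for i in range(n_components)),
        key=lambda c: c[1],
    )
    return LifetimeFit(
        components=tuple(comps),
        baseline=float(p["baseline"].value),
        chi2_per_dof=ney_chi2,
        n_components=n_components,
        fit_window_ns=window,
        converged=bool(best.success),
        message="" if best.success else str(best.message),
        n_photons_window=float(w_counts.sum()),
    )


@dataclass(frozen=True)
class CellAggregate:
    """Photon-weighted mean lifetime of one cell plus a pixel-exclusion report."""

    tau_ns: float
    n_pixels: int
    n_failed: int
    total_photons: float


def aggregate_cell(
    pixel_fits: Sequence[tuple[LifetimeFit, float]],
    mask: Sequence[bool] | None = None,
) -> CellAggregate:
    """Photon-count-weighted mean of per-pixel intensity-weighted lifetimes.

    ``pixel_fits`` pairs each pixel's fit with its photon count; pixels whose
    fit did not converge are excluded and counted in the report.
    """
    if mask is not None:
        pixel_fits = [pf for pf, m in zip(pixel_fits, mask) if m]
    if not pixel_fits:
        raise InsufficientDataError("no masked pixels to aggregate")
    taus, photons = [], []
    n_failed = 0
    for fit, n in pixel_fits:
        if not fit.converged:
            n_failed += 1
            continue
        taus.append(fit.tau_intensity_weighted)
        photons.append(n)
    if not taus:
        raise InsufficientDataError("no converged pixel fits in cell")
    taus = np.asarray(taus)
    photons = np.asarray(photons, dtype=float)
    if photons.sum() <= 0:
        raise InsufficientDataError("total photon count is zero")
    return CellAggregate(
        tau_ns=float((taus * photons).sum() / photons.sum()),
        n_pixels=len(taus),
        n_failed=n_failed,
        total_photons=float(photons.sum()),
    )


@dataclass(frozen=True)
class ConditionSummary:
    """Unweighted across-cell mean and SEM (each cell weighted equally)."""

    mean: float
    sem: float  # NaN when only one cell
    n_cells: int

    @property
    def sem_defined(self) -> bool:
        return not math.isnan(self.sem)


def aggregate_condition(cell_means: Sequence[float]) -> ConditionSummary:
    """Arithmetic mean and standard error over cells."""
    vals = np.asarray(list(cell_means), dtype=float)
    if vals.size == 0:
        raise InsufficientDataError("no cells to aggregate")
    mean = float(vals.mean())
    if vals.size < 2:
        return ConditionSummary(mean=mean, sem=math.nan, n_cells=1)
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return ConditionSummary(mean=mean, sem=sem, n_cells=int(vals.size))


@dataclass
class StackFitResult:
    """Per-pixel fit maps for one FLIM stack."""

    tau_ns: np.ndarray  # intensity-weighted lifetime, NaN where failed/unmasked
    photons: np.ndarray
    chi2_per_dof: np.ndarray
    n_failed: int
    n_binned: int  # pixels fitted on a 3x3 neighbourhood sum

    def cell_mean_lifetime(self) -> CellAggregate:
        ok = np.isfinite(self.tau_ns) & (self.photons > 0)
        if not ok.any():
            raise InsufficientDataError("no successfully fitted pixels in stack")
        taus = self.tau_ns[ok]
        ph = self.photons[ok]
        return CellAggregate(
            tau_ns=float((taus * ph).sum() / ph.sum()),
            n_pixels=int(ok.sum()),
            n_failed=self.n_failed,
            total_photons=float(ph.sum()),
        )


def fit_stack(
    stack: np.ndarray,
    period_ns: float,
    mask: np.ndarray | None = None,
    n_components: int = 1,
    photon_threshold: int = 300,
    options: FitOptions = FitOptions(),
) -> StackFitResult:
    """Fit every masked pixel of a FLIM stack (time bins, rows, cols).

    Pixels below ``photon_threshold`` photons are fitted on the sum of their
    3x3 neighbourhood (standard low-count binning); pixels that still lack
    counts, or whose fit fails, are NaN in the output maps and counted.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InvalidParameterError("stack must be (n_bins, rows, cols)")
    n_bins, rows, cols = stack.shape
    centers = (np.arange(n_bins) + 0.5) * (period_ns / n_bins)
    photons = stack.sum(axis=0).astype(float)
    if mask is None:
        mask = photons > 0
    mask = np.asarray(mask, dtype=bool)

    tau_map = np.full((rows, cols), np.nan)
    chi2_map = np.full((rows, cols), np.nan)
    n_failed = 0
    n_binned = 0
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            trace = stack[:, r, c]
            if photons[r, c] < photon_threshold:
                r0, r1 = max(r - 1, 0), min(r + 2, rows)
                c0, c1 = max(c - 1, 0), min(c + 2, cols)
                trace = stack[:, r0:r1, c0:c1].sum(axis=(1, 2))
                n_binned += 1
            hist = DecayHistogram(
                bin_centers=centers, counts=trace, period_ns=period_ns,
                is_expectation=not np.issubdtype(stack.dtype, np.integer),
            )
            try:
                fit = fit_decay(hist, n_components=n_components, options=options)
            except InsufficientDataError:
                n_failed += 1
                continue
            if not fit.converged:
                n_failed += 1
                continue
            tau_map[r, c] = fit.tau_intensity_weighted
            chi2_map[r, c] = fit.chi2_per_dof
    return StackFitResult(
        tau_ns=tau_map, photons=photons, chi2_per_dof=chi2_map,
        n_failed=n_failed, n_binned=n_binned,
    )
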