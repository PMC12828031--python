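"""Molecular tension from FRET tension-sensor measurements.

A tension-sensor module (TSMod) places an elastic linker of ``N`` amino acids
between a FRET pair inside a protein; tension extends the linker, increasing
the donor-acceptor separation and lowering FRET.  The mean force follows from
the separations measured for the tension construct (TS) and a zero-force
tailless control (TL):

    <F> = (<R_TS> - <R_TL>) * (0.01196 N + 0.0001255)

This is the calibration as printed for the 40-residue flagelliform linker; the
same source describes the linker as having a compliance of ~0.478 nm/pN, which
would instead imply division by the coefficient.  Both conventions are exposed
(``force_model="printed"`` / ``"compliance"``); printed is the default.  See
docs/methods.md for the discussion.

Per-pixel force maps chain: lifetime -> total rate -> (optional bystander
correction) -> transfer rate -> efficiency -> separation -> force.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from . import cascade
from .cascade import FluorophorePair
from .errors import ConfigurationError, InsufficientDataError, InvalidParameterError

__all__ = [
    "ForceCalibration",
    "ForceMap",
    "BimodalFit",
    "linker_coefficient",
    "force_from_separations",
    "separation_from_force",
    "lifetime_from_force",
    "pixel_force_map",
    "fit_bimodal",
    "area_weights",
]

DEFAULT_SLOPE = 0.01196  # pN nm^-1 per residue term of the linker calibration
DEFAULT_INTERCEPT = 0.0001255


def linker_coefficient(N: int, slope: float = DEFAULT_SLOPE, intercept: float = DEFAULT_INTERCEPT) -> float:
    """Elastic-linker calibration coefficient 0.01196 N + 0.0001255.

    ``N`` is the number of amino acids in the linker (40 for the TSMod
    flagelliform linker, giving ~0.4785).  N = 0 is allowed as a hypothetical
    (returns the intercept); negative N is a domain error.
    """
    if N < 0:
        raise InvalidParameterError(f"linker length must be >= 0, got {N}")
    return slope * N + intercept


@dataclass(frozen=True)
class ForceCalibration:
    """Tension-sensor calibration: linker length, Eq. coefficient terms and the
    no-tension reference separation ``r_TL_nm`` (measured from the TL control,
    not hard-coded)."""

    linker_n: int = 40
    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    r_TL_nm: float | None = None
    force_model: str = "printed"  # or "compliance"

    def __post_init__(self) -> None:
        if self.linker_n < 1:
            raise InvalidParameterError("linker_n must be >= 1")
        if self.coefficient <= 0:
            raise InvalidParameterError("calibration coefficient must be positive")
        if self.force_model not in ("printed", "compliance"):
            raise InvalidParameterError(f"unknown force_model {self.force_model!r}")

    @property
    def coefficient(self) -> float:
        return self.slope * self.linker_n + self.intercept

    def force_from_delta_r(self, delta_r_nm):
        """Force (pN) from a separation change (nm), per the selected convention."""
        if self.force_model == "printed":
            return delta_r_nm * self.coefficient
        return delta_r_nm / self.coefficient

    def delta_r_from_force(self, force_pN):
        """Inverse of :meth:`force_from_delta_r` (nm from pN)."""
        if self.force_model == "printed":
            return force_pN / self.coefficient
        return force_pN * self.coefficient


def force_from_separations(
    r_TS_nm: float, r_TL_nm: float, N: int = 40, force_model: str = "printed"
) -> float:
    """Mean force from TS and TL separations; negative values clamp to 0.

    Compression is not modelled: r_TS < r_TL yields 0 pN with a warning.
    """
    if r_TS_nm <= 0 or r_TL_nm <= 0:
        raise InvalidParameterError("separations must be positive")
    cal = ForceCalibration(linker_n=N, force_model=force_model)
    f = cal.force_from_delta_r(r_TS_nm - r_TL_nm)
    if f < 0:
        warnings.warn("r_TS < r_TL implies compression; force clamped to 0", stacklevel=2)
        return 0.0
    return float(f)


def separation_from_force(force_pN: float, calibration: ForceCalibration) -> float:
    """TS separation implied by a force, given the calibration's r_TL (nm)."""
    if calibration.r_TL_nm is None:
        raise ConfigurationError("calibration.r_TL_nm is required to invert the force chain")
    return calibration.r_TL_nm + float(calibration.delta_r_from_force(force_pN))


def lifetime_from_force(
    force_pN: float,
    pair: FluorophorePair,
    calibration: ForceCalibration,
    bystander_gamma_ns: float = 0.0,
) -> float:
    """Exact forward model force -> separation -> transfer rate -> lifetime (ns).

    This is the inverse of the :func:`pixel_force_map` chain and is what the
    synthetic tension scenes use to turn ground-truth forces into decays.
    """
    r = separation_from_force(force_pN, calibration)
    if r <= 0:
        raise InvalidParameterError(
            f"force {force_pN} pN implies non-positive separation {r} nm"
        )
    gamma = cascade.rate_from_separation(r, pair.tau_D_ns, pair.R0_nm)
    E = cascade.efficiency_from_rate(gamma, pair.tau_D_ns)
    if not 0.0 < E < 1.0:
        raise InvalidParameterError(
            f"force {force_pN} pN implies FRET efficiency {E} outside (0, 1) "
            f"(r = {r} nm, R0 = {pair.R0_nm} nm)"
        )
    return cascade.lifetime_from_rates(pair.tau_D_ns, [gamma, bystander_gamma_ns])


@dataclass
class ForceMap:
    """Per-pixel tension values with mask and provenance.

    ``force_pN`` is NaN outside the mask and at no-FRET sentinel pixels;
    clamped (compression) pixels hold 0 and are counted.
    """

    force_pN: np.ndarray
    mask: np.ndarray
    n_no_fret: int
    n_clamped: int
    provenance: dict

    @property
    def valid(self) -> np.ndarray:
        return self.mask & np.isfinite(self.force_pN)

    @property
    def mean_force_pN(self) -> float:
        v = self.force_pN[self.valid]
        if v.size == 0:
            raise InsufficientDataError("no valid pixels in force map")
        return float(v.mean())

    def values(self) -> np.ndarray:
        """Valid per-pixel forces (1-D), for histogramming."""
        return self.force_pN[self.valid]


def pixel_force_map(
    lifetime_map_ns: np.ndarray,
    pair: FluorophorePair,
    calibration: ForceCalibration,
    bystander_gamma_ns: float | np.ndarray = 0.0,
    mask: np.ndarray | None = None,
) -> ForceMap:
    """Convert a per-pixel donor lifetime map into a force map.

    Chain per pixel: Gamma_total = 1/tau - 1/tau_D; subtract the bystander
    rate; pixels with no remaining FRET (Gamma <= 0) become NaN sentinels and
    are excluded from downstream histograms; efficiency -> separation ->
    force, clamping compression to 0 pN with a counter.
    """
    tau = np.asarray(lifetime_map_ns, dtype=float)
    if calibration.r_TL_nm is None:
        raise ConfigurationError("calibration.r_TL_nm is required for force mapping")
    if mask is None:
        mask = np.isfinite(tau) & (tau > 0)
    mask = np.asarray(mask, dtype=bool)
    by = np.broadcast_to(np.asarray(bystander_gamma_ns, dtype=float), tau.shape)

    k_d = 1.0 / pair.tau_D_ns
    force = np.full(tau.shape, np.nan)
    ok = mask & np.isfinite(tau) & (tau > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(ok, 1.0 / np.where(ok, tau, 1.0) - k_d, np.nan) - by
        no_fret = ok & ~(gamma > 0)
        fret = ok & (gamma > 0)
        E = gamma / (gamma + k_d)
        r = pair.R0_nm * ((1.0 - E) / E) ** (1.0 / 6.0)
        f = calibration.force_from_delta_r(r - calibration.r_TL_nm)
    clamped = fret & (f < -1e-9)  # tolerance excludes pure round-off at F = 0
    force[fret] = np.where(f[fret] < 0, 0.0, f[fret])
    return ForceMap(
        force_pN=force,
        mask=mask,
        n_no_fret=int(no_fret.sum()),
        n_clamped=int(clamped.sum()),
        provenance={
            "pair": f"{pair.donor}-{pair.acceptor}",
            "tau_D_ns": pair.tau_D_ns,
            "R0_nm": pair.R0_nm,
            "r_TL_nm": calibration.r_TL_nm,
            "linker_n": calibration.linker_n,
            "force_model": calibration.force_model,
            "bystander_correction_applied": bool(np.any(by > 0)),
        },
    )


@dataclass
class BimodalFit:
    """Two-Gaussian model A1 exp(-(x-x1)^2/2 s1^2) + A2 exp(-(x-x2)^2/2 s2^2)
    fitted to a binned density; components ordered by mean."""

    x1: float
    sigma1: float
    A1: float
    x2: float
    sigma2: float
    A2: float
    residual_norm: float
    converged: bool
    single_mean: float
    single_sigma: float
    single_A: float
    single_residual_norm: float
    message: str = ""

    @property
    def effectively_unimodal(self) -> bool:
        """True when the two components are too close to resolve or one
        carries a negligible share of the total area."""
        a1, a2 = self.A1 * self.sigma1, self.A2 * self.sigma2
        if a1 + a2 > 0 and min(a1, a2) / (a1 + a2) < 0.05:
            return True
        pooled = 0.5 * (self.sigma1 + self.sigma2)
        return abs(self.x2 - self.x1) < 0.25 * pooled

    def as_dict(self) -> dict:
        return {
            "x1": self.x1, "sigma1": self.sigma1, "A1": self.A1,
            "x2": self.x2, "sigma2": self.sigma2, "A2": self.A2,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "effectively_unimodal": self.effectively_unimodal,
        }


def area_weights(A1: float, sigma1: float, A2: float, sigma2: float) -> tuple[float, float]:
    """Normalised mixture weights proportional to Gaussian area A * sigma.

    Published bimodal fit amplitudes are of unnormalised Gaussians; the area
    of each component is A * sigma * sqrt(2 pi), so relative occupancies are
    proportional to A * sigma.
    """
    w1, w2 = A1 * sigma1, A2 * sigma2
    t = w1 + w2
    if t <= 0:
        raise InvalidParameterError("component areas must be positive")
    return w1 / t, w2 / t


def _two_gauss(p: np.ndarray, x: np.ndarray) -> np.ndarray:
    x1, s1, a1, x2, s2, a2 = p
    return a1 * np.exp(-0.5 * ((x - x1) / s1) ** 2) + a2 * np.exp(-0.5 * ((x - x2) / s2) ** 2)


def _kmeans2(v: np.ndarray, n_iter: int = 25) -> tuple[float, float]:
    c1, c2 = np.quantile(v, [0.25, 0.75])
    for _ in range(n_iter):
        assign = np.abs(v - c1) <= np.abs(v - c2)
        if assign.all() or (~assign).all():
            break
        n1, n2 = v[assign].mean(), v[~assign].mean()
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    return float(c1), float(c2)


def fit_bimodal(
    values: Sequence[float],
    weights: Sequence[float] | None = None,
    bins: int | str = "fd",
    min_entries: int = 50,
) -> BimodalFit:
    """Fit a two-Gaussian population model to a histogram of values.

    The histogram is binned with the Freedman-Diaconis rule by default and the
    model is fitted to the density (so the bin choice is second-order).
    Several starting points are tried (quantile pair, 1-D two-means split,
    perturbed single Gaussian); the best residual wins.  A single-Gaussian fit
    is reported alongside for comparison.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < min_entries:
        raise InsufficientDataError(f"need >= {min_entries} entries, got {v.size}")
    edges = np.histogram_bin_edges(v, bins=bins)
    if len(edges) - 1 < 10:
        edges = np.histogram_bin_edges(v, bins=10)
    dens, edges = np.histogram(v, bins=edges, weights=weights, density=True)
    x = 0.5 * (edges[:-1] + edges[1:])
    span = v.max() - v.min()
    if span <= 0:
        raise InsufficientDataError("values span a single point; nothing to fit")
    s_lo = 0.25 * (edges[1] - edges[0])
    peak = dens.max()

    mu, sd = float(v.mean()), float(v.std())
    sd = max(sd, s_lo)

    # single-Gaussian reference fit
    def _one(p):
        return p[2] * np.exp(-0.5 * ((x - p[0]) / p[1]) ** 2) - dens

    res1 = least_squares(
        _one, x0=[mu, sd, peak],
        bounds=([v.min(), s_lo, 0.0], [v.max(), 2 * span + s_lo, 10 * peak + 1e-12]),
    )
    single = res1.x

    q25, q75 = np.quantile(v, [0.25, 0.75])
    km1, km2 = _kmeans2(v)
    starts = [
        [q25, sd / 2, peak, q75, sd / 2, peak],
        [km1, sd / 2, peak, km2, sd / 2, peak],
        [mu - 0.5 * sd, sd / 2, peak, mu + 0.5 * sd, sd / 2, peak],
    ]
    lb = [v.min(), s_lo, 0.0, v.min(), s_lo, 0.0]
    ub = [v.max(), 2 * span + s_lo, 10 * peak + 1e-12, v.max(), 2 * span + s_lo, 10 * peak + 1e-12]

    best = None
    message = ""
    for p0 in starts:
        p0 = np.clip(p0, lb, ub)
        try:
            res = least_squares(lambda p: _two_gauss(p, x) - dens, x0=p0, bounds=(lb, ub))
        except Exception as exc:  # pragma: no cover - defensive
            message = str(exc)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return BimodalFit(
            x1=np.nan, sigma1=np.nan, A1=np.nan, x2=np.nan, sigma2=np.nan, A2=np.nan,
            residual_norm=np.inf, converged=False,
            single_mean=single[0], single_sigma=single[1], single_A=single[2],
            single_residual_norm=float(np.linalg.norm(res1.fun)),
            message=message or "all starts failed",
        )
    p = best.x
    c1, c2 = (p[0], p[1], p[2]), (p[3], p[4], p[5])
    # order by mean, ties broken by smaller sigma first
    if (c2[0], c2[1]) < (c1[0], c1[1]):
        c1, c2 = c2, c1
    return BimodalFit(
        x1=float(c1[0]), sigma1=float(c1[1]), A1=float(c1[2]),
        x2=float(c2[0]), sigma2=float(c2[1]), A2=float(c2[2]),
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
        single_mean=float(single[0]), single_sigma=float(single[1]), single_A=float(single[2]),
        single_residual_norm=float(np.linalg.norm(res1.fun)),
    )
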