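"""FRET-cascade rate algebra.

The measured donor lifetime in the presence of FRET satisfies

    1/tau_DA = Gamma_DA + 1/tau_D

where Gamma_DA is the energy-transfer rate and tau_D the intrinsic donor
lifetime.  Pairwise efficiency is E = Gamma / (Gamma + 1/tau_D); with several
acceptors the transfer rates add, so the total efficiency of a donor with n
acceptors is E = sum(Gamma_j) / (sum(Gamma_j) + 1/tau_D).  Distances follow
from Gamma = (1/tau_D) (R0 / r)^6, the sixth-power Förster law.

All rates are kept in ns^-1 internally; conversion to s^-1 happens only at
I/O boundaries (``NS_TO_S``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import InconsistentMeasurementError, InvalidParameterError, NoFretWarning

__all__ = [
    "NS_TO_S",
    "FluorophorePair",
    "RateDecomposition",
    "rate_from_lifetime",
    "transfer_rate",
    "efficiency_from_lifetimes",
    "efficiency_from_rate",
    "total_efficiency",
    "separation_from_rate",
    "separation_from_efficiency",
    "rate_from_separation",
    "lifetime_from_rates",
    "predict_cascade_lifetime",
    "consistency_difference",
    "correct_for_bystander",
]

NS_TO_S = 1e9  # multiply a ns^-1 rate by this to print s^-1

_ADDITIVITY_TOL = 1e-12


@dataclass(frozen=True)
class FluorophorePair:
    """A donor/acceptor pair with its intrinsic donor lifetime and Förster radius.

    ``kappa2`` (orientation factor, 2/3 in the dynamic isotropic limit) is
    metadata only: ``R0_nm`` is consumed as given, never recomputed from it.
    """

    donor: str
    acceptor: str
    tau_D_ns: float
    R0_nm: float
    kappa2: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.tau_D_ns <= 0:
            raise InvalidParameterError(f"tau_D must be positive, got {self.tau_D_ns}")
        if self.R0_nm <= 0:
            raise InvalidParameterError(f"R0 must be positive, got {self.R0_nm}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.donor, self.acceptor)


@dataclass(frozen=True)
class RateDecomposition:
    """Intrinsic rate plus per-acceptor transfer rates for one donor (ns^-1)."""

    donor: str
    k_intrinsic: float
    transfers: tuple[tuple[str, float], ...]
    K_total: float

    def __post_init__(self) -> None:
        if self.k_intrinsic <= 0:
            raise InvalidParameterError("k_intrinsic must be positive")
        for name, g in self.transfers:
            if g < 0:
                raise InvalidParameterError(f"transfer rate for {name} is negative")
        if abs(self.K_total - self.k_intrinsic - self.gamma_sum) > _ADDITIVITY_TOL:
            raise InvalidParameterError("K_total != k_intrinsic + sum(Gamma) beyond tolerance")

    @property
    def gamma_sum(self) -> float:
        return sum(g for _, g in self.transfers)

    @property
    def tau_DA_ns(self) -> float:
        return 1.0 / self.K_total

    @classmethod
    def from_rates(cls, donor: str, tau_D_ns: float, transfers: dict[str, float]) -> "RateDecomposition":
        k = rate_from_lifetime(tau_D_ns)
        items = tuple(sorted(transfers.items()))
        return cls(donor=donor, k_intrinsic=k, transfers=items, K_total=k + sum(transfers.values()))

    @classmethod
    def from_lifetimes(cls, donor: str, tau_D_ns: float, pair_lifetimes: dict[str, float]) -> "RateDecomposition":
        """Decompose from the donor lifetime measured with each acceptor alone."""
        transfers = {a: transfer_rate(t, tau_D_ns) for a, t in pair_lifetimes.items()}
        return cls.from_rates(donor, tau_D_ns, transfers)


def rate_from_lifetime(tau_ns: float) -> float:
    """Total excited-state depopulation rate 1/tau (ns^-1)."""
    if tau_ns <= 0:
        raise InvalidParameterError(f"lifetime must be positive, got {tau_ns}")
    return 1.0 / tau_ns


def transfer_rate(tau_DA_ns: float, tau_D_ns: float, clamp_negative: bool = True) -> float:
    """FRET transfer rate Gamma = 1/tau_DA - 1/tau_D (ns^-1).

    Measurement noise can give tau_DA > tau_D; the negative rate is clamped to
    0 with a :class:`NoFretWarning` rather than raising, since this occurs in
    real per-cell data.
    """
    gamma = rate_from_lifetime(tau_DA_ns) - rate_from_lifetime(tau_D_ns)
    if gamma < 0 and clamp_negative:
        warnings.warn(
            f"tau_DA ({tau_DA_ns} ns) exceeds tau_D ({tau_D_ns} ns); clamping Gamma to 0",
            NoFretWarning,
            stacklevel=2,
        )
        return 0.0
    return gamma


def efficiency_from_lifetimes(tau_DA_ns: float, tau_D_ns: float) -> float:
    """Pairwise FRET efficiency E = 1 - tau_DA/tau_D, clamped to [0, 1)."""
    if tau_DA_ns <= 0 or tau_D_ns <= 0:
        raise InvalidParameterError("lifetimes must be positive")
    return min(max(1.0 - tau_DA_ns / tau_D_ns, 0.0), math.nextafter(1.0, 0.0))


def efficiency_from_rate(gamma_ns: float, tau_D_ns: float) -> float:
    """E = Gamma / (Gamma + 1/tau_D) for a single transfer rate."""
    return total_efficiency([gamma_ns], tau_D_ns)


def total_efficiency(gammas_ns, tau_D_ns: float) -> float:
    """Total efficiency of one donor transferring to n acceptors.

    E = sum(Gamma_j) / (sum(Gamma_j) + 1/tau_D); reduces to the pairwise
    expression for a single rate.
    """
    gs = list(gammas_ns)
    if any(g < 0 for g in gs):
        raise InvalidParameterError("transfer rates must be >= 0")
    k = rate_from_lifetime(tau_D_ns)
    s = sum(gs)
    return s / (s + k)


def separation_from_rate(gamma_ns: float, tau_D_ns: float, R0_nm: float) -> float:
    """Donor-acceptor separation from a transfer rate via the sixth-power law.

    r = R0 * (1 / (Gamma * tau_D))^(1/6).  A non-positive rate means no
    measurable coupling and returns ``inf`` rather than raising.
    """
    if tau_D_ns <= 0 or R0_nm <= 0:
        raise InvalidParameterError("tau_D and R0 must be positive")
    if gamma_ns <= 0:
        return math.inf
    return R0_nm * (1.0 / (gamma_ns * tau_D_ns)) ** (1.0 / 6.0)


def separation_from_efficiency(E: float, R0_nm: float) -> float:
    """r = R0 * ((1 - E) / E)^(1/6); strictly decreasing in E, r(0.5) = R0."""
    if not 0.0 < E < 1.0:
        raise InvalidParameterError(f"efficiency must be in (0, 1), got {E}")
    if R0_nm <= 0:
        raise InvalidParameterError("R0 must be positive")
    return R0_nm * ((1.0 - E) / E) ** (1.0 / 6.0)


def rate_from_separation(r_nm: float, tau_D_ns: float, R0_nm: float) -> float:
    """Forward Förster law Gamma = (1/tau_D) * (R0/r)^6 (ns^-1)."""
    if r_nm <= 0:
        raise InvalidParameterError("separation must be positive")
    return rate_from_lifetime(tau_D_ns) * (R0_nm / r_nm) ** 6


def lifetime_from_rates(tau_D_ns: float, gammas_ns) -> float:
    """Donor lifetime with the given transfer pathways: 1/(1/tau_D + sum Gamma)."""
    gs = list(gammas_ns)
    if any(g < 0 for g in gs):
        raise InvalidParameterError("transfer rates must be >= 0")
    return 1.0 / (rate_from_lifetime(tau_D_ns) + sum(gs))


def predict_cascade_lifetime(tau_D_ns: float, pairwise_taus_ns) -> tuple[float, float]:
    """Predict the multi-acceptor donor lifetime from pairwise measurements.

    Each pairwise lifetime contributes Gamma = 1/tau_pair - 1/tau_D; by
    rate additivity K_calc = 1/tau_D + sum(Gamma) and tau_pred = 1/K_calc.
    Returns ``(K_calc ns^-1, tau_pred ns)``.
    """
    k = rate_from_lifetime(tau_D_ns)
    K_calc = k + sum(transfer_rate(t, tau_D_ns) for t in pairwise_taus_ns)
    return K_calc, 1.0 / K_calc


def consistency_difference(K_calc_ns: float, tau_measured_ns: float) -> float:
    """Percent difference between the calculated and measured total rates.

    100 * (K_calc - 1/tau_measured) / K_calc.
    """
    if K_calc_ns <= 0:
        raise InvalidParameterError("K_calc must be positive")
    return 100.0 * (K_calc_ns - rate_from_lifetime(tau_measured_ns)) / K_calc_ns


def correct_for_bystander(
    K_total_ns: float, tau_D_ns: float, gamma_bystander_ns: float
) -> tuple[float, float, list[str]]:
    """Remove a bystander acceptor's transfer rate from a total decay rate.

    Given the measured total rate K_total = 1/tau_D + Gamma_primary +
    Gamma_bystander, returns ``(Gamma_primary, E_primary, warnings)`` where
    E_primary = Gamma_primary / (Gamma_primary + 1/tau_D).  A negative
    remainder is clamped to 0 with a warning entry.
    """
    if gamma_bystander_ns < 0:
        raise InvalidParameterError("bystander rate must be >= 0")
    k = rate_from_lifetime(tau_D_ns)
    if K_total_ns < k:
        raise InconsistentMeasurementError(
            f"K_total ({K_total_ns} ns^-1) is below the intrinsic rate 1/tau_D ({k} ns^-1)"
        )
    gamma_primary = K_total_ns - k - gamma_bystander_ns
    notes: list[str] = []
    if gamma_primary < 0:
        notes.append(
            f"bystander rate {gamma_bystander_ns} ns^-1 exceeds the total FRET rate "
            f"{K_total_ns - k} ns^-1; primary rate clamped to 0"
        )
        gamma_primary = 0.0
    return gamma_primary, efficiency_from_rate(gamma_primary, tau_D_ns), notes
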