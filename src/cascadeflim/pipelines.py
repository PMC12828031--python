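"""The two headline analysis pipelines.

``run_construct_pipeline`` characterises a three-colour FRET-cascade
construct: from the donor lifetimes measured in each control construct it
builds the energy-transfer-rate decomposition, predicts the three-colour
lifetime by rate additivity, checks it against the measured one, extracts
pairwise separations via the Förster law, and reconstructs the fluorophore
triangle.

``run_tension_pipeline`` analyses a tension-sensor experiment: per-pixel
lifetime fits of TS (tension) and TL (no-tension control) FLIM stacks,
per-cell mean lifetimes, a measured no-tension reference separation, per-pixel
force maps (optionally bystander-corrected), population statistics, and a
bimodal two-population fit of the pooled force histogram.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cascade as casc
from .cascade import NS_TO_S, FluorophorePair
from .decay import DecayHistogram
from .errors import ConfigurationError, MissingConditionError
from .fitting import FitOptions, aggregate_condition, fit_decay, fit_stack
from .forces import BimodalFit, ForceCalibration, ForceMap, fit_bimodal, pixel_force_map
from .geometry import TriangleGeometry, triangle_from_separations

logger = logging.getLogger("cascadeflim")

__all__ = [
    "ConstructReport",
    "TensionReport",
    "run_construct_pipeline",
    "run_tension_pipeline",
    "REQUIRED_CONSTRUCT_CONDITIONS",
]

# condition roles for the construct pipeline; donor/mid/far are the first,
# intermediate and terminal fluorophores of the cascade
REQUIRED_CONSTRUCT_CONDITIONS = ("donor", "donor_mid", "donor_dark_far", "three_colour_donor")
OPTIONAL_CONSTRUCT_CONDITIONS = ("mid", "mid_far", "three_colour_mid")


def _condition_lifetime(value, options: FitOptions) -> float:
    """A condition may be a lifetime (ns), one decay histogram, or a list of
    per-cell histograms (fitted then averaged with equal cell weights)."""
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, DecayHistogram):
        return fit_decay(value, n_components=1, options=options).tau_intensity_weighted
    taus = [fit_decay(h, n_components=1, options=options).tau_intensity_weighted for h in value]
    return aggregate_condition(taus).mean


@dataclass
class ConstructReport:
    """Rates, efficiencies/separations and geometry for one cascade construct."""

    names: tuple[str, str, str]
    lifetimes_ns: dict[str, float]
    rates_table: pd.DataFrame  # Table-2 style: K and Gamma rows in s^-1
    efficiency_table: pd.DataFrame  # Table-1 style: E, R0, R per pair
    K_calc_per_ns: float
    tau_predicted_ns: float
    difference_pct: float | None
    separations_nm: dict[str, float]
    geometry: TriangleGeometry | None
    warnings: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rates_table.to_csv(out / "energy_transfer_rates.csv", index=False)
        self.efficiency_table.to_csv(out / "efficiencies_separations.csv", index=False)
        geom = None
        if self.geometry is not None:
            geom = {
                "vertices": list(self.geometry.vertices),
                "sides_nm": list(self.geometry.sides_nm),
                "angles_deg": list(self.geometry.angles_deg),
                "degenerate": self.geometry.degenerate,
            }
        (out / "construct_report.json").write_text(
            json.dumps(
                {
                    "names": list(self.names),
                    "lifetimes_ns": self.lifetimes_ns,
                    "K_calc_per_s": self.K_calc_per_ns * NS_TO_S,
                    "tau_predicted_ns": self.tau_predicted_ns,
                    "difference_pct": self.difference_pct,
                    "separations_nm": self.separations_nm,
                    "geometry": geom,
                    "warnings": self.warnings,
                },
                indent=2,
            )
        )


def run_construct_pipeline(
    conditions: Mapping[str, object],
    pairs: Mapping[tuple[str, str], FluorophorePair],
    names: tuple[str, str, str],
    fit_options: FitOptions = FitOptions(),
    out_dir=None,
) -> ConstructReport:
    """Characterise a three-colour cascade from its control-construct lifetimes.

    ``conditions`` maps condition roles to lifetimes (ns), decay histograms,
    or lists of per-cell histograms.  Required roles: ``donor`` (donor alone),
    ``donor_mid`` (pairwise with the intermediate), ``donor_dark_far``
    (dark-intermediate construct: donor transfers to the far acceptor only)
    and ``three_colour_donor`` (donor in the full construct).  Optional:
    ``mid``, ``mid_far`` and ``three_colour_mid`` for the second cascade step.
    ``names`` are the (donor, intermediate, far) fluorophore names used to
    look up pair parameters.
    """
    missing = [c for c in REQUIRED_CONSTRUCT_CONDITIONS if c not in conditions]
    if missing:
        raise MissingConditionError(f"missing construct condition(s): {missing}")
    donor, mid, far = names
    taus = {role: _condition_lifetime(v, fit_options) for role, v in conditions.items()}

    def pair(d, a) -> FluorophorePair:
        try:
            return pairs[(d, a)]
        except KeyError:
            raise ConfigurationError(f"no FluorophorePair parameters for ({d}, {a})") from None

    tau_D = taus["donor"]
    notes: list[str] = []

    gamma_mid = casc.transfer_rate(taus["donor_mid"], tau_D)
    gamma_far = casc.transfer_rate(taus["donor_dark_far"], tau_D)
    K_calc, tau_pred = casc.predict_cascade_lifetime(
        tau_D, [taus["donor_mid"], taus["donor_dark_far"]]
    )
    diff_pct = casc.consistency_difference(K_calc, taus["three_colour_donor"])

    rate_rows = [
        {"label": f"K_{donor}", "rate_per_s": 1.0 / tau_D * NS_TO_S, "lifetime_ns": tau_D},
        {"label": f"K_{donor}-{mid}", "rate_per_s": 1.0 / taus["donor_mid"] * NS_TO_S,
         "lifetime_ns": taus["donor_mid"]},
        {"label": f"Gamma_{donor}-{mid}", "rate_per_s": gamma_mid * NS_TO_S,
         "lifetime_ns": (1.0 / gamma_mid if gamma_mid > 0 else np.inf)},
        {"label": f"K_{donor}-dark({mid})-{far}", "rate_per_s": 1.0 / taus["donor_dark_far"] * NS_TO_S,
         "lifetime_ns": taus["donor_dark_far"]},
        {"label": f"Gamma_{donor}-{far}", "rate_per_s": gamma_far * NS_TO_S,
         "lifetime_ns": (1.0 / gamma_far if gamma_far > 0 else np.inf)},
        {"label": f"K_{donor}-{mid}-{far} calculated", "rate_per_s": K_calc * NS_TO_S,
         "lifetime_ns": tau_pred},
        {"label": f"K_{donor}-{mid}-{far} measured",
         "rate_per_s": 1.0 / taus["three_colour_donor"] * NS_TO_S,
         "lifetime_ns": taus["three_colour_donor"]},
        {"label": "difference_pct", "rate_per_s": diff_pct, "lifetime_ns": np.nan},
    ]
    # the "lifetime" attached to a Gamma row is 1/Gamma: a transfer time, not
    # a physical fluorescence lifetime
    rates_table = pd.DataFrame(rate_rows).rename(columns={"lifetime_ns": "transfer_or_lifetime_ns"})

    eff_rows = []
    separations: dict[str, float] = {}

    def add_pair(label, d, a, tau_da, tau_d_ref):
        E = casc.efficiency_from_lifetimes(tau_da, tau_d_ref)
        p = pair(d, a)
        r = casc.separation_from_efficiency(E, p.R0_nm) if 0 < E < 1 else np.inf
        eff_rows.append({"pair": label, "tau_ns": tau_da, "E_pct": 100 * E,
                         "R0_nm": p.R0_nm, "R_nm": r})
        separations[f"{d}-{a}"] = r

    add_pair(f"{donor}-{mid}", donor, mid, taus["donor_mid"], tau_D)
    add_pair(f"{donor}-dark({mid})-{far}", donor, far, taus["donor_dark_far"], tau_D)
    if "mid" in taus and "three_colour_mid" in taus:
        add_pair(f"{mid}-{far} (in cascade)", mid, far, taus["three_colour_mid"], taus["mid"])
    elif "mid" in taus and "mid_far" in taus:
        add_pair(f"{mid}-{far}", mid, far, taus["mid_far"], taus["mid"])
    efficiency_table = pd.DataFrame(eff_rows)

    geometry = None
    r_nm = separations.get(f"{donor}-{mid}")
    r_nc = separations.get(f"{donor}-{far}")
    r_mc = separations.get(f"{mid}-{far}")
    if all(r is not None and np.isfinite(r) for r in (r_nm, r_mc, r_nc)):
        try:
            geometry = triangle_from_separations(r_nm, r_mc, r_nc, vertices=names)
        except Exception as exc:
            notes.append(f"triangle reconstruction failed: {exc}")

    report = ConstructReport(
        names=names,
        lifetimes_ns={k: float(v) for k, v in sorted(taus.items())},
        rates_table=rates_table,
        efficiency_table=efficiency_table,
        K_calc_per_ns=K_calc,
        tau_predicted_ns=tau_pred,
        difference_pct=diff_pct,
        separations_nm=separations,
        geometry=geometry,
        warnings=notes,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


@dataclass
class TensionReport:
    """Per-cell and population tension results for one condition set."""

    r_TL_nm: float
    tau_TL_cells_ns: list[float]
    tau_TS_cells_ns: list[float]
    cell_forces_pN: list[float]
    population_force_pN: float
    population_force_sem_pN: float
    force_maps: list[ForceMap]
    bimodal: BimodalFit | None
    corrected: "TensionReport | None" = None
    calibration: ForceCalibration | None = None

    def pooled_forces(self) -> np.ndarray:
        if not self.force_maps:
            return np.empty(0)
        return np.concatenate([fm.values() for fm in self.force_maps])

    def write(self, out_dir, prefix: str = "tension") -> None:
        from .io import write_map_tiff

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "cell_id": np.arange(len(self.cell_forces_pN)),
                "tau_ns": self.tau_TS_cells_ns,
                "F_pN": self.cell_forces_pN,
            }
        ).to_csv(out / f"{prefix}_per_cell.csv", index=False)
        pooled = self.pooled_forces()
        if pooled.size:
            counts, edges = np.histogram(pooled, bins="fd")
            pd.DataFrame(
                {"F_pN": 0.5 * (edges[:-1] + edges[1:]), "count": counts}
            ).to_csv(out / f"{prefix}_force_histogram.csv", index=False)
        for i, fm in enumerate(self.force_maps):
            write_map_tiff(out / f"{prefix}_force_map_cell{i}.tif", fm.force_pN)
        summary = {
            "r_TL_nm": self.r_TL_nm,
            "population_force_pN": self.population_force_pN,
            "population_force_sem_pN": self.population_force_sem_pN,
            "n_cells": len(self.cell_forces_pN),
            "bimodal": self.bimodal.as_dict() if self.bimodal else None,
        }
        (out / f"{prefix}_summary.json").write_text(json.dumps(summary, indent=2))
        if self.force_maps:
            _render_force_png(self.force_maps[0], out / f"{prefix}_force_map_cell0.png")
        if self.corrected is not None:
            self.corrected.write(out_dir, prefix=f"{prefix}_corrected")


def _render_force_png(fm: ForceMap, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(fm.force_pN, cmap="inferno")
    fig.colorbar(im, ax=ax, label="force (pN)")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _cells_to_lifetimes(
    cells: Sequence[tuple[np.ndarray, np.ndarray | None]],
    period_ns: float,
    fit_options: FitOptions,
    photon_threshold: int,
):
    """Fit each cell's stack; returns (list of StackFitResult, per-cell tau)."""
    results, taus = [], []
    for stack, mask in cells:
        res = fit_stack(
            stack, period_ns, mask=mask, n_components=1,
            photon_threshold=photon_threshold, options=fit_options,
        )
        results.append(res)
        taus.append(res.cell_mean_lifetime().tau_ns)
    return results, taus


def run_tension_pipeline(
    ts_cells: Sequence[tuple[np.ndarray, np.ndarray | None]],
    tl_cells: Sequence[tuple[np.ndarray, np.ndarray | None]],
    pair: FluorophorePair,
    period_ns: float = 12.5,
    linker_n: int = 40,
    force_model: str = "printed",
    bystander_gamma_ns: float | None = None,
    fit_options: FitOptions = FitOptions(),
    photon_threshold: int = 300,
    min_bimodal_entries: int = 50,
    out_dir=None,
) -> TensionReport:
    """Full tension-sensor analysis from TS and TL FLIM stacks.

    Each cell is one ``(stack, mask)`` pair, stack shaped (n_bins, rows, cols).
    The no-tension reference separation is the mean over TL cells of the
    separation implied by each cell's photon-weighted mean lifetime.  When
    ``bystander_gamma_ns`` is given the corrected chain is run as well and
    attached as ``report.corrected`` (the uncorrected result remains the
    primary return, mirroring how both are reported side by side).
    """
    if not tl_cells:
        raise MissingConditionError("TL (no-tension control) condition is required for calibration")
    if not ts_cells:
        raise MissingConditionError("TS condition is required")

    _, tau_tl_cells = _cells_to_lifetimes(tl_cells, period_ns, fit_options, photon_threshold)
    r_tl_cells = []
    for tau in tau_tl_cells:
        gamma = casc.transfer_rate(tau, pair.tau_D_ns)
        r_tl_cells.append(casc.separation_from_rate(gamma, pair.tau_D_ns, pair.R0_nm))
    r_tl = float(np.mean(r_tl_cells))
    calibration = ForceCalibration(
        linker_n=linker_n, force_model=force_model, r_TL_nm=r_tl
    )
    logger.info("tension pipeline: r_TL = %.3f nm from %d TL cells", r_tl, len(tl_cells))

    ts_results, tau_ts_cells = _cells_to_lifetimes(ts_cells, period_ns, fit_options, photon_threshold)

    def build(by_gamma: float) -> TensionReport:
        maps, cell_forces = [], []
        for res in ts_results:
            fm = pixel_force_map(
                res.tau_ns, pair, calibration,
                bystander_gamma_ns=by_gamma,
                mask=np.isfinite(res.tau_ns),
            )
            maps.append(fm)
            cell_forces.append(fm.mean_force_pN)
        summary = aggregate_condition(cell_forces)
        pooled = np.concatenate([fm.values() for fm in maps]) if maps else np.empty(0)
        bimodal = None
        if pooled.size >= min_bimodal_entries:
            bimodal = fit_bimodal(pooled, min_entries=min_bimodal_entries)
        return TensionReport(
            r_TL_nm=r_tl,
            tau_TL_cells_ns=list(tau_tl_cells),
            tau_TS_cells_ns=list(tau_ts_cells),
            cell_forces_pN=cell_forces,
            population_force_pN=summary.mean,
            population_force_sem_pN=summary.sem,
            force_maps=maps,
            bimodal=bimodal,
            calibration=calibration,
        )

    report = build(0.0)
    if bystander_gamma_ns is not None:
        report.corrected = build(bystander_gamma_ns)
    if out_dir is not None:
        report.write(out_dir)
    return report
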