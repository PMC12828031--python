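"""Full tension-sensor round trip: scene -> FLIM stack -> force map.

A synthetic cell with focal-adhesion patches at a uniform 3.0 pN tension is
imaged (10^5 photons/pixel), together with a no-tension (TL) control scene.
The pipeline fits every pixel's lifetime, measures the TL reference
separation, and converts lifetimes to forces via the elastic-linker
calibration.
"""

from cascadeflim import (
    DEFAULT_TS_PAIR,
    DEFAULT_TS_R_TL_NM,
    ForceCalibration,
    run_tension_pipeline,
    simulate_tension_scene,
)

pair = DEFAULT_TS_PAIR
calibration = ForceCalibration(linker_n=40, r_TL_nm=DEFAULT_TS_R_TL_NM)


def make_cells(force_pN, seed):
    scene, stack = simulate_tension_scene(
        pop1=(force_pN, 0.0, 0.5), pop2=(force_pN, 0.0, 0.5),
        pair=pair, calibration=calibration,
        image_shape=(28, 28), photons_per_pixel=1e5, seed=seed,
    )
    return [(stack, scene.adhesion_mask)]


tl_cells = make_cells(0.0, seed=1)
ts_cells = make_cells(3.0, seed=2)
report = run_tension_pipeline(ts_cells, tl_cells, pair, min_bimodal_entries=10**9)

print(f"no-tension reference separation {report.r_TL_nm:.3f} nm "
      f"(generator used {DEFAULT_TS_R_TL_NM} nm)")
print(f"recovered adhesion force {report.population_force_pN:.2f} pN (truth 3.00 pN)")
print(f"{report.force_maps[0].n_no_fret} no-FRET and "
      f"{report.force_maps[0].n_clamped} clamped pixels")
# Recovery within ~5% shows the whole chain -- decay fit, transfer rate,
# Förster-law separation, linker calibration -- inverts consistently.
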