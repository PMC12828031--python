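"""End-to-end pipelines, file formats, configuration and CLI surface."""

import json

import numpy as np
import pandas as pd
import pytest

from cascadeflim import (
    KineticsSpec,
    PipelineConfig,
    run_construct_pipeline,
    run_tension_pipeline,
    separation_from_rate,
    simulate_cascade_ensemble,
    simulate_decay,
    simulate_tension_scene,
    transfer_rate,
)
from cascadeflim.errors import ConfigurationError, MissingConditionError
from cascadeflim.io import (
    load_pair_table,
    read_decay_csv,
    read_flim_stack,
    save_pair_table,
    write_decay_csv,
    write_flim_stack,
)


@pytest.fixture(scope="module")
def table_distances(three_colour_pairs):
    return {
        ("mTurq2", "mVenus"): separation_from_rate(transfer_rate(2.668, 4.178), 4.178, 5.83),
        ("mTurq2", "mScarlet"): separation_from_rate(transfer_rate(3.242, 4.178), 4.178, 5.08),
        ("mVenus", "mScarlet"): separation_from_rate(transfer_rate(2.509, 3.020), 3.020, 5.53),
    }


@pytest.fixture(scope="module")
def noiseless_ensemble(three_colour_pairs, table_distances):
    return simulate_cascade_ensemble(
        three_colour_pairs, table_distances, seed=0, expectation=True
    )


def _conditions(ens):
    return {
        "donor": ens["mTurq2"],
        "donor_mid": ens["mTurq2-mVenus"],
        "donor_dark_far": ens["mTurq2-dark(mVenus)-mScarlet"],
        "three_colour_donor": ens["mTurq2-mVenus-mScarlet"],
        "mid": ens["mVenus"],
        "three_colour_mid": ens["mVenus-mScarlet"],
    }


class TestConstructPipeline:
    def test_rates_reproduced_from_simulated_ensemble(self, noiseless_ensemble, three_colour_pairs):
        report = run_construct_pipeline(
            _conditions(noiseless_ensemble), three_colour_pairs,
            names=("mTurq2", "mVenus", "mScarlet"),
        )
        rates = dict(zip(report.rates_table["label"], report.rates_table["rate_per_s"]))
        assert rates["K_mTurq2"] == pytest.approx(2.39e8, rel=2e-3)
        assert rates["Gamma_mTurq2-mVenus"] == pytest.approx(1.35e8, rel=5e-3)
        assert rates["Gamma_mTurq2-mScarlet"] == pytest.approx(6.91e7, rel=5e-3)
        assert rates["K_mTurq2-mVenus-mScarlet calculated"] == pytest.approx(4.44e8, rel=5e-3)
        assert report.tau_predicted_ns == pytest.approx(2.253, abs=2e-3)
        assert report.geometry is not None
        assert sum(report.geometry.angles_deg) == pytest.approx(180.0, abs=1e-9)

    def test_missing_condition_named(self, noiseless_ensemble, three_colour_pairs):
        conds = _conditions(noiseless_ensemble)
        conds.pop("donor_dark_far")
        with pytest.raises(MissingConditionError, match="donor_dark_far"):
            run_construct_pipeline(conds, three_colour_pairs, names=("mTurq2", "mVenus", "mScarlet"))

    def test_input_order_invariance(self, noiseless_ensemble, three_colour_pairs):
        conds = _conditions(noiseless_ensemble)
        shuffled = dict(reversed(list(conds.items())))
        a = run_construct_pipeline(conds, three_colour_pairs, names=("mTurq2", "mVenus", "mScarlet"))
        b = run_construct_pipeline(shuffled, three_colour_pairs, names=("mTurq2", "mVenus", "mScarlet"))
        pd.testing.assert_frame_equal(a.rates_table, b.rates_table)
        pd.testing.assert_frame_equal(a.efficiency_table, b.efficiency_table)

    def test_scalar_lifetimes_accepted(self, three_colour_pairs):
        report = run_construct_pipeline(
            {"donor": 4.178, "donor_mid": 2.668, "donor_dark_far": 3.242,
             "three_colour_donor": 2.331},
            three_colour_pairs, names=("mTurq2", "mVenus", "mScarlet"),
        )
        assert report.difference_pct == pytest.approx(3.36, abs=5e-3)

    def test_unknown_pair_errors(self, noiseless_ensemble):
        with pytest.raises(ConfigurationError):
            run_construct_pipeline(
                _conditions(noiseless_ensemble), {}, names=("mTurq2", "mVenus", "mScarlet")
            )

    def test_report_written(self, tmp_path, noiseless_ensemble, three_colour_pairs):
        run_construct_pipeline(
            _conditions(noiseless_ensemble), three_colour_pairs,
            names=("mTurq2", "mVenus", "mScarlet"), out_dir=tmp_path,
        )
        assert (tmp_path / "energy_transfer_rates.csv").exists()
        assert json.loads((tmp_path / "construct_report.json").read_text())["difference_pct"] is not None


def _scene_cells(ts_pair, ts_calibration, force, seed, shape=(24, 24), photons=2e4,
                 bystander=0.0):
    scene, stack = simulate_tension_scene(
        pop1=(force, 0.0, 0.5), pop2=(force, 0.0, 0.5),
        pair=ts_pair, calibration=ts_calibration,
        image_shape=shape, photons_per_pixel=photons, seed=seed,
        bystander_gamma_ns=bystander,
    )
    return scene, [(stack, scene.adhesion_mask)]


class TestTensionPipeline:
    def test_ts_equals_tl_gives_zero_force(self, ts_pair, ts_calibration):
        _, tl = _scene_cells(ts_pair, ts_calibration, 0.0, seed=21)
        _, ts = _scene_cells(ts_pair, ts_calibration, 0.0, seed=22)
        report = run_tension_pipeline(ts, tl, ts_pair, min_bimodal_entries=10**9)
        assert report.population_force_pN == pytest.approx(0.0, abs=0.15)

    def test_round_trip_recovers_force(self, ts_pair, ts_calibration):
        _, tl = _scene_cells(ts_pair, ts_calibration, 0.0, seed=31)
        _, ts = _scene_cells(ts_pair, ts_calibration, 3.0, seed=32)
        report = run_tension_pipeline(ts, tl, ts_pair, min_bimodal_entries=10**9)
        assert report.population_force_pN == pytest.approx(3.0, rel=0.10)

    def test_zero_bystander_correction_is_identity(self, ts_pair, ts_calibration):
        _, tl = _scene_cells(ts_pair, ts_calibration, 0.0, seed=41, shape=(16, 16))
        _, ts = _scene_cells(ts_pair, ts_calibration, 2.0, seed=42, shape=(16, 16))
        report = run_tension_pipeline(
            ts, tl, ts_pair, bystander_gamma_ns=0.0, min_bimodal_entries=10**9
        )
        assert report.corrected is not None
        np.testing.assert_array_equal(
            report.force_maps[0].force_pN, report.corrected.force_maps[0].force_pN
        )

    def test_missing_tl_condition(self, ts_pair, ts_calibration):
        _, ts = _scene_cells(ts_pair, ts_calibration, 2.0, seed=5, shape=(16, 16))
        with pytest.raises(MissingConditionError):
            run_tension_pipeline(ts, [], ts_pair)

    def test_end_to_end_determinism(self, tmp_path, ts_pair, ts_calibration):
        _, tl = _scene_cells(ts_pair, ts_calibration, 0.0, seed=51, shape=(16, 16))
        _, ts = _scene_cells(ts_pair, ts_calibration, 2.5, seed=52, shape=(16, 16))
        outs = []
        for name in ("a", "b"):
            out = tmp_path / name
            run_tension_pipeline(ts, tl, ts_pair, min_bimodal_entries=10**9, out_dir=out)
            outs.append((out / "tension_per_cell.csv").read_bytes())
        assert outs[0] == outs[1]


class TestFileFormats:
    def test_decay_csv_round_trip(self, tmp_path):
        hist = simulate_decay(KineticsSpec.mono(3.3), 1e4, seed=0)
        path = tmp_path / "decay.csv"
        write_decay_csv(path, hist)
        back = read_decay_csv(path)
        np.testing.assert_allclose(back.counts, hist.counts)
        assert back.period_ns == pytest.approx(hist.period_ns)

    def test_flim_stack_round_trip(self, tmp_path):
        stack = np.arange(2 * 3 * 4, dtype=np.int64).reshape(4, 2, 3) % 7
        path = tmp_path / "stack.tif"
        write_flim_stack(path, stack, period_ns=12.5)
        back, period = read_flim_stack(path)
        np.testing.assert_array_equal(back, stack)
        assert period == pytest.approx(12.5)

    def test_pair_table_round_trip(self, tmp_path, three_colour_pairs):
        path = tmp_path / "pairs.json"
        save_pair_table(path, three_colour_pairs)
        back = load_pair_table(path)
        assert back == three_colour_pairs

    def test_pair_table_missing_key(self, tmp_path):
        (tmp_path / "bad.json").write_text('[{"donor": "a", "acceptor": "b"}]')
        with pytest.raises(ConfigurationError):
            load_pair_table(tmp_path / "bad.json")


class TestConfig:
    def test_yaml_round_trip_identical(self, tmp_path):
        cfg = PipelineConfig.from_dict(
            {"seed": 7, "acquisition": {"n_bins": 128},
             "calibration": {"linker_n": 40, "r_TL_nm": 4.2},
             "simulate": {"decay": {"total_photons": 1000.0}}}
        )
        p1 = tmp_path / "a.yaml"
        cfg.to_yaml(p1)
        cfg2 = PipelineConfig.from_yaml(p1)
        assert cfg2.to_dict() == cfg.to_dict()
        p2 = tmp_path / "b.yaml"
        cfg2.to_yaml(p2)
        assert p1.read_text() == p2.read_text()

    def test_unknown_keys_rejected(self):
        with pytest.raises(ConfigurationError):
            PipelineConfig.from_dict({"sede": 1})

    def test_non_integer_seed_rejected(self):
        with pytest.raises(ConfigurationError):
            PipelineConfig.from_dict({"seed": "abc"})

    def test_missing_path_flagged(self, tmp_path):
        cfg = PipelineConfig.from_dict({"pair_table": "nope.json"})
        with pytest.raises(ConfigurationError):
            cfg.validate_paths(tmp_path)


class TestCli:
    def test_simulate_and_fit_decay(self, tmp_path):
        from click.testing import CliRunner

        from cascadeflim.cli import main

        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "seed: 3\nsimulate:\n  decay:\n    components: [[1.0, 4.178]]\n"
            "    total_photons: 200000.0\n"
        )
        runner = CliRunner()
        res = runner.invoke(main, ["simulate", "decay", "--config", str(cfg), "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        res = runner.invoke(main, ["fit", "--csv", str(tmp_path / "decay.csv"), "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        fit = json.loads((tmp_path / "fit.json").read_text())
        assert fit["tau_intensity_weighted_ns"] == pytest.approx(4.178, rel=0.02)

    def test_geometry_command(self, tmp_path):
        from click.testing import CliRunner

        from cascadeflim.cli import main

        sides = tmp_path / "sides.csv"
        pd.DataFrame([{"r_NM_nm": 3.0, "r_MC_nm": 4.0, "r_NC_nm": 5.0}]).to_csv(sides, index=False)
        runner = CliRunner()
        res = runner.invoke(main, ["geometry", "--sides", str(sides), "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        geo = json.loads((tmp_path / "geometry.json").read_text())
        assert geo["angles_deg"][1] == pytest.approx(90.0, abs=1e-6)

    def test_run_construct_command(self, tmp_path, three_colour_pairs):
        from click.testing import CliRunner

        from cascadeflim.cli import main

        pairs = tmp_path / "pairs.json"
        save_pair_table(pairs, three_colour_pairs)
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            f"pair_table: {pairs}\n"
            "simulate:\n  construct:\n    names: [mTurq2, mVenus, mScarlet]\n"
            "    conditions:\n      donor: 4.178\n      donor_mid: 2.668\n"
            "      donor_dark_far: 3.242\n      three_colour_donor: 2.331\n"
        )
        runner = CliRunner()
        res = runner.invoke(main, ["run-construct", "--config", str(cfg), "--out", str(tmp_path)])
        assert res.exit_code == 0, res.output
        assert "3.36" in res.output
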