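import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from einet.cli import main as cli_main
from einet.ei_core import NetworkParams, ParameterError, ScalingMode
from einet.experiments import (
    ExperimentSpec,
    StimulusProfile,
    classify_temporal,
    fwhm,
    make_fixtures,
    run_io_sweep,
    run_sustained,
    run_temporal_profiles,
    run_tuning,
    write_run,
)
from einet.lif_sim import LIFParams


class TestStimulusProfile:
    def test_ramp_plateau_ramp_shape(self):
        prof = StimulusProfile(
            shape="ramp_plateau_ramp", steady=0.5, duration_ms=200.0,
            pre_ms=5.0, post_ms=30.0, ramp_ms=20.0,
        )
        pE = prof.pE_t(0.01)
        t = np.arange(len(pE)) * 0.01
        assert pE[t < 5.0].max() == 0.0
        assert pE[(t > 25.0) & (t < 150.0)] == pytest.approx(0.5)
        assert pE[-1] == 0.0
        assert pE.max() == pytest.approx(0.5)

    def test_lag_shifts_inhibition(self):
        prof = StimulusProfile(
            shape="ramp_plateau_ramp", steady=1.0, duration_ms=200.0, lag_ms=2.0
        )
        pE = prof.pE_t(0.01)
        pI = prof.pI_t(0.01)
        shift_bins = int(2.0 / 0.01)
        assert np.allclose(pI[shift_bins:], pE[:-shift_bins])

    def test_lag_out_of_range(self):
        with pytest.raises(ParameterError):
            StimulusProfile(shape="ramp_plateau_ramp", lag_ms=3.0, duration_ms=200.0)

    def test_gaussian_tuning_peak(self):
        prof = StimulusProfile(shape="gaussian_tuning", a=0.35, x_center=1.0, sigma_x=2.0)
        x = np.linspace(-5, 5, 101)
        y = prof.pE_x(x)
        assert y.max() == pytest.approx(0.35)
        assert x[np.argmax(y)] == pytest.approx(1.0, abs=0.1)

    def test_spec_roundtrip(self):
        spec = ExperimentSpec(
            which="fig3_io",
            scaling=ScalingMode.fixed(0.3),
            stimulus=StimulusProfile(shape="constant", steady=0.4),
            trials=10,
            seed=3,
        )
        again = ExperimentSpec.from_dict(json.loads(json.dumps(spec.to_dict())))
        assert again == spec


class TestRunSustained:
    def test_control_rate_near_60(self, lif):
        res = run_sustained(
            NetworkParams(), lif, duration=1000.0, n_trials=20,
            rng_seed=1, pI_override=0.0,
        )
        assert res.mean_rate == pytest.approx(60.0, rel=0.12)

    def test_inhibition_reduces_rate(self, lif):
        p = NetworkParams(pE=0.5, pE_to_I=0.8)
        r0 = run_sustained(p, lif, duration=300.0, n_trials=10, rng_seed=2,
                           pI_override=0.0)
        r1 = run_sustained(p, lif, duration=300.0, n_trials=10, rng_seed=2,
                           scaling=ScalingMode.fixed(0.4))
        assert r1.mean_rate < r0.mean_rate
        assert r1.meta["pI"] == 0.4

    def test_metadata_recorded(self, lif):
        p = NetworkParams(pE=0.5, pE_to_I=0.7)
        res = run_sustained(p, lif, duration=200.0, n_trials=4, rng_seed=2)
        for key in ("pI", "pI_hat_measured", "rI_measured_Hz", "n_trials"):
            assert key in res.meta


class TestTemporalProfiles:
    @staticmethod
    def _spec(steady, lag=0.0, trials=100, seed=7):
        net = NetworkParams(nE=250, nI=250, rI=50.0)
        stim = StimulusProfile(
            shape="ramp_plateau_ramp", steady=steady, duration_ms=260.0,
            pre_ms=5.0, post_ms=30.0, lag_ms=lag,
        )
        return ExperimentSpec(
            which="fig5_temporal", network=net, lif=LIFParams(),
            stimulus=stim, trials=trials, seed=seed,
        )

    def test_moderate_steady_tonic_with_quarter_pnet(self):
        spec = self._spec(0.5, trials=1000)
        out = run_temporal_profiles(spec)
        assert out["pnet_t"].max() == pytest.approx(0.25)
        label = classify_temporal(
            out["result"].psth, out["result"].dt, spec.stimulus, n_trials=1000
        )
        assert label == "tonic"

    def test_full_steady_transients_only(self):
        spec = self._spec(1.0, trials=1200)
        out = run_temporal_profiles(spec)
        # pnet vanishes on the plateau
        k = len(out["pnet_t"]) // 2
        assert out["pnet_t"][k] == 0.0
        label = classify_temporal(
            out["result"].psth, out["result"].dt, spec.stimulus, n_trials=1200
        )
        assert label == "onset_offset"

    def test_lagged_inhibition_onset_only(self):
        spec = self._spec(1.0, lag=2.0, trials=400)
        out = run_temporal_profiles(spec)
        label = classify_temporal(
            out["result"].psth, out["result"].dt, spec.stimulus, n_trials=400
        )
        assert label == "onset_only"

    def test_leading_inhibition_offset_only(self):
        spec = self._spec(1.0, lag=-2.0, trials=400)
        out = run_temporal_profiles(spec)
        label = classify_temporal(
            out["result"].psth, out["result"].dt, spec.stimulus, n_trials=400
        )
        assert label == "offset_only"


class TestTuning:
    @staticmethod
    def _spec(a=0.35, trials=8, seed=3):
        stim = StimulusProfile(shape="gaussian_tuning", a=a, x_center=0.0, sigma_x=1.0)
        return ExperimentSpec(
            which="fig4_tuning", network=NetworkParams(), lif=LIFParams(),
            stimulus=stim, trials=trials, seed=seed,
        )

    def test_mode1_control_peak_near_60(self):
        frame = run_tuning(
            self._spec(trials=12), 1, levels=(0.0,),
            x_grid=np.array([-1.0, 0.0, 1.0]), duration=400.0,
        )
        peak = frame[frame["x"] == 0.0]["rate_Hz"].iloc[0]
        assert peak == pytest.approx(60.0, rel=0.15)

    def test_mode1_amplitude_falls_with_level(self):
        frame = run_tuning(
            self._spec(), 1, levels=(0.0, 0.13),
            x_grid=np.array([0.0]), duration=300.0,
        )
        peaks = frame.groupby("level")["rate_Hz"].max()
        assert peaks[0.13] < peaks[0.0]

    def test_mode2_normalized_curves_superimpose(self):
        frame = run_tuning(
            self._spec(trials=16, seed=5), 2, levels=(0.0, 0.4),
            x_grid=np.linspace(-1.0, 1.0, 5), duration=300.0,
        )
        pivot = frame.pivot(index="x", columns="level", values="rate_norm")
        dev = (pivot[0.4] - pivot[0.0]).abs().max()
        assert dev < 0.25

    def test_mode3_central_dip_with_large_input(self):
        frame = run_tuning(
            self._spec(a=0.9, trials=10, seed=3), 3, levels=(0.9,),
            x_grid=np.linspace(-1.5, 1.5, 7), duration=250.0,
        )
        rates = frame.sort_values("x")["rate_Hz"].to_numpy()
        center = rates[len(rates) // 2]
        flank = max(rates[1], rates[-2])
        assert center < 0.5 * flank  # local minimum at x_center

    def test_fwhm_helper(self):
        x = np.linspace(-3, 3, 301)
        y = np.exp(-(x**2) / 2)
        assert fwhm(x, y) == pytest.approx(2.355, abs=0.02)


class TestIOSweep:
    def test_uninhibited_sweep_matches_theory(self):
        spec = ExperimentSpec(
            which="fig3_io", network=NetworkParams(), lif=LIFParams(),
            scaling=ScalingMode.fixed(0.0), trials=20, seed=13,
        )
        frame = run_io_sweep(spec, pE_grid=[0.4, 0.6, 0.9], duration=300.0)
        osc = frame[frame["regime"] == "oscillatory"]
        assert len(osc) == 3
        rel = (osc["r_sim_Hz"] - osc["r_combined_Hz"]).abs() / osc["r_combined_Hz"]
        assert rel.max() < 0.10

    def test_linear_family_onset_invariant(self):
        # minimum pE for evoked firing stays put as kc varies
        onsets = []
        for kc in (0.2, 0.6):
            spec = ExperimentSpec(
                which="fig3_io",
                network=NetworkParams(rI=50.0, nI=250),
                lif=LIFParams(),
                scaling=ScalingMode.linear(kc), trials=15, seed=13,
            )
            frame = run_io_sweep(
                spec, pE_grid=np.linspace(0.1, 0.9, 9), duration=250.0
            )
            evoked = frame[frame["evoked"]]
            onsets.append(evoked["pE"].min() if len(evoked) else 1.0)
        assert abs(onsets[0] - onsets[1]) < 0.11

    def test_threshold_increases_with_pI(self):
        onsets = []
        for pI in (0.0, 0.5):
            spec = ExperimentSpec(
                which="fig3_io", network=NetworkParams(), lif=LIFParams(),
                scaling=ScalingMode.fixed(pI), trials=15, seed=13,
            )
            frame = run_io_sweep(
                spec, pE_grid=np.linspace(0.1, 0.9, 9), duration=250.0
            )
            evoked = frame[frame["evoked"]]
            onsets.append(evoked["pE"].min() if len(evoked) else 1.0)
        assert onsets[1] > onsets[0]


class TestFixtures:
    def test_bit_identical_regeneration(self, tmp_path):
        a = make_fixtures(11)
        b = make_fixtures(11)
        assert np.array_equal(a["barrage"], b["barrage"])
        assert np.array_equal(a["interneuron_counts"], b["interneuron_counts"])

    def test_barrage_mean_within_5pct(self):
        fx = make_fixtures(11)
        assert fx["barrage"].mean() == pytest.approx(243.6875, rel=0.05)

    def test_transient_histogram_mass(self):
        fx = make_fixtures(11)
        assert fx["arrival_hist"].sum() == pytest.approx(0.8 * 100, rel=1e-6)

    def test_files_written(self, tmp_path):
        make_fixtures(3, out_dir=tmp_path)
        for name in ("barrage.csv", "arrival_hist.csv", "interneuron_counts.csv"):
            assert (tmp_path / name).exists()


class TestWriteRun:
    def test_outputs_and_sidecar(self, tmp_path):
        frame = pd.DataFrame({"a": [1, 2]})
        write_run(tmp_path, "demo", {"table": frame}, {"seed": 5})
        assert (tmp_path / "demo_table.csv").exists()
        meta = json.loads((tmp_path / "demo_meta.json").read_text())
        assert meta["seed"] == 5
        assert "version" in meta
        assert (tmp_path / "demo.log").exists()


class TestCLI:
    def test_simulate_sustained(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "network: {pE: 0.5}\nduration_ms: 150\nscaling: {mode: fixed_pI, pi_fixed: 0.0}\n"
        )
        runner = CliRunner()
        out = tmp_path / "out"
        result = runner.invoke(
            cli_main,
            ["simulate-sustained", "--config", str(cfg), "--trials", "3",
             "--seed", "1", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert (out / "sustained_psth.csv").exists()
        assert (out / "sustained_spikes.csv").exists()
        assert "mean rate" in result.output

    def test_temporal_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "out"
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({
            "network": {"nE": 250, "nI": 250},
            "stimulus": {"shape": "ramp_plateau_ramp", "steady": 0.5,
                         "duration_ms": 150.0},
        }))
        result = runner.invoke(
            cli_main,
            ["temporal", "--config", str(cfg), "--trials", "5",
             "--seed", "2", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert "classification" in result.output

    def test_transient_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "out"
        cfg = tmp_path / "cfg.json"
        cfg.write_text(json.dumps({"network": {"nE": 100, "nI": 10, "pE": 0.8,
                                               "pE_to_I": 0.8}}))
        result = runner.invoke(
            cli_main,
            ["transient", "--config", str(cfg), "--trials", "30",
             "--seed", "2", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert (out / "transient_traces.csv").exists()

    def test_fixtures_command(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["fixtures", "--seed", "4", "--out", str(tmp_path / "fx")]
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "fx" / "barrage.csv").exists()

    def test_io_curve_command(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "out"
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text(
            "scaling: {mode: fixed_pI, pi_fixed: 0.0}\n"
            "pE_grid: [0.5, 0.8]\nduration_ms: 120\n"
        )
        result = runner.invoke(
            cli_main,
            ["io-curve", "--config", str(cfg), "--trials", "3",
             "--seed", "1", "--out", str(out)],
        )
        assert result.exit_code == 0, result.output
        assert (out / "io_curve_table.csv").exists()
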