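"""Configuration round-trips, file formats, and the CLI layer."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from poreqc import EventTable, IonTrace, RunConfig, simulate_event_table
from poreqc.cli import main
from poreqc.detect import Event
from poreqc.io import read_events, read_trace, write_events, write_trace


class TestRunConfig:
    def test_yaml_roundtrip_lossless(self, tmp_path):
        config = RunConfig(
            marker_concentration_pM=100.0,
            geometry=dict(tip_diameter_nm=9.7, half_cone_angle_deg=5.0, conductivity_S_per_m=20.0),
        )
        path = tmp_path / "run.yaml"
        config.to_yaml(path)
        assert RunConfig.from_yaml(path) == config

    def test_content_hash_tracks_content(self):
        a, b = RunConfig(), RunConfig(marker_concentration_pM=99.0)
        assert a.content_hash() == RunConfig().content_hash()
        assert a.content_hash() != b.content_hash()

    def test_unknown_field_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("marker_concentratoin_pM: 100\n")
        with pytest.raises(Exception, match="marker_concentratoin_pM"):
            RunConfig.from_yaml(path)

    def test_inconsistent_cone_rejected(self):
        with pytest.raises(Exception):
            RunConfig(
                geometry=dict(
                    tip_diameter_nm=10.0,
                    half_cone_angle_deg=5.0,
                    taper_length_um=2000.0,
                    conductivity_S_per_m=20.0,
                )
            )


class TestFileFormats:
    def test_trace_text_roundtrip(self, tmp_path):
        trace = IonTrace(
            samples=np.array([5000.0, 4999.5, 4800.25]),
            sampling_rate_hz=1000.0,
            bias_voltage_mV=400.0,
            pore_id="np1",
        )
        path = tmp_path / "trace.tsv"
        write_trace(path, trace)
        back = read_trace(path)
        assert np.allclose(back.samples, trace.samples)
        assert back.sampling_rate_hz == 1000.0
        assert back.pore_id == "np1"

    def test_trace_npz_roundtrip(self, tmp_path):
        trace = IonTrace(
            samples=np.linspace(5000, 4000, 100), sampling_rate_hz=2000.0, pore_id="np2"
        )
        path = tmp_path / "trace.npz"
        write_trace(path, trace)
        back = read_trace(path)
        assert np.array_equal(back.samples, trace.samples)
        assert back.pore_id == "np2"

    def test_events_roundtrip_with_exclusions(self, tmp_path):
        table = EventTable.from_events(
            [Event(1.5, 2e-3, 60.0, "np1"), Event(7.25, 1e-3, 150.0, "np1")],
            effective_duration_s=90.0,
            excluded_intervals=[(10.0, 20.0)],
        )
        path = tmp_path / "events.tsv"
        write_events(path, table)
        back = read_events(path)
        assert back.n_events == 2
        assert back.effective_duration_s == 90.0
        assert back.excluded_intervals == [(10.0, 20.0)]
        assert np.allclose(back.amplitudes(), [60.0, 150.0])


@pytest.fixture
def sim_config_file(tmp_path):
    config = {
        "simulation": {
            "species": [
                dict(name="target", length_bp=150, concentration_pM=300.0,
                     amplitude_mean_pA=300.0, amplitude_sd_pA=12.0,
                     dwell_log_mean=-6.2, dwell_log_sd=0.3),
                dict(name="marker", length_bp=1000, concentration_pM=250.0,
                     amplitude_mean_pA=700.0, amplitude_sd_pA=25.0,
                     dwell_log_mean=-5.5, dwell_log_sd=0.3),
                dict(name="gdna", length_bp=10000, concentration_pM=250.0,
                     amplitude_mean_pA=1400.0, amplitude_sd_pA=45.0,
                     dwell_log_mean=-4.8, dwell_log_sd=0.3),
            ],
            "duration_s": 20.0,
            "open_pore_current_pA": 10000.0,
            "noise_sd_pA": 12.0,
            "sampling_rate_hz": 20000.0,
            "filter_cutoff_hz": 2000.0,
            "seed": 5,
        }
    }
    path = tmp_path / "sim.yaml"
    path.write_text(yaml.safe_dump(config))
    return path


class TestCli:
    def test_simulate_writes_trace_and_truth(self, tmp_path, sim_config_file):
        runner = CliRunner()
        out = tmp_path / "out"
        result = runner.invoke(
            main, ["simulate", "--config", str(sim_config_file), "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        assert (out / "truth_events.tsv").exists()
        assert (out / "trace.npz").exists()
        prov = json.loads((out / "provenance.json").read_text())
        assert "config_hash" in prov

    def test_simulate_is_seed_reproducible(self, tmp_path, sim_config_file):
        runner = CliRunner()
        outs = []
        for name in ("a", "b"):
            out = tmp_path / name
            result = runner.invoke(
                main,
                ["simulate", "--config", str(sim_config_file), "--out", str(out), "--events-only"],
            )
            assert result.exit_code == 0, result.output
            outs.append((out / "truth_events.tsv").read_text())
        assert outs[0] == outs[1]

    def test_detect_then_quantify_roundtrip(self, tmp_path, sim_config_file):
        runner = CliRunner()
        out = tmp_path / "out"
        assert (
            runner.invoke(
                main, ["simulate", "--config", str(sim_config_file), "--out", str(out)]
            ).exit_code
            == 0
        )
        events_file = tmp_path / "detected.tsv"
        result = runner.invoke(
            main, ["detect", str(out / "trace.npz"), "--out", str(events_file)]
        )
        assert result.exit_code == 0, result.output
        report_file = tmp_path / "qc.json"
        result = runner.invoke(
            main, ["quantify", str(events_file), "--out", str(report_file)]
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(report_file.read_text())
        # target at 300 pM vs marker at 250 pM -> C_T ~ 120 pM
        assert payload["c_target_pM"] == pytest.approx(120.0, rel=0.2)
        assert payload["mixture"]["n_components"] == 3

    def test_qc_pools_event_tables(self, tmp_path, mock_spec_factory):
        runner = CliRunner()
        files = []
        for i in range(2):
            table = simulate_event_table(
                mock_spec_factory(duration_s=600.0, seed=i), pore_id=f"np{i}"
            )
            path = tmp_path / f"events{i}.tsv"
            write_events(path, table)
            files.append(str(path))
        out = tmp_path / "qc"
        result = runner.invoke(main, ["qc", *files, "--out", str(out)])
        assert result.exit_code == 0, result.output
        payload = json.loads((out / "qc_report.json").read_text())
        assert payload["c_target_pM"] == pytest.approx(120.0, rel=0.15)
        assert payload["effective_duration_s"] == pytest.approx(1200.0)

    def test_uncertainty_grid_files(self, tmp_path, mock_spec_factory):
        runner = CliRunner()
        files = []
        for i in range(2):
            table = simulate_event_table(
                mock_spec_factory(duration_s=1800.0, seed=10 + i), pore_id=f"np{i}"
            )
            path = tmp_path / f"pore{i}.tsv"
            write_events(path, table)
            files.append(str(path))
        prefix = tmp_path / "grid"
        result = runner.invoke(
            main,
            [
                "uncertainty", *files,
                "--out", str(prefix),
                "--pores", "1,2",
                "--minutes", "5,10",
                "--replicates", "3",
            ],
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "grid_cv_concentration.tsv").exists()
        long = (tmp_path / "grid_long.tsv").read_text().strip().splitlines()
        assert len(long) == 1 + 2 * 2 * 2  # header + pores x minutes x metrics

    def test_missing_simulation_section_fails(self, tmp_path):
        config = tmp_path / "empty.yaml"
        config.write_text("marker_concentration_pM: 100\n")
        runner = CliRunner()
        result = runner.invoke(
            main, ["simulate", "--config", str(config), "--out", str(tmp_path / "o")]
        )
        assert result.exit_code != 0
        assert "simulation" in result.output
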