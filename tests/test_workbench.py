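"""End-to-end pipeline, container/EDF/BrainVision round-trips, network
exports and the command-line interface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import balancenet as bn
from balancenet import io as bio
from balancenet.cli import main as cli_main
from balancenet.workbench import PipelineConfig, run_pipeline

from conftest import small_config


def tiny_pipeline_config(seed=0):
    sim = small_config(seed=seed, couple=True, n_subjects=3, n_trials=6,
                       include_eog=True,
                       sway=bn.SwayInterference(amplitude=3.0),
                       onset_impulse_amplitude=20.0)
    return PipelineConfig(
        simulation=sim,
        kalman=bn.KalmanConfig(p=8),
        screen_channels=("CPz", "Oz"),
        pdc_t_step=5,
        parafac_rank=3,
        parafac_restarts=2,
        seed=seed,
    )


@pytest.fixture(scope="module")
def pipeline_results(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    return run_pipeline(tiny_pipeline_config(seed=1), out), out


class TestRunPipeline:
    def test_report_written_with_all_artifacts(self, pipeline_results):
        results, out = pipeline_results
        report = json.loads((out / "report.json").read_text())
        assert report["n_subjects"] == 3
        assert (out / "network_edges.csv").exists()
        assert (out / "ans_ttest.csv").exists()
        for mode in ("space", "time", "frequency", "subject"):
            assert (out / f"loadings_{mode}.csv").exists()
        assert set(report["screen_verdicts"]) == {"CPz", "Oz"}
        assert 0 <= report["parafac_fit"] <= 1

    def test_planted_edge_in_theta_network(self, pipeline_results):
        results, _ = pipeline_results
        table = results["edge_table"]
        theta_late = table[(table["band"] == "theta") & (table["interval"] == "TI4")]
        assert len(theta_late) >= 1
        top = theta_late.sort_values("weight", ascending=False).iloc[0]
        assert (top["source"], top["target"]) == ("CPz", "Cz")

    def test_deterministic_across_runs(self, tmp_path):
        cfg = tiny_pipeline_config(seed=3)
        cfg2 = tiny_pipeline_config(seed=3)
        r1 = run_pipeline(cfg)
        r2 = run_pipeline(cfg2)
        assert np.array_equal(r1["grand_pdc"].values, r2["grand_pdc"].values)
        assert np.array_equal(r1["parafac"].factors[0], r2["parafac"].factors[0])
        assert r1["ans_table"].equals(r2["ans_table"])

    def test_roi_inside_artifact_window_rejected(self):
        with pytest.raises(ValueError, match="artifact"):
            PipelineConfig(
                simulation=small_config(),
                time_intervals={"TI0": (3.0, 3.5)},
            )


class TestContainerIO:
    def test_round_trip_bit_exact(self, tmp_path):
        rec = bn.simulate_dataset(small_config(seed=2, n_subjects=1, n_trials=2,
                                               fs_raw=100.0, include_eog=True))
        path = tmp_path / "rec.h5"
        bio.write_container(rec, path)
        back = bio.read_container(path)
        assert np.array_equal(back.data, rec.data)
        assert back.fs == rec.fs
        assert back.channel_names == rec.channel_names
        assert back.onset_sample == rec.onset_sample


class TestEDF:
    def test_round_trip_channels_and_markers(self, tmp_path):
        """33-channel EDF export/import keeps channel names and the onset."""
        pytest.importorskip("mne")
        from balancenet.synthdata import FULL_1010_LAYOUT

        cfg = small_config(seed=3, n_subjects=1, n_trials=2, fs_raw=100.0,
                           channel_names=list(FULL_1010_LAYOUT), include_eog=True,
                           couplings=[], oscillators=[])
        rec = bn.simulate_dataset(cfg)
        path = tmp_path / "rec.edf"
        bio.write_edf(rec, path)
        back = bio.read_edf(path, trial_length=8.0)
        assert back.channel_names == rec.channel_names  # 32 + EOG
        assert back.onset_sample == rec.onset_sample
        assert back.data.shape[1] == 2
        # 16-bit quantization bounds the round-trip error
        span = rec.data.max() - rec.data.min()
        assert np.abs(back.data[0] - rec.data[0]).max() < span / 2**15

    def test_brainvision_import(self, tmp_path):
        pytest.importorskip("mne")
        rng = np.random.default_rng(0)
        data = rng.standard_normal((3, 500)).astype("<f4")  # µV
        (tmp_path / "t.vmrk").write_text(
            "Brain Vision Data Exchange Marker File, Version 1.0\n"
            "[Common Infos]\nDataFile=t.eeg\n[Marker Infos]\n"
            "Mk1=New Segment,,1,1,0,00000000000000000000\n"
        )
        (tmp_path / "t.vhdr").write_text(
            "Brain Vision Data Exchange Header File Version 1.0\n"
            "[Common Infos]\nDataFile=t.eeg\nMarkerFile=t.vmrk\n"
            "DataFormat=BINARY\nDataOrientation=MULTIPLEXED\nNumberOfChannels=3\n"
            "SamplingInterval=10000\n[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n"
            "[Channel Infos]\nCh1=Cz,,1,µV\nCh2=CPz,,1,µV\nCh3=Oz,,1,µV\n"
        )
        data.T.tofile(tmp_path / "t.eeg")
        rec = bio.read_brainvision(tmp_path / "t.vhdr")
        assert rec.channel_names == ["Cz", "CPz", "Oz"]
        assert rec.fs == 100.0
        assert np.allclose(rec.data[0, 0], data, atol=1e-5)


class TestNetworkExport:
    def _network(self):
        m = np.array([[0.0, 0.09, 0.11], [0.13, 0.0, 0.0], [0.0, 0.0, 0.0]])
        return bn.discretize(m, ["a", "b", "c"])

    def test_json_round_trip(self, tmp_path):
        net = self._network()
        path = tmp_path / "net.json"
        bio.write_network_json(net, path)
        back = bio.read_network_json(path)
        assert back.nodes == net.nodes
        assert sorted(back.edges) == sorted(net.edges)

    def test_graphml_readable_by_networkx(self, tmp_path):
        import networkx as nx

        net = self._network()
        path = tmp_path / "net.graphml"
        bio.write_network_graphml(net, path)
        g = nx.read_graphml(path)
        assert g.number_of_edges() == 3
        for _, _, attrs in g.edges(data=True):
            assert "weight" in attrs


class TestCLI:
    def test_simulate_and_preprocess(self, tmp_path):
        runner = CliRunner()
        cfg_path = tmp_path / "sim.yaml"
        cfg_path.write_text("n_subjects: 1\nn_trials: 2\n")
        raw = tmp_path / "raw.h5"
        res = runner.invoke(
            cli_main,
            ["simulate", "--config", str(cfg_path), "--out", str(raw), "--seed", "4"],
        )
        assert res.exit_code == 0, res.output
        out = tmp_path / "prep.h5"
        res = runner.invoke(
            cli_main,
            ["preprocess", "--in", str(raw), "--out", str(out), "--downsample", "10"],
        )
        assert res.exit_code == 0, res.output
        rec = bio.read_container(out)
        assert rec.fs == 100.0

    def test_fit_and_pdc_commands(self, tmp_path):
        runner = CliRunner()
        cfg = small_config(seed=6, n_subjects=1, n_trials=4, fs_raw=100.0)
        rec = bn.simulate_dataset(cfg)
        path = tmp_path / "rec.h5"
        bio.write_container(rec, path)
        model_path = tmp_path / "model.h5"
        res = runner.invoke(
            cli_main,
            ["fit", "--in", str(path), "--out", str(model_path), "--order", "5"],
        )
        assert res.exit_code == 0, res.output
        net_path = tmp_path / "net.json"
        res = runner.invoke(
            cli_main,
            ["pdc", "--model", str(model_path), "--out", str(net_path),
             "--band", "5:7", "--ti", "6.5:7.5"],
        )
        assert res.exit_code == 0, res.output
        net = bio.read_network_json(net_path)
        assert net.nodes == cfg.channel_names

    def test_screen_command(self, tmp_path):
        runner = CliRunner()
        cfg = small_config(seed=5, n_subjects=1, n_trials=4, fs_raw=100.0)
        rec = bn.simulate_dataset(cfg)
        path = tmp_path / "rec.h5"
        bio.write_container(rec, path)
        res = runner.invoke(cli_main, ["screen", "--in", str(path), "--channel", "Cz"])
        assert res.exit_code == 0, res.output
        assert "verdicts" in res.output
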