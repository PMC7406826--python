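"""File round-trips, configuration, CLI and the end-to-end pipeline."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from hippomediate import io
from hippomediate.cli import main as cli_main
from hippomediate.pipeline import RunConfig, run_pipeline
from hippomediate.synthetic import CohortSpec, gen_behavior, gen_motion
from hippomediate.types import MotionParams, Volume4D


class TestRoundTrips:
    def test_behavior_tsv_exact(self, tmp_path):
        table = gen_behavior(CohortSpec(n_subjects=12, rng_seed=1))
        path = io.save_behavior(table, tmp_path / "behavior.tsv")
        loaded = io.load_behavior(path)
        pd.testing.assert_frame_equal(loaded, table)

    def test_volume_nifti_within_tolerance(self, tmp_path, rng):
        vol = Volume4D(data=rng.standard_normal((20, 6, 6, 4)), voxel_size=(3, 3, 4.5), tr=2.0)
        path = io.save_volume(vol, tmp_path / "func.nii.gz")
        loaded = io.load_volume(path)
        np.testing.assert_allclose(loaded.data, vol.data, atol=1e-6)
        assert loaded.tr == pytest.approx(2.0)
        assert loaded.voxel_size == pytest.approx((3.0, 3.0, 4.5))

    def test_motion_roundtrip_and_malformed_row(self, tmp_path):
        motion = gen_motion(CohortSpec(n_subjects=8, rng_seed=2), 0)
        path = io.save_motion(motion, tmp_path / "motion.txt")
        loaded = io.load_motion(path)
        np.testing.assert_allclose(loaded.values, motion.values, atol=1e-7)
        bad = tmp_path / "bad_motion.txt"
        lines = path.read_text().splitlines()
        lines[4] = "0.1 0.2 0.3"
        bad.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="line 5"):
            io.load_motion(bad)

    def test_labels_roundtrip(self, tmp_path):
        labels = CohortSpec(n_subjects=8).label_volume()
        path = io.save_labels(labels, tmp_path / "labels.nii.gz")
        np.testing.assert_array_equal(io.load_labels(path), labels)


class TestRunConfig:
    def test_yaml_roundtrip_lossless(self, tmp_path):
        cfg = RunConfig(
            out_dir=str(tmp_path / "run"),
            cohort={"n_subjects": 10, "rng_seed": 3},
            n_boot=500,
            n_perm=200,
            band=(0.01, 0.09),
        )
        path = cfg.to_yaml(tmp_path / "config.yaml")
        assert RunConfig.from_yaml(path) == cfg

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            RunConfig(mode="nonsense")

    def test_mediation_seed_must_be_computed(self):
        with pytest.raises(ValueError):
            RunConfig(seed_labels=("head",), mediation_seed="body")


@pytest.fixture(scope="module")
def e2e(tmp_path_factory):
    """One small synthetic end-to-end run shared by the checks below."""
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        out_dir=str(out / "a"),
        cohort={
            "n_subjects": 16,
            "n_volumes": 60,
            "rng_seed": 7,
            "high_motion_subjects": [2, 5],
        },
        n_boot=150,
        n_perm=120,
        rng_seed=7,
    )
    summary = run_pipeline(cfg)
    return cfg, summary, out


class TestEndToEnd:
    def test_artifacts_written(self, e2e):
        cfg, summary, _ = e2e
        from pathlib import Path

        root = Path(cfg.out_dir)
        for rel in (
            "qc.tsv",
            "clusters.tsv",
            "cluster_labels.nii.gz",
            "provenance.json",
            "config.yaml",
            "inputs/behavior.tsv",
            "inputs/labels.nii.gz",
            "mediation/ab_coef.nii.gz",
            "mediation/ab_p.nii.gz",
            "mediation/mediation.json",
            "zmaps/manifest.tsv",
        ):
            assert (root / rel).exists(), rel
        prov = json.loads((root / "provenance.json").read_text())
        assert prov["n_subjects"] == 16

    def test_high_motion_subjects_excluded_by_id(self, e2e):
        cfg, summary, _ = e2e
        # subjects planted with frequent motion spikes exceed mean FD 0.5
        assert sorted(summary["excluded_ids"]) == ["sub-003", "sub-006"]
        assert summary["n_excluded"] == 2

    def test_rerun_is_deterministic(self, e2e):
        cfg, _, out = e2e
        from pathlib import Path

        cfg2 = RunConfig(**{**cfg.__dict__, "out_dir": str(out / "b")})
        run_pipeline(cfg2)
        a = (Path(cfg.out_dir) / "clusters.tsv").read_text()
        b = (Path(cfg2.out_dir) / "clusters.tsv").read_text()
        assert a == b
        qa = pd.read_csv(Path(cfg.out_dir) / "qc.tsv", sep="\t")
        qb = pd.read_csv(Path(cfg2.out_dir) / "qc.tsv", sep="\t")
        pd.testing.assert_frame_equal(qa, qb)

    def test_zmaps_roundtrip_consistent_with_manifest(self, e2e):
        cfg, _, _ = e2e
        from pathlib import Path

        root = Path(cfg.out_dir)
        manifest = pd.read_csv(root / "zmaps" / "manifest.tsv", sep="\t")
        assert set(manifest["seed"]) == {"head", "body", "tail"}
        assert len(manifest) == 14 * 3  # retained subjects x seeds
        z = io.load_map(root / "zmaps" / manifest.iloc[0]["path"])
        assert np.isfinite(z).all()


class TestMismatchedInputs:
    def test_missing_imaging_inputs_named(self, tmp_path):
        cfg = RunConfig(
            out_dir=str(tmp_path / "r"),
            cohort={"n_subjects": 8, "n_volumes": 60, "rng_seed": 1},
        )
        from hippomediate.pipeline import stage_qc, stage_simulate

        stage_simulate(cfg)
        # remove one subject's image to break the id join
        (tmp_path / "r" / "inputs" / "sub-004_func.nii.gz").unlink()
        with pytest.raises(FileNotFoundError, match="sub-004"):
            stage_qc(cfg)

    def test_volume_motion_length_mismatch_detected(self, tmp_path):
        cfg = RunConfig(
            out_dir=str(tmp_path / "r"),
            cohort={"n_subjects": 8, "n_volumes": 60, "rng_seed": 1},
        )
        from hippomediate.pipeline import stage_preprocess, stage_qc, stage_simulate

        stage_simulate(cfg)
        stage_qc(cfg)
        motion = io.load_motion(tmp_path / "r" / "inputs" / "sub-001_motion.txt")
        io.save_motion(MotionParams(motion.values[:30]), tmp_path / "r" / "inputs" / "sub-001_motion.txt")
        with pytest.raises(ValueError, match="sub-001"):
            stage_preprocess(cfg)


class TestCli:
    def test_power_subcommand_emits_json(self):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["power", "--r-xm", "0.65", "--r-my", "0.65", "--r-xy", "0.60",
             "-n", "33", "--n-reps", "200", "--n-mc-draws", "2000", "--seed", "1"],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert 0.5 < payload["power"] < 1.0
        assert payload["spec"]["n"] == 33

    def test_power_curve_tsv(self):
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["power", "--r-xm", "0.65", "--r-my", "0.65", "--r-xy", "0.60",
             "-n", "33", "--n-reps", "100", "--n-mc-draws", "1000",
             "--curve", "20,40"],
        )
        assert result.exit_code == 0, result.output
        lines = result.output.strip().splitlines()
        assert lines[0].split("\t") == ["n", "power", "mc_se"]
        assert len(lines) == 3

    def test_simulate_and_qc_subcommands(self, tmp_path):
        cfg = RunConfig(
            out_dir=str(tmp_path / "cli_run"),
            cohort={"n_subjects": 8, "n_volumes": 60, "rng_seed": 2},
        )
        cfg_path = cfg.to_yaml(tmp_path / "cfg.yaml")
        runner = CliRunner()
        r1 = runner.invoke(cli_main, ["simulate", "-c", str(cfg_path)])
        assert r1.exit_code == 0, r1.output
        r2 = runner.invoke(cli_main, ["qc", "-c", str(cfg_path)])
        assert r2.exit_code == 0, r2.output
        assert "sub-001" in r2.output
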