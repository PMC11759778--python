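import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from tremorclust import (
    ConfigurationError,
    TremorSeverityModel,
    run_task,
    task_spec,
    transform_score,
)
from tremorclust.cli import main


class TestTaskSpecs:
    def test_task_definitions(self):
        t1, t2, t3 = task_spec(1), task_spec(2), task_spec(3)
        assert t1.groups == ("PD", "HC") and t1.k == 2
        assert t2.groups == ("PD",) and t2.k is None
        assert t3.groups == ("PD",) and t3.k == 2 and t3.positive == 2

    def test_label_transforms(self):
        assert transform_score(0, "tremor_binary") == 0
        assert [transform_score(s, "tremor_binary") for s in (1, 2, 3)] == [1, 1, 1]
        assert [transform_score(s, "severity_binary") for s in (1, 2, 3)] == [1, 1, 2]
        with pytest.raises(ConfigurationError):
            transform_score(0, "severity_binary")

    def test_invalid_task(self):
        with pytest.raises(ConfigurationError):
            task_spec(4)


class TestPipeline:
    def test_noise_free_separable_task1_is_perfect(self, noise_free_instances):
        res = run_task(noise_free_instances, 1, seed=0)
        assert res.accuracy == 1.0
        assert res.k == 2

    def test_task2_resolves_k_to_observed_scores(self, noise_free_instances):
        res = run_task(noise_free_instances, 2, seed=0)
        assert res.k == 3  # scores {1, 2, 3} observed among PD instances
        assert len(res.model.instances) == 6  # PD only

    def test_task3_is_independent_two_cluster_run(self, noise_free_instances):
        res = run_task(noise_free_instances, 3, seed=0)
        assert res.clustering.k == 2
        assert set(d.dominant_cluster for d in res.dominants) <= {0, 1}
        assert sorted(np.unique(res.model.truth)) == [1, 2]

    def test_report_json_byte_identical_across_runs(self, noise_free_instances, tmp_path):
        for d in ("a", "b"):
            run_task(noise_free_instances, 1, seed=5).save(tmp_path / d)
        assert (tmp_path / "a/report.json").read_bytes() == (
            tmp_path / "b/report.json"
        ).read_bytes()

    def test_exclude_hc_from_fit_still_classifies_all(self, noise_free_instances):
        # centroids are fitted on PD moduli only, but every instance —
        # controls included — still receives a nearest-centroid prediction
        res = run_task(noise_free_instances, 1, seed=0, exclude_hc_from_fit=True)
        frame = res.per_instance_frame()
        assert len(frame) == len(noise_free_instances)
        assert (frame.loc[frame["group"] == "HC", "mapped_score"] == 0).all()

    def test_k_larger_than_cohort_rejected(self, noise_free_instances):
        with pytest.raises(ConfigurationError, match="exceeds"):
            run_task(noise_free_instances, 1, k=50)

    def test_no_instances_in_group_rejected(self, noise_free_instances):
        hc_only = [i for i in noise_free_instances if i.group == "HC"]
        with pytest.raises(ConfigurationError):
            TremorSeverityModel(hc_only, task=2)

    def test_summary_mentions_mapping_and_accuracy(self, noise_free_instances):
        text = run_task(noise_free_instances, 1, seed=0).summary()
        assert "mapping" in text and "accuracy" in text


class TestCLI:
    def test_reproduce_paper_prints_summary(self):
        result = CliRunner().invoke(main, ["reproduce-paper"])
        assert result.exit_code == 0, result.output
        assert "Task 1      0.76       1.00    0.57      0.73" in result.output
        assert "Task 2      0.57" in result.output
        assert "Task 3      0.71" in result.output

    def test_stagewise_commands_end_to_end(self, tmp_path):
        runner = CliRunner()
        cfg = {
            "n_per_severity": {0: 2, 1: 2, 2: 2, 3: 2},
            "amplitude_bands": {0: [0, 0], 1: [2.2, 2.4], 2: [3.3, 3.6], 3: [4.95, 5.4]},
            "tremor_freq_range": [5.0, 5.0],
            "noise_sd": 0.0,
            "rest_duration": 10.0,
            "n_rest_intervals": 2,
            "filler_duration": 5.0,
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        cohort = tmp_path / "cohort"

        steps = [
            ["simulate", "--config", str(cfg_path), "--out", str(cohort), "--seed", "3"],
            ["preprocess", "--in", str(cohort), "--out", str(tmp_path / "moduli.csv")],
            ["cluster", "--moduli", str(tmp_path / "moduli.csv"), "--k", "2",
             "--seed", "3", "--out", str(tmp_path / "clusters.csv")],
            ["assign", "--clusters", str(tmp_path / "clusters.csv"),
             "--out", str(tmp_path / "dominant.csv")],
            ["map-labels", "--dominant", str(tmp_path / "dominant.csv"),
             "--truth", str(cohort / "ground_truth.csv"),
             "--out", str(tmp_path / "mapping.json")],
        ]
        for args in steps:
            result = runner.invoke(main, args)
            assert result.exit_code == 0, f"{args}: {result.output}"
        mapping = json.loads((tmp_path / "mapping.json").read_text())
        assert 0 < mapping["accuracy"] <= 1

    def test_run_command_with_synthetic_config(self, tmp_path):
        cfg = {
            "synthetic": {
                "n_per_severity": {0: 2, 1: 2, 2: 2, 3: 2},
                "amplitude_bands": {0: [0, 0], 1: [2.2, 2.4], 2: [3.3, 3.6], 3: [4.95, 5.4]},
                "tremor_freq_range": [5.0, 5.0],
                "noise_sd": 0.0,
                "rest_duration": 10.0,
                "n_rest_intervals": 2,
                "filler_duration": 5.0,
            },
            "kmeans": {"seed": 4},
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        out = tmp_path / "out"
        result = CliRunner().invoke(
            main, ["run", "--task", "1", "--config", str(cfg_path), "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        report = json.loads((out / "report.json").read_text())
        assert report["task"] == 1 and report["k"] == 2
        assert report["report"]["accuracy"] == 1.0
        assert (out / "clusters.csv").exists() and (out / "dominant.csv").exists()
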