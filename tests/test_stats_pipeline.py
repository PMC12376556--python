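"""Group-comparison plumbing and the end-to-end pipeline."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rmtrack import (
    PipelineConfig,
    SimulationParams,
    anova_oneway,
    group_comparison,
    run_pipeline,
    significance_label,
)
from rmtrack.errors import ParameterError, PipelineError


class TestGroupComparison:
    def test_identical_sets_are_not_distinguishable(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = group_comparison(a, list(a), test="mann_whitney")
        assert res.p_value == pytest.approx(1.0, abs=0.05)
        assert res.significance == "ns"

    def test_extreme_separation_is_highly_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 40)
        b = rng.normal(50.0, 1.0, 40)
        for test in ("mann_whitney", "t"):
            res = group_comparison(a, b, test=test)
            assert res.p_value < 0.001
            assert res.significance == "***"

    def test_delegates_to_scipy_exactly(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 25), rng.normal(0.5, 1.2, 30)
        mw = group_comparison(a, b, test="mann_whitney")
        ref = sps.mannwhitneyu(a, b, alternative="two-sided")
        assert mw.statistic == ref.statistic and mw.p_value == ref.pvalue
        tt = group_comparison(a, b, test="t")
        ref_t = sps.ttest_ind(a, b)
        assert tt.statistic == ref_t.statistic and tt.p_value == ref_t.pvalue
        assert mw.mean_a == pytest.approx(np.mean(a))
        assert mw.sem_a == pytest.approx(sps.sem(a))

    def test_insufficient_group_named(self):
        with pytest.raises(ParameterError, match="'b'"):
            group_comparison([1.0, 2.0], [3.0], test="t")

    def test_anova_delegates_to_scipy(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 20) for m in (0, 0.2, 3)]
        res = anova_oneway(*groups)
        ref = sps.f_oneway(*groups)
        assert res["statistic"] == ref.statistic and res["p_value"] == ref.pvalue

    @pytest.mark.parametrize(
        "p,label",
        [(0.5, "ns"), (0.05, "ns"), (0.049, "*"), (0.009, "**"), (0.0009, "***")],
    )
    def test_significance_thresholds(self, p, label):
        assert significance_label(p) == label


def _sim_config(tmp_path, name, **overrides):
    sim = SimulationParams(n_cells=25, n_frames=120, seed=17)
    return PipelineConfig(simulation=sim, output_dir=str(tmp_path / name),
                          **overrides)


class TestPipeline:
    def test_bundle_contents_and_internal_consistency(self, tmp_path):
        res = run_pipeline(_sim_config(tmp_path, "run"))
        out = res.output_dir
        for fname in ("tracks.csv", "truth.json", "metrics.csv", "labels.json",
                      "density.csv", "summary.json", "run.log"):
            assert (out / fname).exists(), fname
        summary = json.loads((out / "summary.json").read_text())
        labels = json.loads((out / "labels.json").read_text())
        assert summary["n_rm"] == sum(labels.values())
        assert summary["n_cells"] == 25
        assert summary["n_contacted"] >= summary["n_rm"]
        assert summary["ground_truth"]["label_accuracy"] == 1.0
        assert 0.95 <= summary["density"]["integral"] <= 1.05

    def test_rerun_is_byte_identical(self, tmp_path):
        r1 = run_pipeline(_sim_config(tmp_path, "a"))
        r2 = run_pipeline(_sim_config(tmp_path, "b"))
        for fname in ("metrics.csv", "labels.json", "tracks.csv", "summary.json"):
            assert (r1.output_dir / fname).read_bytes() == \
                (r2.output_dir / fname).read_bytes(), fname

    def test_seed_override_changes_cohort(self, tmp_path):
        r1 = run_pipeline(_sim_config(tmp_path, "s1", seed=100))
        r2 = run_pipeline(_sim_config(tmp_path, "s2", seed=101))
        assert (r1.output_dir / "tracks.csv").read_bytes() != \
            (r2.output_dir / "tracks.csv").read_bytes()

    def test_noiseless_summary_reports_perfect_approach_straightness(self, tmp_path):
        sim = SimulationParams(n_cells=8, n_frames=100, heading_noise_sd=0.0,
                               speed_sd=0.0, persistence=0.0, p_rm=0.0, seed=1)
        cfg = PipelineConfig(simulation=sim, output_dir=str(tmp_path / "clean"))
        res = run_pipeline(cfg)
        s = res.summary["segments"]["approach"]["straightness"]
        assert s["mean"] == pytest.approx(1.0, abs=1e-9)

    def test_file_input_round_trip(self, tmp_path):
        sim_res = run_pipeline(_sim_config(tmp_path, "src"))
        cfg = PipelineConfig(
            tracks_path=str(sim_res.output_dir / "tracks.csv"),
            pixel_size=1.0,
            frame_interval=1.0,
            spheroid=sim_res.trackset.spheroid,
            output_dir=str(tmp_path / "reread"),
        )
        res = run_pipeline(cfg)
        assert res.labels == sim_res.labels
        m1 = pd.read_csv(sim_res.output_dir / "metrics.csv")
        m2 = pd.read_csv(res.output_dir / "metrics.csv")
        np.testing.assert_allclose(m1["straightness"], m2["straightness"],
                                   rtol=1e-9)

    def test_config_requires_exactly_one_source(self, tmp_path):
        with pytest.raises(ParameterError, match="exactly one"):
            run_pipeline(PipelineConfig(output_dir=str(tmp_path / "x")))

    def test_config_json_roundtrip(self, tmp_path):
        cfg = _sim_config(tmp_path, "cfg")
        p = tmp_path / "config.json"
        p.write_text(json.dumps(cfg.to_json_dict()))
        back = PipelineConfig.from_json(p)
        assert back.simulation == cfg.simulation
        assert back.output_dir == cfg.output_dir

    def test_unknown_config_field_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text(json.dumps({"output_dir": "x", "bogus_knob": 1}))
        with pytest.raises(ParameterError, match="bogus_knob"):
            PipelineConfig.from_json(p)

    def test_stage_failure_names_the_stage(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("track_id,frame,x,y\nc1,0,0,nope\n")
        cfg = PipelineConfig(
            tracks_path=str(bad), pixel_size=1.0, frame_interval=1.0,
            spheroid=None, output_dir=str(tmp_path / "fail"),
        )
        with pytest.raises(ParameterError):
            run_pipeline(cfg)  # missing spheroid caught by validation
        cfg.spheroid = __import__("rmtrack").SpheroidGeometry(0, 0, 10)
        with pytest.raises(PipelineError, match="stage input"):
            run_pipeline(cfg)
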