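import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import readerstudy as rs
from readerstudy.errors import CalibrationError
from readerstudy.simulate import _latent_mixture


class TestSimulateCases:
    def test_default_counts_match_study_conditions(self):
        cases = rs.simulate_cases(rs.SimulationConfig(), seed=1)
        assert len(cases) == 400
        assert cases["label"].sum() == 133          # round(0.3325 * 400)
        assert cases["block_id"].nunique() == 4
        assert cases["center"].nunique() == 4

    def test_positives_stratified_across_blocks(self):
        cases = rs.simulate_cases(rs.SimulationConfig(), seed=3)
        per_block = cases.groupby("block_id")["label"].sum()
        assert per_block.max() - per_block.min() <= 1

    def test_zero_prevalence_all_benign(self):
        cfg = rs.SimulationConfig(n_cases=40, prevalence=0.0)
        cases = rs.simulate_cases(cfg, seed=0)
        assert (cases["label"] == 0).all() and (cases["gg"] <= 1).all()

    def test_label_grade_consistency(self):
        cases = rs.simulate_cases(rs.SimulationConfig(n_cases=100), seed=9)
        assert (cases["label"] == (cases["gg"] >= 2).astype(int)).all()

    def test_determinism(self):
        a = rs.simulate_cases(rs.SimulationConfig(), seed=7)
        b = rs.simulate_cases(rs.SimulationConfig(), seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_uneven_split_warns_and_differs_by_at_most_one(self):
        with pytest.warns(UserWarning, match="divide"):
            cases = rs.simulate_cases(rs.SimulationConfig(n_cases=42), seed=0)
        sizes = cases.groupby("block_id").size()
        assert sizes.max() - sizes.min() <= 1

    def test_psad_pooled_quantiles_near_clinical_table(self):
        cases = pd.concat([rs.simulate_cases(rs.SimulationConfig(), seed=s)
                           for s in range(5)])
        q25, q50, q75 = cases["psad"].quantile([0.25, 0.5, 0.75])
        assert q50 == pytest.approx(0.13, abs=0.02)
        assert q25 == pytest.approx(0.09, abs=0.02)
        assert q75 == pytest.approx(0.21, abs=0.04)


class TestCalibrateCutpoints:
    def test_equal_targets_are_quartiles_of_the_latent_mixture(self):
        cfg = rs.SimulationConfig()
        cuts = rs.calibrate_cutpoints(cfg, targets=(0.25, 0.25, 0.25, 0.25))
        weights, means, sd = _latent_mixture(cfg)
        for c, q in zip(cuts, (0.25, 0.5, 0.75)):
            assert (weights * norm.cdf((c - means) / sd)).sum() == pytest.approx(q)

    def test_degenerate_targets_put_everything_in_category_2(self):
        cfg = rs.SimulationConfig(n_readers=4, n_cases=16,
                                  cutpoints=None, category_targets=(1.0, 0.0, 0.0, 0.0))
        study = rs.simulate_study(cfg, seed=0)
        assert (study.readings["patient_pirads"] == 2).all()

    def test_infeasible_targets_raise(self):
        with pytest.raises(CalibrationError):
            rs.calibrate_cutpoints(rs.SimulationConfig(), targets=(0.5, 0.5, 0.5, 0.5))

    def test_cutpoints_strictly_increasing_for_positive_targets(self):
        cuts = rs.calibrate_cutpoints(rs.SimulationConfig())
        assert cuts[0] < cuts[1] < cuts[2]


class TestSimulateStudy:
    def test_default_row_count(self, default_study):
        # 62 readers x 100 block cases x 2 modalities
        assert len(default_study.readings) == 12_400
        assert len(default_study.readers) == 62
        assert (default_study.readers["expertise"] == "expert").sum() == 46

    def test_small_design_row_count(self):
        study = rs.simulate_study(rs.SimulationConfig(n_readers=8, n_cases=40), seed=2)
        # each of 8 readers reads its block's 10 cases under both modalities
        assert len(study.readings) == 160

    def test_byte_for_byte_reproducibility(self, tmp_path):
        cfg = rs.SimulationConfig(n_readers=4, n_cases=16)
        p1, p2 = tmp_path / "a", tmp_path / "b"
        rs.simulate_study(cfg, seed=42, out_dir=p1)
        rs.simulate_study(cfg, seed=42, out_dir=p2)
        for name in ("readings.csv", "cases.csv", "readers.csv"):
            assert (p1 / name).read_bytes() == (p2 / name).read_bytes()

    def test_adding_readers_does_not_perturb_existing_draws(self):
        small = rs.simulate_study(rs.SimulationConfig(n_readers=8, n_cases=40), seed=4)
        large = rs.simulate_study(rs.SimulationConfig(n_readers=12, n_cases=40), seed=4)
        keep = small.readings["reader_id"].unique()[:4]
        a = small.readings[small.readings["reader_id"].isin(keep)].reset_index(drop=True)
        b = large.readings[large.readings["reader_id"].isin(keep)].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_shared_latents_make_modalities_identical(self):
        cfg = rs.SimulationConfig(n_readers=4, n_cases=16, modality_effect=0.0,
                                  var_modality_case=0.0, var_modality_reader=0.0,
                                  var_error=0.0)
        study = rs.simulate_study(cfg, seed=5)
        paired = study.paired_readings(warn_unpaired=False)
        assert (paired["bp_category"] == paired["mp_category"]).all()
        assert (paired["bp_suspicion"] == paired["mp_suspicion"]).all()

    def test_positive_modality_effect_raises_mp_auroc(self):
        cfg = rs.SimulationConfig(n_readers=8, n_cases=200, modality_effect=0.5)
        study = rs.simulate_study(cfg, seed=6)
        table = rs.per_reader_metric_table(study, "auroc")
        assert table.values["mp"].mean() > table.values["bp"].mean()

    def test_expertise_deficit_lowers_nonexpert_auroc(self, default_study):
        table = rs.per_reader_metric_table(default_study, "auroc")
        grouped = table.values.join(table.reader_info).groupby("expertise")[["bp", "mp"]].mean()
        assert (grouped.loc["expert"] > grouped.loc["nonexpert"]).all()

    def test_suspicion_and_category_are_consistent_transforms(self, small_study):
        # same latent drives both outputs: scores within category 5 all exceed
        # scores within category 2 for a given reader-modality series
        r = small_study.readings
        for (_, _), grp in r.groupby(["reader_id", "modality"]):
            hi = grp.loc[grp["patient_pirads"] == 5, "suspicion"]
            lo = grp.loc[grp["patient_pirads"] == 2, "suspicion"]
            if len(hi) and len(lo):
                assert hi.min() >= lo.max()


class TestDeltaCalibration:
    def test_closed_form_auroc_difference(self):
        cfg = rs.SimulationConfig()
        delta = rs.delta_for_auc_difference(cfg, -0.05)
        shifted = rs.SimulationConfig(modality_effect=delta)
        diff = shifted.true_mean_auroc("bp") - shifted.true_mean_auroc("mp")
        assert diff == pytest.approx(-0.05, abs=1e-9)

    def test_zero_difference_means_zero_delta(self):
        assert rs.delta_for_auc_difference(rs.SimulationConfig(), 0.0) == pytest.approx(0.0, abs=1e-9)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = rs.SimulationConfig(n_readers=10, modality_effect=0.1,
                                  cutpoints=(0.3, 0.6, 1.2))
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        again = rs.SimulationConfig.from_yaml(path)
        assert again == cfg

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            rs.SimulationConfig(var_case=-1.0)

    def test_nonincreasing_cutpoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            rs.SimulationConfig(cutpoints=(1.0, 0.5, 2.0))
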