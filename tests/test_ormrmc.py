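import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import readerstudy as rs
from readerstudy.errors import DegenerateInputError
from readerstudy.metrics import AccuracyTable
from readerstudy.ormrmc import BlockComponents, ORComponents

from conftest import case, make_study, reader, reading


def brute_force_loo(values, labels, metric, psad=None, rule=None):
    """Recompute the metric after deleting each case, by definition."""
    out = []
    for k in range(len(labels)):
        keep = np.arange(len(labels)) != k
        v, y = np.asarray(values)[keep], np.asarray(labels)[keep]
        if metric == "auroc":
            out.append(rs.empirical_auroc(v, y))
        else:
            p = None if psad is None else np.asarray(psad)[keep]
            s, sp = rs.sens_spec(v, y, p, rule)
            out.append(s if metric == "sensitivity" else sp)
    return np.array(out)


class TestJackknife:
    def test_auroc_four_case_fixture_matches_full_recomputation(self):
        scores = np.array([80, 20, 60, 40])
        labels = np.array([1, 0, 1, 0])
        jk = rs.jackknife_accuracies(scores, labels, "auroc")
        np.testing.assert_allclose(jk, brute_force_loo(scores, labels, "auroc"))

    @pytest.mark.parametrize("seed", range(8))
    def test_auroc_matches_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        labels = np.zeros(n, dtype=int)
        labels[: max(2, int(rng.integers(2, n - 1)))] = 1
        rng.shuffle(labels)
        if labels.sum() < 2 or (1 - labels).sum() < 2:
            labels[:2], labels[-2:] = 1, 0
        scores = rng.integers(0, 15, size=n)
        jk = rs.jackknife_accuracies(scores, labels, "auroc")
        np.testing.assert_allclose(jk, brute_force_loo(scores, labels, "auroc"))

    @pytest.mark.parametrize("metric", ["sensitivity", "specificity"])
    def test_binary_metrics_match_brute_force(self, metric):
        rng = np.random.default_rng(3)
        cats = rng.choice([2, 3, 4, 5], size=20)
        labels = np.r_[np.ones(7, dtype=int), np.zeros(13, dtype=int)]
        rng.shuffle(labels)
        psad = rng.lognormal(np.log(0.13), 0.4, size=20)
        jk = rs.jackknife_accuracies(cats, labels, metric, psad=psad, rule=rs.PIRADS4_PSAD)
        np.testing.assert_allclose(
            jk, brute_force_loo(cats, labels, metric, psad, rs.PIRADS4_PSAD))

    def test_deleting_a_negative_case_leaves_sensitivity_unchanged(self):
        cats = np.array([5, 2, 4, 2, 3])
        labels = np.array([1, 0, 1, 0, 1])
        jk = rs.jackknife_accuracies(cats, labels, "sensitivity", rule=rs.PIRADS3)
        full = rs.sens_spec(cats, labels, None, rs.PIRADS3)[0]
        assert np.allclose(jk[labels == 0], full)

    def test_constant_metric_gives_zero_variance_vector(self):
        cats = np.array([5, 2, 5, 2, 5, 2])
        labels = np.array([1, 0, 1, 0, 1, 0])
        jk = rs.jackknife_accuracies(cats, labels, "sensitivity", rule=rs.PIRADS3)
        assert np.ptp(jk) == 0.0

    def test_single_deletion_degeneracy_is_reported(self):
        with pytest.raises(DegenerateInputError, match="single-class|only positive"):
            rs.jackknife_accuracies([9, 1, 2, 3], [1, 0, 0, 0], "auroc")


def definitional_components(study, metric="auroc"):
    """Independent oracle: every pairwise jackknife covariance, by definition."""
    paired = study.paired_readings(warn_unpaired=False)
    case_ids = sorted(paired["case_id"].unique())
    reader_ids = sorted(paired["reader_id"].unique())
    loo = {}
    for r in reader_ids:
        grp = paired[paired["reader_id"] == r].set_index("case_id").loc[case_ids]
        for m in ("bp", "mp"):
            col = f"{m}_suspicion" if metric == "auroc" else f"{m}_category"
            loo[(m, r)] = brute_force_loo(grp[col].to_numpy(), grp["label"].to_numpy(), metric)
    n = len(case_ids)
    keys = [(m, r) for m in ("bp", "mp") for r in reader_ids]
    cov = {}
    for a in keys:
        for b in keys:
            da = loo[a] - loo[a].mean()
            db = loo[b] - loo[b].mean()
            cov[(a, b)] = (n - 1) / n * (da * db).sum()
    var_error = np.mean([cov[(k, k)] for k in keys])
    cov1 = np.mean([cov[(("bp", r), ("mp", r))] for r in reader_ids]
                   + [cov[(("mp", r), ("bp", r))] for r in reader_ids])
    cov2 = np.mean([cov[((m, r1), (m, r2))] for m in ("bp", "mp")
                    for r1 in reader_ids for r2 in reader_ids if r1 != r2])
    cov3 = np.mean([cov[((m1, r1), (m2, r2))] for m1, m2 in (("bp", "mp"), ("mp", "bp"))
                    for r1 in reader_ids for r2 in reader_ids if r1 != r2])
    return var_error, cov1, cov2, cov3


class TestCovarianceComponents:
    def test_matches_definitional_oracle_on_two_reader_fixture(self, two_reader_study):
        comps = rs.estimate_components(two_reader_study, "auroc")
        b = comps.blocks[0]
        var_error, cov1, cov2, cov3 = definitional_components(two_reader_study)
        assert b.var_error == pytest.approx(var_error)
        assert b.raw["cov1"] == pytest.approx(cov1)
        assert b.raw["cov2"] == pytest.approx(cov2)
        assert b.raw["cov3"] == pytest.approx(cov3)
        # MS(T*R) from the 2x2 theta table: Var(d_j) / 2
        d = b.theta[0] - b.theta[1]
        assert b.ms_tr == pytest.approx(((d - d.mean()) ** 2).sum() / (2 * (len(d) - 1)))

    def test_identical_modalities_collapse_cov1_to_var_error(self):
        cases = [case(f"C{i}", label=int(i < 3)) for i in range(8)]
        readers = [reader("R1"), reader("R2")]
        rng = np.random.default_rng(0)
        rows = []
        for r in ("R1", "R2"):
            scores = rng.integers(0, 100, size=8)
            for i in range(8):
                for m in ("bp", "mp"):
                    rows.append(reading(r, f"C{i}", m, 2, int(scores[i]), ""))
        study = make_study(rows, cases, readers)
        comps = rs.estimate_components(study, "auroc")
        b = comps.blocks[0]
        assert b.cov1 == pytest.approx(b.var_error)
        result = rs.or_test(comps)
        assert result.diff == 0.0

    def test_independent_readers_have_near_zero_cross_covariances(self):
        # independent scores per reader-modality: cov2 and cov3 vanish in mean
        rng = np.random.default_rng(42)
        cov2s, cov3s = [], []
        cases = [case(f"C{i}", label=int(i < 10)) for i in range(30)]
        readers = [reader(r) for r in ("R1", "R2", "R3", "R4")]
        for _ in range(120):
            rows = []
            for r in ("R1", "R2", "R3", "R4"):
                for m in ("bp", "mp"):
                    scores = rng.integers(0, 100, size=30)
                    for i in range(30):
                        rows.append(reading(r, f"C{i}", m, 2, int(scores[i]), ""))
            study = make_study(rows, cases, readers)
            b = rs.estimate_components(study, "auroc").blocks[0]
            cov2s.append(b.raw["cov2"])
            cov3s.append(b.raw["cov3"])
        assert abs(np.mean(cov2s)) < 5e-4
        assert abs(np.mean(cov3s)) < 5e-4


def synthetic_components(diff, se_scale=0.01, j=10, seed=0):
    """Hand-built single-block components with a prescribed mean difference."""
    rng = np.random.default_rng(seed)
    d = diff + rng.normal(0, se_scale, size=j)
    d += diff - d.mean()  # force the exact mean difference
    theta = np.vstack([0.85 + d / 2, 0.85 - d / 2])
    ms_tr = ((d - d.mean()) ** 2).sum() / (2 * (j - 1))
    block = BlockComponents(
        block_id="B1", reader_ids=[f"R{i}" for i in range(j)],
        case_ids=[f"C{i}" for i in range(50)], theta=theta,
        var_error=4e-4, cov1=3e-4, cov2=2e-4, cov3=1e-4,
        ms_tr=ms_tr, ms_r=np.array([4e-4, 4e-4]),
        cov2_by_modality=np.array([2e-4, 2e-4]),
    )
    return ORComponents(blocks=[block], metric="auroc")


class TestORTest:
    def test_difference_exactly_at_margin_gives_p_half(self):
        comps = synthetic_components(diff=-0.05)
        res = rs.or_test(comps, margin=0.05)
        assert res.diff == pytest.approx(-0.05)
        assert res.p_value == pytest.approx(0.5)

    def test_identical_columns_give_symmetric_ci_about_zero(self):
        comps = synthetic_components(diff=0.0)
        res = rs.or_test(comps)
        assert res.diff == pytest.approx(0.0)
        assert res.ci_low == pytest.approx(-res.ci_high)

    def test_wald_interval_uses_normal_quantile(self):
        comps = synthetic_components(diff=-0.01)
        res = rs.or_test(comps)
        assert res.ci_high - res.ci_low == pytest.approx(2 * 1.959964 * res.se_diff, rel=1e-5)
        assert np.isinf(res.ddf)

    def test_t_interval_is_wider_than_wald(self):
        comps = synthetic_components(diff=-0.01)
        wald = rs.or_test(comps)
        tt = rs.or_test(comps, interval="t")
        assert np.isfinite(tt.ddf)
        assert tt.ci_high - tt.ci_low > wald.ci_high - wald.ci_low

    def test_zero_se_reports_p_half_at_boundary_with_warning(self):
        comps = synthetic_components(diff=-0.05, se_scale=0.0)
        comps.blocks[0].cov2 = comps.blocks[0].cov3 = 0.0
        with pytest.warns(UserWarning, match="zero standard error"):
            res = rs.or_test(comps, margin=0.05)
        assert res.p_value == 0.5


class TestPoolBlocks:
    def test_single_block_identity(self, two_reader_study):
        comps = rs.estimate_components(two_reader_study, "auroc")
        pooled = rs.pool_blocks(comps)
        b = comps.blocks[0]
        assert pooled["diff"] == pytest.approx(b.diff)
        assert pooled["var_diff"] == pytest.approx(b.var_diff())

    def test_four_identical_blocks_halve_the_se(self):
        one = synthetic_components(diff=-0.02, j=8).blocks[0]
        import copy
        blocks = []
        for i in range(4):
            blk = copy.deepcopy(one)
            blk.block_id = f"B{i + 1}"
            blk.reader_ids = [f"{r}_{i}" for r in one.reader_ids]
            blocks.append(blk)
        quad = ORComponents(blocks=blocks, metric="auroc")
        p1 = rs.pool_blocks(ORComponents(blocks=[one], metric="auroc"))
        p4 = rs.pool_blocks(quad)
        assert p4["mean_bp"] == pytest.approx(p1["mean_bp"])
        assert p4["diff"] == pytest.approx(p1["diff"])
        assert np.sqrt(p4["var_diff"]) == pytest.approx(np.sqrt(p1["var_diff"]) / 2)

    def test_unequal_blocks_weight_by_reader_count(self):
        b1 = synthetic_components(diff=-0.02, j=12, seed=1).blocks[0]
        b2 = synthetic_components(diff=0.04, j=4, seed=2).blocks[0]
        b2.block_id, b2.reader_ids = "B2", [f"S{i}" for i in range(4)]
        pooled = rs.pool_blocks(ORComponents(blocks=[b1, b2], metric="auroc"))
        expected = (12 * -0.02 + 4 * 0.04) / 16
        assert pooled["diff"] == pytest.approx(expected)

    def test_single_reader_block_excluded_with_warning(self, two_reader_study):
        table = rs.per_reader_metric_table(two_reader_study, "auroc")
        jk = rs.compute_jackknife_vectors(two_reader_study, "auroc")
        solo = {"B1": {"case_ids": jk["B1"]["case_ids"],
                       "reader_ids": jk["B1"]["reader_ids"][:1],
                       "loo": jk["B1"]["loo"][:, :1, :]}}
        with pytest.raises(DegenerateInputError):
            with pytest.warns(UserWarning, match="excluded"):
                rs.covariance_components(table, solo)


class TestEstimatorFacade:
    def test_fit_sets_trailing_underscore_attributes(self, small_study):
        est = rs.ObuchowskiRockette(metric="auroc").fit(small_study)
        assert 0 <= est.mean_bp_ <= 1 and 0 <= est.mean_mp_ <= 1
        assert est.ci_[0] <= est.diff_ <= est.ci_[1]
        assert 0 <= est.p_value_ <= 1
        assert est.result_.se_diff > 0

    def test_diff_is_mean_of_per_reader_paired_differences(self, small_study):
        est = rs.ObuchowskiRockette(metric="sensitivity", rule="p3").fit(small_study)
        table = est.table_.values
        assert est.diff_ == pytest.approx((table["bp"] - table["mp"]).mean())

    def test_sklearn_params_round_trip(self):
        est = rs.ObuchowskiRockette(metric="sensitivity", rule="p3", margin=0.04)
        cl = clone(est)
        assert cl.get_params()["margin"] == 0.04
        cl.set_params(metric="specificity")
        assert cl.metric == "specificity"

    def test_expertise_subgroups_analyzable(self, small_study):
        est = rs.ObuchowskiRockette(metric="auroc").fit(small_study, subgroup="expert")
        assert est.n_readers_ == (small_study.readers["expertise"] == "expert").sum()
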