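import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from gradedcat import CohortSpec, DefectSpec, plant_defects, simulate_responses
from gradedcat.calibration import EMConfig
from gradedcat.cat import batch_eap
from gradedcat.models import ItemBank, ItemParameters, ResponseMatrix, ThetaGrid, category_probs
from gradedcat.screening import (
    DIFResult,
    ScreeningConfig,
    dif_purify,
    dif_scan,
    discrimination_filter,
    polychoric_corr,
    q3_flagged_pairs,
    q3_matrix,
    run_screening_pipeline,
    s_chi2_item_fit,
    summed_score_distribution,
    unidimensionality_filter,
)

FAST = EMConfig(tol=5e-4, max_cycles=200)


class TestPolychoric:
    def test_self_agreement(self, rng):
        x = np.digitize(rng.normal(size=2000), [-0.5, 0.5])
        assert polychoric_corr(x, x) >= 0.99

    def test_generative_oracle(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=5000)
        cuts = [-0.8, 0.3, 1.2]
        x, y = np.digitize(z[:, 0], cuts), np.digitize(z[:, 1], cuts)
        assert polychoric_corr(x, y) == pytest.approx(0.5, abs=0.05)

    def test_independent_near_zero(self, rng):
        cuts = [-0.8, 0.3, 1.2]
        x = np.digitize(rng.normal(size=5000), cuts)
        y = np.digitize(rng.normal(size=5000), cuts)
        assert abs(polychoric_corr(x, y)) < 0.05

    def test_constant_vector_rejected(self, rng):
        x = np.digitize(rng.normal(size=100), [0.0])
        with pytest.raises(ValueError, match="degenerate"):
            polychoric_corr(x, np.zeros(100, dtype=int))


class TestUnidimensionality:
    def test_clean_reference_data_passes(self, cohort):
        resp, _ = cohort
        report, retained = unidimensionality_filter(resp)
        assert len(retained) >= 19  # allow at most one noise removal
        assert report.eigenvalue_ratio >= 4
        assert report.first_factor_variance_pct >= 20
        assert report.passed

    def test_planted_noise_item_removed_first_iteration(self, cohort, ref_bank):
        resp, thetas = cohort
        bad = plant_defects(resp, ref_bank, DefectSpec(noise_items=("r5",)), thetas, seed=0)
        report, retained = unidimensionality_filter(bad)
        assert "r5" not in retained
        assert "r5" in report.iterations[0][0]

    def test_too_few_items_rejected(self, cohort):
        resp, _ = cohort
        with pytest.raises(ValueError, match="3 items"):
            unidimensionality_filter(resp.subset_items(["r1", "r2"]))


@pytest.fixture(scope="module")
def q3(cohort, calibrated):
    resp, _ = cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return q3_matrix(resp, calibrated.bank)


class TestQ3:
    def test_diagonal_and_symmetry(self, q3):
        assert np.allclose(np.diag(q3.to_numpy()), 1.0)
        assert np.allclose(q3.to_numpy(), q3.to_numpy().T, atol=1e-12)

    def test_null_data_few_large_values(self, q3):
        off = q3.to_numpy()[np.triu_indices(len(q3), 1)]
        assert (np.abs(off) > 0.36).mean() < 0.05

    def test_planted_dependence_flagged(self, cohort, ref_bank, calibrated):
        resp, thetas = cohort
        spec = DefectSpec(dependent_pairs={("r10", "r3"): 0.8})
        bad = plant_defects(resp, ref_bank, spec, thetas, seed=1)
        q3 = q3_matrix(bad, calibrated.bank)
        assert abs(q3.loc["r10", "r3"]) > 0.36
        pairs = q3_flagged_pairs(q3)
        assert any({p[0], p[1]} == {"r10", "r3"} for p in pairs)

    def test_sparse_pair_undefined(self, ref_bank):
        data = np.full((10, 20), -1)
        data[:, 0] = [0, 1, 2, 3, 0, 1, 2, 3, 0, 1]
        data[:2, 1] = [0, 1]  # only 2 joint observations with item 1
        data[2:, 2] = [0, 1, 2, 3, 0, 1, 2, 3]
        resp = ResponseMatrix(data, item_ids=ref_bank.item_ids)
        q3 = q3_matrix(resp, ref_bank)
        assert np.isnan(q3.loc["r1", "r2"])


class TestDiscrimination:
    def test_reference_bank_untouched(self, ref_bank):
        retained, removed = discrimination_filter(ref_bank, cutoff=0.7)
        assert removed == []
        assert retained == ref_bank.item_ids

    def test_planted_low_a_removed(self, ref_bank):
        weak = ItemParameters("weak", "GRM", 0.3, (0.0, 1.0))
        bank = ItemBank(list(ref_bank) + [weak])
        _, removed = discrimination_filter(bank)
        assert removed == ["weak"]

    def test_zero_cutoff_identity(self, ref_bank):
        retained, removed = discrimination_filter(ref_bank, cutoff=0.0)
        assert retained == ref_bank.item_ids and removed == []


class TestSummedScoreRecursion:
    def test_single_item_base_case(self, ref_bank):
        nodes = np.array([0.7])
        item = ref_bank.by_id("r3")
        dist = summed_score_distribution([item], nodes)
        assert np.allclose(dist[0], category_probs(item, 0.7))

    def test_two_dichotomous_enumeration(self):
        i1 = ItemParameters("x1", "GRM", 1.1, (-0.4,))
        i2 = ItemParameters("x2", "GRM", 0.9, (0.6,))
        nodes = np.array([0.7])
        p1 = category_probs(i1, 0.7)
        p2 = category_probs(i2, 0.7)
        oracle = np.array(
            [p1[0] * p2[0], p1[0] * p2[1] + p1[1] * p2[0], p1[1] * p2[1]]
        )
        dist = summed_score_distribution([i1, i2], nodes)
        assert np.allclose(dist[0], oracle, atol=1e-14)

    def test_sums_to_one_at_every_node(self, ref_bank):
        grid = ThetaGrid.default()
        dist = summed_score_distribution(list(ref_bank)[:8], grid.nodes)
        assert np.allclose(dist.sum(axis=1), 1.0, atol=1e-10)


class TestItemFit:
    def test_type_one_rate(self, cohort, calibrated):
        resp, _ = cohort
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = s_chi2_item_fit(resp, calibrated.bank)
        assert len(fits) == 20
        reject = np.mean([f.p_value < 0.01 for f in fits])
        assert reject <= 0.10
        for f in fits:
            assert 0.0 <= f.p_value <= 1.0
            assert f.df >= 1


class TestDif:
    def test_proportional_odds_vs_independent_optimizer(self):
        # tiny dataset; independent NLL implementation + Nelder-Mead oracle
        y = np.array([0, 1, 0, 2, 1, 2, 0, 1, 2, 1, 0, 2])
        th = np.array([-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, -0.8, 0.2, 1.4, 0.6, -2.0, 1.8])

        def nll(params):
            beta, c1, d = params
            c2 = c1 + np.exp(d)
            eta1 = c1 - beta * th
            eta2 = c2 - beta * th
            p0 = expit(eta1)
            p1 = expit(eta2) - expit(eta1)
            p2 = 1.0 - expit(eta2)
            probs = np.column_stack([p0, p1, p2])
            return -np.sum(np.log(np.maximum(probs[np.arange(len(y)), y], 1e-12)))

        best = min(
            (
                minimize(nll, [b0, c0, 0.0], method="Nelder-Mead",
                         options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
                for b0 in (-1.0, 0.0, 1.0)
                for c0 in (-1.0, 0.0)
            ),
            key=lambda r: r.fun,
        )
        beta_oracle = best.x[0]

        from statsmodels.miscmodels.ordinal_model import OrderedModel

        res = OrderedModel(y, th[:, None], distr="logit").fit(method="bfgs", disp=0)
        assert res.params[0] == pytest.approx(beta_oracle, abs=1e-3)

    def test_null_no_flags(self, cohort, calibrated):
        resp, _ = cohort
        rng = np.random.default_rng(77)
        group = rng.integers(0, 2, resp.n_persons)
        eaps, _ = batch_eap(resp, calibrated.bank)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = dif_scan(resp, group, eaps)
        assert sum(r.flagged for r in results) == 0
        for r in results:
            if r.estimable:
                assert 0.0 <= r.r2_m1 <= r.r2_m2 + 1e-8
                assert r.r2_m2 <= r.r2_m3 + 1e-8
                assert r.r2_m3 < 1.0

    def test_planted_dif_flagged_and_purified(self, cohort, ref_bank, calibrated):
        resp, thetas = cohort
        rng = np.random.default_rng(78)
        group = rng.integers(0, 2, resp.n_persons)
        spec = DefectSpec(dif_items={"r10": (0.8, 0.5)})
        bad = plant_defects(resp, ref_bank, spec, thetas, group=group.astype(bool), seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results, removed = dif_purify(bad, group, calibrated.bank)
        assert removed == ["r10"]
        assert sum(r.flagged for r in results) == 0  # purified

    def test_small_group_rejected(self, cohort, calibrated):
        resp, _ = cohort
        group = np.zeros(resp.n_persons)
        group[:10] = 1
        eaps, _ = batch_eap(resp, calibrated.bank)
        with pytest.raises(ValueError, match="groups"):
            dif_scan(resp, group, eaps)

    def test_flag_threshold_semantics(self):
        r = DIFResult("x", 0.021, True)
        assert r.flagged and r.pseudo_r2_change > 0.02


@pytest.fixture(scope="module")
def pipeline_run(cohort, ref_bank):
    resp, thetas = cohort
    rng = np.random.default_rng(42)
    group = rng.integers(0, 2, resp.n_persons)
    spec = DefectSpec(
        noise_items=("r4",),
        dif_items={"r10": (0.8, 0.5)},
        dependent_pairs={("r89", "r2"): 0.8},
    )
    bad = plant_defects(resp, ref_bank, spec, thetas, group=group.astype(bool), seed=3)
    cfg = ScreeningConfig(em=FAST)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_screening_pipeline(bad, group=group, config=cfg)


class TestPipeline:
    def test_planted_defects_removed_at_their_stages(self, pipeline_run):
        assert pipeline_run.removal_stage("r4") == "unidimensionality"
        assert pipeline_run.removal_stage("r2") == "local_independence"
        assert pipeline_run.removal_stage("r10") == "dif"

    def test_stage_nesting(self, pipeline_run):
        stages = pipeline_run.stages
        for prev, nxt in zip(stages, stages[1:]):
            assert set(nxt.retained) <= set(prev.retained)

    def test_audit_frame_lists_all_removals(self, pipeline_run):
        audit = pipeline_run.audit_frame()
        assert set(audit["item_id"]) >= {"r4", "r2", "r10"}

    def test_clean_data_mostly_survives(self, cohort):
        resp, _ = cohort
        cfg = ScreeningConfig(em=FAST)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_screening_pipeline(resp, group=None, config=cfg)
        assert len(report.surviving) >= 19  # <= 5% false removals
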