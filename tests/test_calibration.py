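import warnings

import numpy as np
import pytest

from gradedcat import CohortSpec, ItemBank, ItemParameters, simulate_responses
from gradedcat.calibration import (
    EMConfig,
    FitIndices,
    compare_models,
    fit_model,
    n_free_params,
)
from gradedcat.models import ResponseMatrix, category_probs
from gradedcat.synth import _sample_categories

FAST = EMConfig(tol=5e-4, max_cycles=200)


class TestFitIndices:
    def test_arithmetic(self):
        fit = FitIndices(neg2ll=100.0, n_params=10, n_persons=100)
        assert fit.aic == pytest.approx(120.0)
        assert fit.bic == pytest.approx(100 + 10 * np.log(100), abs=1e-10)
        assert fit.bic == pytest.approx(146.0517, abs=1e-4)
        assert fit.aic >= fit.neg2ll

    def test_param_counting_mixed_bank(self):
        # 93 GRM items: 50 four-category + 43 five-category
        cats = [4] * 50 + [5] * 43
        hand_tally = sum(1 + (k - 1) for k in cats)
        assert n_free_params("GRM", cats) == hand_tally == 50 * 4 + 43 * 5

    def test_rsm_counting_requires_common_k(self):
        assert n_free_params("RSM", [4, 4, 4]) == 3 + 4 - 2
        with pytest.raises(ValueError):
            n_free_params("RSM", [4, 5])


class TestFitModel:
    def test_dichotomous_recovery(self):
        # five replicate items make (a, b) identifiable from the joint pattern
        truth = ItemBank(
            [ItemParameters(f"d{j}", "GRM", 1.5, (0.5,)) for j in range(5)]
        )
        errs_a, errs_b = [], []
        for seed in (0, 1, 2):
            resp, _ = simulate_responses(truth, CohortSpec(n_persons=2000, seed=seed))
            res = fit_model(resp, "GRM", FAST)
            errs_a.append(np.mean([it.a for it in res.bank]) - 1.5)
            errs_b.append(np.mean([it.b[0] for it in res.bank]) - 0.5)
        assert abs(np.mean(errs_a)) < 0.15
        assert abs(np.mean(errs_b)) < 0.15

    def test_symmetric_data_symmetric_thresholds(self):
        truth = ItemBank(
            [ItemParameters(f"s{j}", "GRM", 1.2, (-1.0, 1.0)) for j in range(4)]
        )
        resp, _ = simulate_responses(truth, CohortSpec(n_persons=1500, seed=3))
        # augment with the mirrored dataset so responses are exactly symmetric
        flipped = 2 - resp.data
        both = ResponseMatrix(
            np.vstack([resp.data, flipped]), item_ids=truth.item_ids
        )
        res = fit_model(both, "GRM", FAST)
        for it in res.bank:
            assert it.b[0] == pytest.approx(-it.b[1], abs=0.05)

    def test_five_category_reference_recovery(self, ref_bank):
        items = [ref_bank.by_id(f"r{j}") for j in range(84, 94)]
        truth = ItemBank(items)
        resp, _ = simulate_responses(truth, CohortSpec(n_persons=1000, seed=4))
        res = fit_model(resp, "GRM", FAST)
        mae_a = np.mean([abs(e.a - t.a) for e, t in zip(res.bank, truth)])
        assert mae_a < 0.25

    def test_em_monotone_loglik(self, calibrated):
        traj = np.asarray(calibrated.loglik_trajectory)
        assert np.all(np.diff(traj) > -1e-8)
        assert calibrated.converged

    def test_grm_thresholds_ordered(self, calibrated):
        for it in calibrated.bank:
            assert np.all(np.diff(it.b) > 0)

    def test_recovery_improves_with_n(self):
        truth = ItemBank(
            [
                ItemParameters("i1", "GRM", 1.0, (-1.2, 0.2, 1.4)),
                ItemParameters("i2", "GRM", 1.6, (-0.5, 0.7, 1.9)),
                ItemParameters("i3", "GRM", 2.2, (-1.8, -0.3, 1.0)),
                ItemParameters("i4", "GRM", 0.9, (-0.8, 0.9, 2.3)),
                ItemParameters("i5", "GRM", 1.3, (0.0, 1.1, 2.6)),
            ]
        )

        def mae(n, seed):
            resp, _ = simulate_responses(truth, CohortSpec(n_persons=n, seed=seed))
            res = fit_model(resp, "GRM", FAST)
            da = np.mean([abs(e.a - t.a) for e, t in zip(res.bank, truth)])
            db = np.mean(
                [np.abs(np.subtract(e.b, t.b)).mean() for e, t in zip(res.bank, truth)]
            )
            return da + db

        small = np.mean([mae(250, s) for s in (0, 1)])
        large = np.mean([mae(4000, s) for s in (0, 1)])
        assert large < small

    def test_nonconvergence_flagged(self, cohort):
        resp, _ = cohort
        with pytest.warns(UserWarning, match="did not converge"):
            res = fit_model(resp, "GRM", EMConfig(tol=1e-12, max_cycles=2))
        assert not res.converged

    def test_unobserved_category_collapse(self):
        truth = ItemBank([ItemParameters(f"c{j}", "GRM", 1.4, (0.0,)) for j in range(4)])
        resp, _ = simulate_responses(truth, CohortSpec(n_persons=400, seed=5))
        with pytest.raises(ValueError, match="unobserved"):
            fit_model(resp, "GRM", FAST, n_categories=[3, 2, 2, 2])
        cfg = EMConfig(tol=5e-4, max_cycles=200, collapse_unobserved=True)
        res = fit_model(resp, "GRM", cfg, n_categories=[3, 2, 2, 2])
        assert res.collapsed_categories  # the padded item was relabeled

    def test_person_with_no_responses_rejected(self):
        data = np.array([[1, 0], [-1, -1]])
        with pytest.raises(ValueError, match="at least one"):
            fit_model(ResponseMatrix(data), "GRM", FAST)


class TestCompareModels:
    def test_grm_data_prefers_grm_by_aic(self):
        from gradedcat.synth import synth_bank

        bank = synth_bank(10, 4, seed=5)
        resp, _ = simulate_responses(bank, CohortSpec(n_persons=800, seed=5))
        table, results = compare_models(resp, config=FAST)
        assert table.iloc[0]["model"] == "GRM"
        assert set(results) == {"GRM", "GPCM", "RSM"}

    def test_rsm_data_prefers_rsm_by_bic(self):
        rng = np.random.default_rng(7)
        steps = np.array([-1.0, 0.3, 1.2])
        steps -= steps.mean()
        truth = ItemBank(
            [
                ItemParameters(f"r{j}", "RSM", 1.0, tuple(steps), float(loc))
                for j, loc in enumerate(rng.uniform(-1.5, 1.5, size=10))
            ]
        )
        thetas = rng.normal(size=800)
        data = np.column_stack(
            [_sample_categories(category_probs(it, thetas), rng) for it in truth]
        )
        resp = ResponseMatrix(data, item_ids=truth.item_ids)
        table, _ = compare_models(resp, config=FAST)
        assert table.sort_values("bic").iloc[0]["model"] == "RSM"

    def test_nonconvergent_candidate_excluded(self, cohort):
        resp, _ = cohort
        with pytest.warns(UserWarning):
            table, results = compare_models(
                resp, models=("GRM",), config=EMConfig(tol=1e-12, max_cycles=2)
            )
        assert table.empty
        assert not results["GRM"].converged
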