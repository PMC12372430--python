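import warnings

import numpy as np
import pandas as pd
import pytest

from paincat.calibration import CalibrationConfig
from paincat.item_model import Item, ItemBank, ResponseMatrix
from paincat.screening import (
    DISCRIMINATION_BANDS,
    FactorSolution,
    classify_discrimination,
    correlation_matrix,
    dif_wald,
    efa,
    hotdeck_impute,
    loading_filter,
    polychoric,
    polyserial,
    q3_local_dependence,
)
from paincat.synthetic_sim import BankTemplate, generate_bank, generate_cohort


@pytest.fixture(scope="module")
def small_cohort(small_bank):
    cohort, thetas = generate_cohort(small_bank, n=500, seed=31)
    return cohort, thetas


class TestCorrelations:
    def test_unit_diagonal_and_symmetry(self, small_cohort):
        cohort, _ = small_cohort
        sub = ResponseMatrix(
            cohort.respondent_ids,
            cohort.item_ids[:4],
            cohort.responses[:, :4],
        )
        corr = correlation_matrix(sub)
        m = corr.to_numpy()
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m, m.T)

    def test_polychoric_recovers_truth(self):
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], 2000)
        x = np.digitize(z[:, 0], [-1, 0, 1]).astype(float)
        y = np.digitize(z[:, 1], [-0.5, 0.8]).astype(float)
        assert polychoric(x, y) == pytest.approx(0.6, abs=0.07)

    def test_polychoric_null(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, 2000).astype(float)
        y = rng.integers(0, 4, 2000).astype(float)
        assert abs(polychoric(x, y)) < 0.08

    def test_polyserial_recovers_truth(self):
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], 2000)
        y = np.digitize(z[:, 1], [-0.5, 0.8]).astype(float)
        assert polyserial(z[:, 0], y) == pytest.approx(0.6, abs=0.07)

    def test_mixed_types_run(self, small_cohort):
        cohort, _ = small_cohort
        rm = ResponseMatrix(
            cohort.respondent_ids,
            cohort.item_ids[:3],
            cohort.responses[:, :3],
        )
        corr = correlation_matrix(rm, types={cohort.item_ids[0]: "continuous"})
        m = corr.to_numpy()
        assert corr.shape == (3, 3)
        np.testing.assert_allclose(m, m.T)
        assert np.all(np.abs(m) <= 1.0 + 1e-9)

    def test_too_few_items(self, small_cohort):
        cohort, _ = small_cohort
        rm = ResponseMatrix(
            cohort.respondent_ids, cohort.item_ids[:1], cohort.responses[:, :1]
        )
        with pytest.raises(ValueError):
            correlation_matrix(rm)


class TestEfa:
    def test_single_factor_closed_form(self):
        j = 6
        corr = np.full((j, j), 0.49)
        np.fill_diagonal(corr, 1.0)
        sol = efa(corr, 1)
        np.testing.assert_allclose(sol.loadings.to_numpy().ravel(), 0.7, atol=0.01)

    def test_identity_matrix_eigenvalues(self):
        sol = efa(np.eye(10), 1)
        np.testing.assert_allclose(sol.eigenvalues, 1.0, atol=1e-8)

    def test_two_block_oblimin_separates(self):
        blk = np.eye(8)
        blk[:4, :4] = 0.49
        blk[4:, 4:] = 0.49
        np.fill_diagonal(blk, 1.0)
        sol = efa(blk, 2, rotation="oblimin")
        lam = np.abs(sol.loadings.to_numpy())
        primary = lam.max(axis=1)
        secondary = lam.min(axis=1)
        assert np.all(primary > 0.6)
        assert np.all(secondary < 0.30)

    def test_too_many_factors(self):
        with pytest.raises(ValueError):
            efa(np.eye(6), 3)

    def test_unknown_rotation(self):
        with pytest.raises(ValueError):
            efa(np.eye(6), 1, rotation="promax")


class TestLoadingFilter:
    def test_paper_threshold_rules(self):
        lam = pd.DataFrame(
            {
                "F1": [0.29, 0.8, 0.5, 0.31],
                "F2": [0.05, 0.1, 0.5, 0.05],
            },
            index=["low", "clean", "cross", "edge"],
        )
        sol = FactorSolution(2, lam, "none", "ml", np.ones(2))
        kept, excluded = loading_filter(sol, threshold=0.30)
        assert kept == ["clean", "edge"]
        assert "low" in excluded and "no loading" in excluded["low"]
        assert "cross" in excluded and "cross-loading" in excluded["cross"]

    def test_pure_function_of_matrix(self):
        lam = pd.DataFrame({"F1": [0.7, 0.2]}, index=["a", "b"])
        sol = FactorSolution(1, lam, "none", "ml", np.ones(1))
        assert loading_filter(sol) == loading_filter(sol)


class TestQ3:
    def test_independent_data_baseline(self, small_bank, small_cohort):
        cohort, _ = small_cohort
        from paincat.calibration import fit_grm

        fit = fit_grm(cohort, CalibrationConfig(tol=1e-3))
        q3 = q3_local_dependence(cohort, fit.bank)
        j = len(small_bank)
        assert q3["q3"].mean() == pytest.approx(-1 / (j - 1), abs=0.06)
        assert not q3["flagged"].any()

    def test_duplicate_item_flagged(self, small_bank):
        cohort, thetas = generate_cohort(small_bank, n=500, seed=77)
        dup = cohort.responses[:, [0]]
        rm = ResponseMatrix(
            cohort.respondent_ids,
            cohort.item_ids + ["dup"],
            np.hstack([cohort.responses, dup]),
        )
        from paincat.calibration import fit_grm

        fit = fit_grm(rm, CalibrationConfig(tol=1e-3))
        q3 = q3_local_dependence(rm, fit.bank)
        pair = q3[
            (q3["item_1"] == cohort.item_ids[0]) & (q3["item_2"] == "dup")
        ].iloc[0]
        assert pair["q3"] > 0.5
        assert pair["flagged"]

    def test_cutoff_one_nothing_flagged(self, small_cohort):
        cohort, _ = small_cohort
        from paincat.calibration import fit_grm

        fit = fit_grm(cohort, CalibrationConfig(tol=1e-3))
        q3 = q3_local_dependence(cohort, fit.bank, cutoff=1.0)
        assert not q3["flagged"].any()


class TestDifWald:
    def test_single_group_errors(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(ValueError, match="2 groups"):
            dif_wald(cohort, np.array(["F"] * cohort.n_respondents))

    def test_null_mostly_unflagged(self, small_bank):
        cohort, _ = generate_cohort(small_bank, n=1000, seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = dif_wald(cohort, "gender", alpha=0.05)
        assert len(res) == len(small_bank)
        assert sum(r.flagged for r in res) <= 2
        for r in res:
            assert 0 <= r.p_value <= 1
            assert r.wald_statistic >= 0
            assert r.flagged == (r.p_value < 0.05)

    def test_planted_dif_detected(self, small_bank):
        rng = np.random.default_rng(55)
        half = 500
        cohort_f, _ = generate_cohort(small_bank, n=half, seed=56)
        items = list(small_bank.items)
        it0 = items[0]
        items[0] = Item(
            it0.id, it0.instrument, it0.n_categories, it0.discrimination,
            tuple(b + 0.75 for b in it0.thresholds),
        )
        shifted = ItemBank(small_bank.construct, tuple(items))
        cohort_r, _ = generate_cohort(shifted, n=half, seed=57)
        rm = ResponseMatrix(
            [f"r{i}" for i in range(2 * half)],
            small_bank.item_ids,
            np.vstack([cohort_f.responses, cohort_r.responses]),
            covariates=pd.DataFrame({"gender": ["F"] * half + ["M"] * half}),
        )
        res = {r.item_id: r for r in dif_wald(rm, "gender")}
        assert res[it0.id].flagged


class TestClassifyDiscrimination:
    @pytest.mark.parametrize(
        "a,band",
        [
            (0.0, "very_low"),
            (0.34, "very_low"),
            (0.35, "low"),
            (0.64, "low"),
            (0.65, "moderate"),
            (1.34, "moderate"),
            (1.35, "high"),
            (1.69, "high"),
            (1.70, "very_high"),
            (3.0, "very_high"),
        ],
    )
    def test_bands(self, a, band):
        assert classify_discrimination(a) == band

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_discrimination(-0.1)


class TestHotdeckImpute:
    def test_complete_matrix_unchanged(self, small_cohort):
        cohort, _ = small_cohort
        out = hotdeck_impute(cohort, seed=1)
        np.testing.assert_array_equal(out.responses, cohort.responses)

    def test_deterministic_and_complete(self, small_bank):
        cohort, _ = generate_cohort(small_bank, n=300, seed=9, missing_rate=0.1)
        a = hotdeck_impute(cohort, seed=4)
        b = hotdeck_impute(cohort, seed=4)
        assert not np.isnan(a.responses).any()
        np.testing.assert_array_equal(a.responses, b.responses)

    def test_different_seeds_differ(self, small_bank):
        cohort, _ = generate_cohort(small_bank, n=300, seed=9, missing_rate=0.1)
        a = hotdeck_impute(cohort, seed=4)
        b = hotdeck_impute(cohort, seed=5)
        assert not np.array_equal(a.responses, b.responses)

    def test_too_much_missingness(self, small_bank):
        cohort, _ = generate_cohort(small_bank, n=300, seed=9)
        cohort.responses[: int(0.4 * 300), 0] = np.nan
        with pytest.raises(ValueError, match="missingness"):
            hotdeck_impute(cohort)

    def test_calibration_close_after_imputation(self, small_bank):
        from paincat.calibration import fit_grm

        complete, _ = generate_cohort(small_bank, n=800, seed=14)
        holed = complete.copy()
        rng = np.random.default_rng(15)
        mask = rng.random(holed.responses.shape) < 0.10
        holed.responses[mask] = np.nan
        imputed = hotdeck_impute(holed, seed=16)
        fit_c = fit_grm(complete, CalibrationConfig(tol=1e-3))
        fit_i = fit_grm(imputed, CalibrationConfig(tol=1e-3))
        a_c = np.array([it.discrimination for it in fit_c.bank.items])
        a_i = np.array([it.discrimination for it in fit_i.bank.items])
        assert np.max(np.abs(a_c - a_i)) < 0.30
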