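"""Dice overlap, intraclass correlation, coefficient of variation."""

import numpy as np
import pytest

from ppikit import coefficient_of_variation, dice, dice_curves, icc, icc_map


class TestDice:
    def test_identical_nonempty_masks(self):
        mask = np.array([1, 1, 0, 1], dtype=bool)
        assert dice(mask, mask) == 1.0

    def test_disjoint_masks(self):
        assert dice(np.array([1, 0]), np.array([0, 1])) == 0.0

    def test_hand_worked_overlap(self):
        a = np.zeros(12, dtype=bool)
        b = np.zeros(12, dtype=bool)
        a[:4] = True  # |A| = 4
        b[2:8] = True  # |B| = 6, overlap 2
        assert dice(a, b) == pytest.approx(0.4)

    def test_symmetric_and_empty_convention(self, rng):
        a, b = rng.random(30) > 0.6, rng.random(30) > 0.6
        assert dice(a, b) == dice(b, a)
        assert dice(np.zeros(5, bool), np.zeros(5, bool)) == 0.0


class TestDiceCurves:
    def test_identical_maps_give_unit_curve(self, rng):
        t = rng.standard_normal(500) * 3
        for strategy in ("t_threshold", "percentile"):
            curve = dice_curves(t, t, strategy=strategy)
            nonempty = curve.dice[curve.dice > 0]
            assert np.allclose(nonempty, 1.0)

    def test_independent_maps_percentile_95_overlap(self, rng):
        a, b = rng.standard_normal(10_000), rng.standard_normal(10_000)
        curve = dice_curves(a, b, strategy="percentile", grid=np.array([95.0]))
        assert curve.dice[0] == pytest.approx(0.05, abs=0.02)

    def test_percentile_strategy_matches_counts(self, rng):
        a = rng.standard_normal(1000)
        b = rng.standard_normal(1000) * 2 + 1  # systematically different scale
        for g in (80.0, 90.0, 99.0):
            thr_a, thr_b = np.percentile(a, g), np.percentile(b, g)
            assert abs((a >= thr_a).sum() - (b >= thr_b).sum()) <= 1

    def test_negative_sign_selects_negative_tail(self):
        t_a = np.array([-5.0, -3.0, 0.0, 4.0])
        curve = dice_curves(t_a, t_a, sign=-1, grid=np.array([2.0]))
        assert curve.dice[0] == 1.0  # the two negative entries overlap

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            dice_curves(np.zeros(5), np.zeros(5), grid=np.array([]))


class TestICC:
    def test_duplicate_run_gives_one(self, rng):
        col = rng.standard_normal(20)
        assert icc(np.column_stack([col, col])) == pytest.approx(1.0)

    def test_small_matrix_matches_anova_oracle(self):
        x = np.array([[1.0, 2.0], [3.0, 3.5], [5.0, 4.0], [2.0, 2.5]])
        n, k = x.shape
        grand = x.mean()
        ms_subj = k * ((x.mean(1) - grand) ** 2).sum() / (n - 1)
        ms_run = n * ((x.mean(0) - grand) ** 2).sum() / (k - 1)
        ss_err = ((x - grand) ** 2).sum() - ms_subj * (n - 1) - ms_run * (k - 1)
        ms_err = ss_err / ((n - 1) * (k - 1))
        expected = (ms_subj - ms_err) / (ms_subj + (k - 1) * ms_err)
        assert icc(x) == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_consistency_icc(self, rng):
        import pandas as pd
        import pingouin as pg

        x = rng.standard_normal((15, 2)) + rng.standard_normal((15, 1))
        frame = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "run": np.tile([0, 1], 15),
                "score": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(frame, targets="subject", raters="run", ratings="score")
        ref["Type"] = ref["Type"].str.replace("ICC(", "ICC", regex=False).str.rstrip(")")
        icc3 = ref.loc[ref["Type"].isin(["ICC3", "ICCC,1"]), "ICC"].iloc[0]
        icc1 = ref.loc[ref["Type"].isin(["ICC1", "ICC1,1"]), "ICC"].iloc[0]
        assert icc(x, "icc31") == pytest.approx(icc3, rel=1e-8)
        assert icc(x, "icc11") == pytest.approx(icc1, rel=1e-8)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((5000, 2))
        assert abs(icc(x)) < 0.05

    def test_consistency_form_ignores_common_run_shift(self, rng):
        x = rng.standard_normal((25, 2)) + rng.standard_normal((25, 1))
        shifted = x + np.array([0.0, 5.0])
        assert icc(shifted) == pytest.approx(icc(x), rel=1e-10)

    def test_zero_variance_sentinel(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            assert np.isnan(icc(np.ones((5, 2))))


class TestICCMap:
    def test_identical_runs_give_unit_map(self, rng):
        run = rng.standard_normal((10, 30))
        values, hists = icc_map(run, run.copy())
        assert np.allclose(values, 1.0)
        edges, mass = hists["all"]
        assert mass.sum() == pytest.approx(1.0)

    def test_variance_components_ground_truth(self):
        rng = np.random.default_rng(3)
        n, units = 500, 40
        tau2, sigma2 = 1.0, 1.0  # expected ICC = tau2 / (tau2 + sigma2) = 0.5
        subject_effect = rng.standard_normal((n, units)) * np.sqrt(tau2)
        a = subject_effect + rng.standard_normal((n, units)) * np.sqrt(sigma2)
        b = subject_effect + rng.standard_normal((n, units)) * np.sqrt(sigma2)
        values, _ = icc_map(a, b)
        assert values.mean() == pytest.approx(tau2 / (tau2 + sigma2), abs=0.05)

    def test_mask_histograms_normalized(self, rng):
        a, b = rng.standard_normal((8, 50)), rng.standard_normal((8, 50))
        mask = np.zeros(50, dtype=bool)
        mask[:10] = True
        _, hists = icc_map(a, b, masks={"significant": mask})
        for _, mass in hists.values():
            assert mass.sum() == pytest.approx(1.0)


class TestCoefficientOfVariation:
    def test_identical_runs_give_zero(self, rng):
        col = np.abs(rng.standard_normal(12)) + 0.5
        assert coefficient_of_variation(np.column_stack([col, col])) == 0.0

    def test_two_subject_hand_computation(self):
        x = np.exp(np.array([[0.0, 0.2], [0.1, 0.3]]))
        # per-subject variance of the two logs: (0.2^2)/2 = 0.02 each
        expected = (np.exp(np.sqrt(0.02)) - 1.0) * 100.0
        assert coefficient_of_variation(x) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self, rng):
        x = np.abs(rng.standard_normal((10, 2))) + 0.1
        assert coefficient_of_variation(17.3 * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-10
        )

    def test_negative_effects_need_orientation(self):
        x = -np.abs(np.random.default_rng(0).standard_normal((6, 2))) - 0.1
        with pytest.raises(ValueError, match="subject index"):
            coefficient_of_variation(x)
        assert coefficient_of_variation(x, orient_sign=-1) >= 0

    def test_increasing_between_run_discrepancy_raises_cv(self):
        base = np.array([[1.0, 1.0], [2.0, 2.0]])
        values = []
        for shift in (0.1, 0.2, 0.4):
            probe = base.copy()
            probe[:, 1] *= np.exp(shift)
            values.append(coefficient_of_variation(probe))
        assert values[0] < values[1] < values[2]
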