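import numpy as np
import pandas as pd
import pytest

from neurostates import (
    DegenerateDataError,
    SubjectMemory,
    bootstrap_regression,
    mixed_anova_2x2,
    one_sample_t,
    one_sample_t_from_stats,
    pooled_t_test,
)
from neurostates.simulate import simulate_memory


class TestPooledT:
    @pytest.mark.parametrize(
        "m1,sd1,n1,m2,sd2,n2,t_ref,p_ref",
        [
            # cue-clip durations: between- vs within-event clips
            (5.60, 1.43, 10, 5.30, 0.95, 10, 0.55, 0.587),
            # proportion internal details, younger vs older
            (0.888, 0.049, 28, 0.853, 0.063, 26, 2.28, 0.026),
            # between-event cued recall accuracy
            (0.677, 0.198, 28, 0.551, 0.248, 26, 2.06, 0.045),
        ],
    )
    def test_reproduces_published_summary_tests(
        self, m1, sd1, n1, m2, sd2, n2, t_ref, p_ref
    ):
        t, df, p, d = pooled_t_test(m1, sd1, n1, m2, sd2, n2)
        assert df == n1 + n2 - 2
        assert t == pytest.approx(t_ref, abs=0.02)
        assert p == pytest.approx(p_ref, abs=0.005)

    def test_cohens_d_for_internal_details(self):
        _, _, _, d = pooled_t_test(0.888, 0.049, 28, 0.853, 0.063, 26)
        assert d == pytest.approx(0.622, abs=0.005)

    def test_identical_groups(self):
        t, df, p, d = pooled_t_test(1.0, 0.5, 10, 1.0, 0.5, 10)
        assert t == pytest.approx(0.0) and d == pytest.approx(0.0)

    def test_zero_variance_cases(self):
        t, _, p, d = pooled_t_test(2.0, 0.0, 5, 2.0, 0.0, 5)
        assert (t, d) == (0.0, 0.0)
        with pytest.raises(DegenerateDataError):
            pooled_t_test(2.0, 0.0, 5, 3.0, 0.0, 5)


class TestOneSampleT:
    def test_zero_variance_flagged(self):
        with pytest.raises(DegenerateDataError):
            one_sample_t([0.5, 0.5, 0.5])

    def test_summary_reconstruction_of_alignment_test(self, rng):
        # group mean adjusted match 0.237 (SD 0.141, n 28) vs 0
        t, df, p, d = one_sample_t_from_stats(0.237, 0.141, 28)
        assert t == pytest.approx(8.90, abs=0.01)
        assert df == 27 and p < 0.001
        # exact-moment sample gives the same answer through the data path
        x = rng.normal(size=28)
        x = (x - x.mean()) / x.std(ddof=1) * 0.141 + 0.237
        t2, _, _, _ = one_sample_t(x)
        assert t2 == pytest.approx(t, abs=1e-9)

    def test_null_calibration(self):
        gen = np.random.default_rng(0)
        rejections = sum(
            one_sample_t(gen.normal(size=15))[2] < 0.05 for _ in range(200)
        )
        assert 0.005 <= rejections / 200 <= 0.105


class TestMixedAnova:
    def test_identical_condition_means_give_zero_f(self):
        y = np.tile([[0.5, 0.5]], (10, 1))
        res = mixed_anova_2x2(y, ["younger"] * 5 + ["older"] * 5)
        assert np.allclose(res["F"], 0.0)

    def test_pure_condition_shift(self, rng):
        base = rng.normal(0.7, 0.001, size=10)
        y = np.column_stack([base + 0.2, base])
        res = mixed_anova_2x2(y, ["younger"] * 5 + ["older"] * 5)
        assert res.loc["condition", "F"] > 100
        assert res.loc["group", "F"] < 5

    def test_matches_pingouin_on_unbalanced_random_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        n1, n2 = 28, 26
        y = rng.normal(0.7, 0.2, size=(n1 + n2, 2))
        y[:n1, 0] += 0.1
        groups = ["younger"] * n1 + ["older"] * n2
        mine = mixed_anova_2x2(y, groups)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n1 + n2), 2),
                "group": np.repeat(groups, 2),
                "cond": ["w", "b"] * (n1 + n2),
                "y": y.ravel(),
            }
        )
        ref = pg.mixed_anova(
            data=df, dv="y", within="cond", between="group", subject="subject"
        ).set_index("Source")
        for src, mine_name in [
            ("group", "group"), ("cond", "condition"), ("Interaction", "interaction"),
        ]:
            assert mine.loc[mine_name, "F"] == pytest.approx(ref.loc[src, "F"], abs=1e-9)
            assert mine.loc[mine_name, "eta_p2"] == pytest.approx(
                ref.loc[src, "np2"], abs=1e-9
            )

    def test_missing_condition_rejected(self):
        y = np.array([[0.5, np.nan], [0.4, 0.6], [0.2, 0.3], [0.7, 0.5]])
        with pytest.raises(ValueError, match="subject index 0"):
            mixed_anova_2x2(y, ["younger", "younger", "older", "older"])


class TestBootstrapRegression:
    def _cohort(self, seed=0, slope=-1.5, noise=0.04, n_young=28, n_old=26,
                group_effect=0.035):
        rng = np.random.default_rng(seed)
        deltas = np.concatenate(
            [rng.normal(-0.011, 0.010, n_young), rng.normal(-0.017, 0.015, n_old)]
        )
        groups = ["younger"] * n_young + ["older"] * n_old
        mems = simulate_memory(
            deltas, groups, slope=slope, noise_sd=noise, seed=seed + 1,
            group_effect=group_effect,
        )
        y = np.array([m.proportion_internal for m in mems])
        return y, deltas, groups

    def test_noiseless_recovery_is_exact(self):
        y, x, groups = self._cohort(seed=2, slope=-1.5, noise=0.0)
        reg = bootstrap_regression(y, x, groups, B=200, seed=3)
        assert reg.coef_point["neural"] == pytest.approx(-1.5, abs=1e-8)
        assert reg.coef_point["group"] == pytest.approx(0.035, abs=1e-8)
        assert reg.coef_point["neural_x_group"] == pytest.approx(0.0, abs=1e-8)

    def test_single_group_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="both age groups"):
            bootstrap_regression(x * 2, x, ["younger"] * 10, B=10, seed=0)

    def test_bootstrap_median_converges_to_ols(self):
        y, x, groups = self._cohort(seed=5)
        reg = bootstrap_regression(y, x, groups, B=20000, seed=6)
        for term in ("neural", "group"):
            point = reg.coef_point[term]
            assert abs(reg.coef_boot_median[term] - point) < 0.05 * abs(point) + 1e-4

    def test_permuted_x_rarely_significant(self):
        # fully null cohort: no neural slope and no group effect
        y, x, groups = self._cohort(seed=7, slope=0.0, group_effect=0.0)
        gen = np.random.default_rng(8)
        nonsig = 0
        n_rep = 60
        for i in range(n_rep):
            reg = bootstrap_regression(y, gen.permutation(x), groups, B=20, seed=i)
            nonsig += reg.model_p > 0.05
        assert nonsig / n_rep >= 0.85

    def test_group_coding_flip_negates_group_and_interaction(self):
        y, x, groups = self._cohort(seed=9)
        flipped = ["older" if g == "younger" else "younger" for g in groups]
        a = bootstrap_regression(y, x, groups, B=50, seed=1)
        b = bootstrap_regression(y, x, flipped, B=50, seed=1)
        assert b.coef_point["group"] == pytest.approx(-a.coef_point["group"], abs=1e-9)
        assert b.coef_point["neural_x_group"] == pytest.approx(
            -a.coef_point["neural_x_group"], abs=1e-9
        )


class TestSubjectMemory:
    def test_consistent_counts_accepted(self):
        SubjectMemory(
            "s1", "younger", proportion_internal=0.9,
            detail_counts={"event": 50, "perceptual": 20, "conceptual": 20,
                           "external": 5, "incorrect": 5},
        )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SubjectMemory(
                "s1", "younger", proportion_internal=0.5,
                detail_counts={"event": 50, "perceptual": 20, "conceptual": 20,
                               "external": 5, "incorrect": 5},
            )

    def test_range_checks(self):
        with pytest.raises(ValueError):
            SubjectMemory("s1", "younger", proportion_internal=1.2)
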