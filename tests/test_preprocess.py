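import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwgtraj import preprocess as pp


def toy_cohort(n=3):
    return pd.DataFrame(
        {
            "woman_id": np.arange(n),
            "age_years": 30.0,
            "height_m": 1.65,
            "prepreg_weight_kg": [71.0, 60.0, 80.0][:n],
            "ethnicity_region": "Australian/European",
            "parity_class": "0",
        }
    )


class TestComputeGwg:
    def test_zero_gain(self):
        visits = pd.DataFrame(
            {"woman_id": [0], "gest_age_weeks": [20.0], "weight_kg": [71.0]}
        )
        obs = pp.compute_gwg(visits, toy_cohort(1))
        assert obs.gwg_kg.iloc[0] == 0.0

    def test_negative_gain_preserved(self):
        visits = pd.DataFrame(
            {"woman_id": [0], "gest_age_weeks": [12.0], "weight_kg": [66.0]}
        )
        obs = pp.compute_gwg(visits, toy_cohort(1))
        assert obs.gwg_kg.iloc[0] == -5.0

    def test_five_row_subtraction_oracle(self):
        visits = pd.DataFrame(
            {
                "woman_id": [0, 0, 1, 2, 2],
                "gest_age_weeks": [10.0, 30.0, 20.0, 15.0, 38.0],
                "weight_kg": [72.5, 81.0, 58.25, 85.0, 93.3],
            }
        )
        cohort = toy_cohort(3)
        obs = pp.compute_gwg(visits, cohort)
        base = cohort.set_index("woman_id").prepreg_weight_kg
        expect = [
            w - base[i] for i, w in zip(visits.woman_id, visits.weight_kg)
        ]
        assert np.allclose(obs.gwg_kg.to_numpy(), expect)

    def test_round_trip_invariant(self):
        rng = np.random.default_rng(0)
        visits = pd.DataFrame(
            {
                "woman_id": rng.integers(0, 3, 20),
                "gest_age_weeks": rng.uniform(5, 40, 20),
                "weight_kg": rng.uniform(55, 95, 20),
            }
        )
        cohort = toy_cohort(3)
        obs = pp.compute_gwg(visits, cohort)
        base = cohort.set_index("woman_id").prepreg_weight_kg
        rebuilt = obs.gwg_kg.to_numpy() + base[obs.woman_id].to_numpy()
        merged = visits.sort_values(["woman_id", "gest_age_weeks"])
        got = obs.sort_values(["woman_id", "gest_age_weeks"])
        assert np.allclose(
            np.sort(rebuilt), np.sort(visits.weight_kg.to_numpy())
        )

    def test_missing_prepreg_dropped_and_counted(self):
        cohort = toy_cohort(3)
        cohort.loc[1, "prepreg_weight_kg"] = np.nan
        visits = pd.DataFrame(
            {
                "woman_id": [0, 1, 2],
                "gest_age_weeks": [20.0, 20.0, 20.0],
                "weight_kg": [75.0, 75.0, 85.0],
            }
        )
        rep = pp.PreprocessReport()
        obs = pp.compute_gwg(visits, cohort, rep)
        assert len(obs) == 2
        assert rep.n_missing_prepreg == 1

    def test_covariates_joined_complete(self):
        visits = pd.DataFrame(
            {"woman_id": [0], "gest_age_weeks": [20.0], "weight_kg": [75.0]}
        )
        obs = pp.compute_gwg(visits, toy_cohort(1))
        assert set(pp.OBS_COLUMNS) <= set(obs.columns)
        assert not obs[["age_years", "bmi"]].isna().any().any()
        assert obs.bmi.iloc[0] == pytest.approx(71.0 / 1.65 ** 2)


class TestWeek0:
    def test_variance_formula(self):
        assert pp.week0_variance(0.70) == pytest.approx(0.98)
        with pytest.raises(ValueError):
            pp.week0_variance(0.0)

    def test_pseudo_rows_flagged_at_zero(self):
        w0 = pp.draw_week0(toy_cohort(3), seed=1)
        assert (w0.gest_age_weeks == 0.0).all()
        assert w0.is_week0_pseudo.all()
        assert len(w0) == 3

    def test_sample_variance_chisq_interval(self):
        cohort = toy_cohort(3)
        big = pd.concat([cohort] * 1, ignore_index=True)
        big = pd.DataFrame(
            {
                "woman_id": np.arange(100_000),
                "age_years": 30.0,
                "height_m": 1.65,
                "prepreg_weight_kg": 70.0,
                "ethnicity_region": "x",
                "parity_class": "0",
            }
        )
        w0 = pp.draw_week0(big, seed=5)
        v = w0.gwg_kg.var(ddof=0)
        assert 0.95 < v < 1.01
        assert abs(w0.gwg_kg.mean()) < 4 * np.sqrt(0.98 / 100_000)

    def test_ks_against_reference_normal(self):
        big = pd.DataFrame(
            {
                "woman_id": np.arange(10_000),
                "age_years": 30.0,
                "height_m": 1.65,
                "prepreg_weight_kg": 70.0,
                "ethnicity_region": "x",
                "parity_class": "0",
            }
        )
        w0 = pp.draw_week0(big, seed=8)
        stat, pval = stats.kstest(
            w0.gwg_kg, "norm", args=(0.0, np.sqrt(0.98))
        )
        assert pval > 0.01

    def test_reproducible(self):
        a = pp.draw_week0(toy_cohort(3), seed=2)
        b = pp.draw_week0(toy_cohort(3), seed=2)
        pd.testing.assert_frame_equal(a, b)


def _obs(gest, gwg, pseudo=None):
    n = len(gest)
    return pd.DataFrame(
        {
            "woman_id": np.arange(n),
            "gest_age_weeks": gest,
            "gwg_kg": gwg,
            "is_week0_pseudo": pseudo if pseudo is not None else [False] * n,
            "age_years": 30.0,
            "bmi": 24.0,
            "ethnicity_region": "x",
            "parity_class": "0",
        }
    )


class TestExclude4sd:
    def test_toy_outlier_removed(self):
        obs = _obs([20.0] * 5, [0.0, 0.1, -0.1, 0.05, 50.0])
        kept, n_exc, _ = pp.exclude_4sd(obs)
        # brute-force leave-one-out oracle on the toy set
        vals = np.array([0.0, 0.1, -0.1, 0.05, 50.0])
        expect_out = []
        for i, v in enumerate(vals):
            others = np.delete(vals, i)
            expect_out.append(
                abs(v - others.mean()) > 4 * others.std(ddof=1)
            )
        assert n_exc == sum(expect_out) == 1
        assert 50.0 not in kept.gwg_kg.to_numpy()

    def test_identical_values_nothing_removed(self):
        obs = _obs([20.0] * 10, [2.0] * 10)
        kept, n_exc, _ = pp.exclude_4sd(obs)
        assert n_exc == 0 and len(kept) == 10

    def test_normal_tail_oracle(self):
        rng = np.random.default_rng(3)
        n = 100_000
        obs = _obs(np.full(n, 20.0), rng.normal(0, 1, n))
        kept, n_exc, _ = pp.exclude_4sd(obs)
        # expected exclusions ~ 2 n Phi(-4) ~ 6
        assert n_exc < 20

    def test_pseudo_rows_never_excluded(self):
        gest = [0.0] + [20.0] * 5
        gwg = [100.0, 0.0, 0.1, -0.1, 0.05, 50.0]
        obs = _obs(gest, gwg, pseudo=[True] + [False] * 5)
        kept, n_exc, _ = pp.exclude_4sd(obs)
        assert kept.is_week0_pseudo.sum() == 1
        assert 100.0 in kept.gwg_kg.to_numpy()

    def test_idempotent_with_fixed_windows(self):
        rng = np.random.default_rng(4)
        n = 2000
        obs = _obs(
            rng.uniform(4, 42, n), rng.standard_t(3, n) * (1 + rng.uniform(0, 2, n))
        )
        kept, n1, windows = pp.exclude_4sd(obs)
        kept2, n2, _ = pp.exclude_4sd(kept, windows=windows)
        assert n2 == 0
        pd.testing.assert_frame_equal(kept, kept2)

    def test_too_few_observations_raises(self):
        obs = _obs([20.0], [1.0])
        with pytest.raises(ValueError):
            pp.exclude_4sd(obs)


class TestBmiCategory:
    def test_printed_examples(self):
        assert pp.bmi_category(24.5, "China") == "overweight"
        assert pp.bmi_category(24.5, "Australian/European") == "normal"
        assert pp.bmi_category(25.0, "Korea") == "obese"
        assert pp.bmi_category(18.5, "WHO") == "normal"

    def test_region_scheme_mapping(self):
        assert pp.scheme_for_region("Mainland Asian").label == "China"
        assert pp.scheme_for_region("Korea").label == "Korea"
        # Japanese/Taiwanese birth regions use WHO
        assert pp.scheme_for_region("Northeast Asian").label == "WHO"
        assert pp.scheme_for_region("African").label == "WHO"

    @pytest.mark.parametrize("scheme", ["WHO", "China", "Korea"])
    def test_exhaustive_and_exclusive(self, scheme):
        grid = np.arange(10.0, 60.0 + 1e-9, 0.1)
        cats = pp.BMI_SCHEMES[scheme].category(grid)
        assert set(np.unique(cats)) == set(pp.BMI_CATEGORIES)
        # category is a step function with left-closed boundaries
        cuts = pp.BMI_SCHEMES[scheme].cuts
        for c, lo_cat, hi_cat in zip(
            cuts,
            pp.BMI_CATEGORIES[:-1],
            pp.BMI_CATEGORIES[1:],
        ):
            assert pp.BMI_SCHEMES[scheme].category([c - 1e-9])[0] == lo_cat
            assert pp.BMI_SCHEMES[scheme].category([c])[0] == hi_cat

    def test_invalid_bmi_raises(self):
        with pytest.raises(ValueError):
            pp.bmi_category(0.0, "WHO")

    def test_invalid_scheme_boundaries(self):
        with pytest.raises(ValueError):
            pp.BmiScheme("bad", (25.0, 18.5, 30.0))


class TestRebaseline:
    def test_two_visit_example(self):
        visits = pd.DataFrame(
            {
                "woman_id": [0, 0],
                "gest_age_weeks": [10.0, 30.0],
                "weight_kg": [66.0, 75.0],
            }
        )
        obs = pp.rebaseline_first_visit(visits, toy_cohort(1))
        assert np.allclose(sorted(obs.gwg_kg), [0.0, 9.0])

    def test_single_visit_anchor(self):
        visits = pd.DataFrame(
            {"woman_id": [0], "gest_age_weeks": [15.0], "weight_kg": [70.0]}
        )
        obs = pp.rebaseline_first_visit(visits, toy_cohort(1))
        assert len(obs) == 1
        assert obs.gwg_kg.iloc[0] == 0.0
        assert obs.gest_age_weeks.iloc[0] == 15.0

    def test_unsorted_input(self):
        visits = pd.DataFrame(
            {
                "woman_id": [0, 0, 0],
                "gest_age_weeks": [30.0, 10.0, 20.0],
                "weight_kg": [80.0, 66.0, 72.0],
            }
        )
        obs = pp.rebaseline_first_visit(visits, toy_cohort(1))
        anchored = obs.sort_values("gest_age_weeks")
        assert np.allclose(anchored.gwg_kg.to_numpy(), [0.0, 6.0, 14.0])
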