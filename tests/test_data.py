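"""Records, outcome construction, recoding and design matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import zigreg as zg
from zigreg.data import CategoricalTerm, NumericTerm


class TestWeeklyMinutes:
    @pytest.mark.parametrize(
        "days,minutes,expected", [(3, 30, 90), (0, 45, 0), (7, 60, 420), (1, 12.5, 12.5)]
    )
    def test_product_rule(self, days, minutes, expected):
        assert zg.weekly_minutes(days, minutes) == expected

    @pytest.mark.parametrize("days,minutes", [(-1, 30), (8, 30), (3, -5)])
    def test_invalid_inputs_rejected(self, days, minutes):
        with pytest.raises(ValueError):
            zg.weekly_minutes(days, minutes)


class TestCategorize:
    @pytest.mark.parametrize(
        "minutes,expected",
        [(0, "none"), (149.9, "low"), (150, "high"), (0.1, "low"), (1000, "high")],
    )
    def test_three_levels_with_inclusive_150(self, minutes, expected):
        assert zg.categorize(minutes) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            zg.categorize(-1.0)
        with pytest.raises(ValueError):
            zg.categorize_minutes(np.array([10.0, -1.0]))

    @given(
        days=st.integers(min_value=0, max_value=7),
        minutes=st.floats(min_value=0, max_value=500, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_zero_category_iff_no_activity(self, days, minutes):
        total = zg.weekly_minutes(days, minutes)
        is_none = zg.categorize(total) == "none"
        assert is_none == (days == 0 or minutes == 0)


class TestOutcomeViews:
    def test_views_are_synchronised(self):
        views = zg.outcome_views([0.0, 10.0, 150.0, 149.999, 0.0])
        assert list(views.any_activity) == [0, 1, 1, 1, 0]
        assert list(views.category3) == ["none", "low", "high", "low", "none"]
        # zero minutes, inactivity and the none category coincide
        assert np.array_equal(views.any_activity == 0, views.y_minutes == 0)
        assert np.array_equal(views.category3 == "none", views.y_minutes == 0)

    def test_negative_minutes_rejected(self):
        with pytest.raises(ValueError):
            zg.outcome_views([1.0, -2.0])


class TestBuildDesign:
    def test_reference_profile_gives_zero_dummies(self):
        df = pd.DataFrame(
            [{"gender": "female", "education": "basic", "age_years": 50.0,
              "income_usd": 5000.0}]
        )
        dm = zg.build_design(df)
        assert list(dm.columns) == [
            "intercept", "male", "high_school", "college", "graduate",
            "age_decades", "income_k",
        ]
        np.testing.assert_allclose(dm.values[0], [1, 0, 0, 0, 0, 5.0, 5.0])

    def test_dummy_and_scaling_arithmetic(self):
        df = pd.DataFrame(
            [{"gender": "male", "education": "graduate", "age_years": 35.0,
              "income_usd": 12000.0}]
        )
        np.testing.assert_allclose(
            zg.build_design(df).values[0], [1, 1, 0, 0, 1, 3.5, 12.0]
        )

    def test_complete_case_rule(self, small_table):
        dm = zg.build_design(small_table)
        assert dm.n == 3
        assert dm.n_dropped == 1

    def test_unknown_education_rejected(self, small_table):
        bad = small_table.assign(education=["basic", "phd", "college", "college"])
        with pytest.raises(ValueError, match="education"):
            zg.build_design(bad)

    def test_case_insensitive_levels(self, small_table):
        dm = zg.build_design(small_table)
        # rows 2 and 4 use odd capitalisation; the male dummy must still work
        male = dm.values[:, dm.column_index("male")]
        assert list(male) == [0.0, 1.0, 1.0]

    def test_row_permutation_equivariance(self, small_table, rng):
        full = small_table.dropna()
        perm = rng.permutation(len(full))
        dm = zg.build_design(full)
        dm_perm = zg.build_design(full.iloc[perm])
        np.testing.assert_allclose(dm_perm.values, dm.values[perm])

    @given(
        n_levels=st.lists(st.integers(min_value=2, max_value=5), min_size=0,
                          max_size=3),
        n_numeric=st.integers(min_value=0, max_value=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_column_count_formula(self, n_levels, n_numeric):
        terms = []
        for i, L in enumerate(n_levels):
            levels = tuple(f"c{i}_l{j}" for j in range(L))
            terms.append(CategoricalTerm(f"cat{i}", levels, reference=levels[0]))
        terms += [NumericTerm(f"num{i}") for i in range(n_numeric)]
        spec = zg.DesignSpec(terms=tuple(terms))
        expected = 1 + sum(L - 1 for L in n_levels) + n_numeric
        assert spec.n_columns == expected

    def test_at_most_one_education_dummy_per_row(self, simulated_cohort):
        _, dm = simulated_cohort
        edu = dm.values[:, 2:5]
        assert set(np.unique(edu)) <= {0.0, 1.0}
        assert edu.sum(axis=1).max() <= 1
        np.testing.assert_allclose(dm.values[:, 0], 1.0)


class TestCsvRoundTrip:
    def test_write_then_read(self, small_table, tmp_path):
        path = tmp_path / "participants.csv"
        zg.write_participants_csv(small_table, path)
        back = zg.read_participants_csv(path)
        assert len(back) == len(small_table)
        assert back["income_usd"].isna().sum() == 1

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"id": [1], "gender": ["female"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="required columns"):
            zg.read_participants_csv(path)

    def test_negative_minutes_rejected(self, small_table, tmp_path):
        path = tmp_path / "neg.csv"
        small_table.assign(weekly_minutes=[-1.0, 0, 0, 0]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="negative"):
            zg.read_participants_csv(path)


def test_participant_record_canonicalises_levels():
    rec = zg.ParticipantRecord(
        id=1, gender="Woman", age_years=40.0, education="High School",
        income_usd=1000.0, weekly_minutes=30.0,
    )
    assert rec.gender == "female"
    assert rec.education == "high_school"
    with pytest.raises(ValueError):
        zg.ParticipantRecord(id=2, gender="female", age_years=40.0,
                             education="basic", income_usd=1.0,
                             weekly_minutes=-3.0)
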