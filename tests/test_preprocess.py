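"""Bidirectional preprocessing: encoding, quantile machinery, inversion."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tabsafe.fixtures import FixtureSpec, generate_cohort
from tabsafe.preprocess import (
    PLACEHOLDER,
    encode_dates,
    fit_quantile_grid,
    fit_transform,
    fit_transform_level12,
    FittedTransform,
    inverse_quantile_transform,
    inverse_transform,
    quantile_transform,
)
from tabsafe.schema import ColumnSpec, StudyConfig


class TestDateEncoding:
    @pytest.mark.parametrize(
        "day, expected",
        [("2010-05-20", 3792), ("2003-02-01", 1127), ("2000-01-01", 0)],
    )
    def test_day_counts_against_calendar_oracle(self, day, expected):
        s = pd.Series(pd.to_datetime([day]))
        got = encode_dates(s, date(2000, 1, 1)).iloc[0]
        oracle = (date.fromisoformat(day) - date(2000, 1, 1)).days
        assert got == expected == oracle

    def test_missing_dates_stay_missing(self):
        s = pd.Series(pd.to_datetime(["2010-05-20", None]))
        out = encode_dates(s, date(2000, 1, 1))
        assert out.notna().iloc[0] and np.isnan(out.iloc[1])


class TestQuantileGrid:
    def test_grid_strictly_increasing_with_ties_collapsed(self):
        gv, gl = fit_quantile_grid(np.array([5.0, 1.0, 5.0, 9.0, 5.0]))
        assert gv.tolist() == [1.0, 5.0, 9.0]
        # levels (i-0.5)/5; the tied 5s at positions 2,3,4 average to 0.5
        np.testing.assert_allclose(gl, [0.1, 0.5, 0.9])
        assert np.all(np.diff(gv) > 0) and np.all(np.diff(gl) > 0)

    def test_minimum_maps_to_lowest_boundary_level(self):
        gv, gl = fit_quantile_grid(np.arange(10.0))
        q = quantile_transform(np.array([0.0, -100.0]), gv, gl)
        assert q[0] == q[1] == gl[0]  # clamped at the lower grid boundary

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50),
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=20),
    )
    def test_monotone_and_bijective_on_grid(self, sample, queries):
        gv, gl = fit_quantile_grid(np.array(sample))
        q = quantile_transform(np.array(sorted(queries)), gv, gl)
        assert np.all(np.diff(q) >= 0)  # x <= y => T(x) <= T(y)
        back = inverse_quantile_transform(
            quantile_transform(gv, gv, gl), gv, gl
        )
        np.testing.assert_allclose(back, gv, rtol=1e-12, atol=1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            quantile_transform(np.array([1.0]), np.array([]), np.array([]))


class TestWorkedExampleEncoding:
    """The printed five-patient table drives the exact pipeline contract."""

    @pytest.fixture()
    def encoded(self, five_patients, five_patient_config):
        return fit_transform(five_patients, five_patient_config)

    def test_missing_flags_match_printed_table(self, encoded):
        enc, _ = encoded
        flags = enc.data[["diagnosis_date_q_m", "blood_pressure_q_m"]].to_numpy()
        np.testing.assert_array_equal(
            flags, [[0, 0], [1, 1], [0, 0], [0, 0], [1, 0]]
        )

    def test_record3_one_hot_unknown(self, encoded):
        enc, _ = encoded
        row = enc.data.iloc[2]
        assert row["smoking_status=Unknown"] == 1.0
        for level in ("Current", "Former", "Never"):
            assert row[f"smoking_status={level}"] == 0.0

    def test_imputed_records_share_median_quantile(self, encoded):
        enc, _ = encoded
        q = enc.data["diagnosis_date_q"]
        # median of observed dates equals record 1's date, so 1, 2, 5 coincide
        assert q.iloc[0] == q.iloc[1] == q.iloc[4]
        assert q.iloc[3] < q.iloc[0] < q.iloc[2]

    def test_blood_pressure_rank_order_preserved(self, encoded):
        enc, _ = encoded
        bp_q = enc.data["blood_pressure_q"].to_numpy()
        # raw 120, 130 (imputed median), 180, 95, 140
        assert (
            bp_q[3] < bp_q[0] < bp_q[1] < bp_q[4] < bp_q[2]
        )

    def test_round_trip_restores_printed_table(
        self, encoded, five_patients, five_patient_config
    ):
        enc, tf = encoded
        back = inverse_transform(enc, tf, five_patient_config)
        for col in ("diagnosis_date", "blood_pressure", "smoking_status"):
            pd.testing.assert_series_equal(back[col], five_patients[col])

    def test_provenance_and_dimensional_accounting(self, encoded):
        enc, _ = encoded
        # 2 numeric columns with flags (2·2) + 3 categories + placeholder
        assert enc.shape[1] == 2 * 2 + 4
        kinds = {k for _, k in enc.provenance.values()}
        assert kinds == {"quantile_value", "missing_flag", "onehot_level"}


@pytest.mark.parametrize("seed", range(10))
def test_fixture_round_trip_property(seed):
    """inverse ∘ forward is the identity on randomized cohorts."""
    spec = FixtureSpec(n_rows=80, seed=seed)
    cohort = generate_cohort(spec)
    config = spec.study_config()
    enc, tf = fit_transform(cohort, config)
    back = inverse_transform(enc, tf, config)
    _assert_round_trip(cohort, back, config)


def _assert_round_trip(cohort, back, config):
    for spec_col in config.columns:
        name, role = spec_col.name, spec_col.role
        if role == "identifier":
            continue
        a, b = cohort[name], back[name]
        assert (a.isna() == b.isna()).all(), name
        if role == "continuous":
            np.testing.assert_allclose(
                a.dropna(), b.dropna(), rtol=1e-9, err_msg=name
            )
        else:
            assert (a.dropna() == b.dropna()).all(), name


def test_flags_equal_missingness_mask(small_cohort):
    cohort, config = small_cohort
    enc, tf = fit_transform(cohort, config)
    for name in [c.name for c in config.by_role("continuous", "date")]:
        mask = cohort[name].isna().to_numpy(float)
        np.testing.assert_array_equal(enc.data[f"{name}_q_m"].to_numpy(), mask)


def test_one_hot_partition(small_cohort):
    cohort, config = small_cohort
    enc, _ = fit_transform(cohort, config)
    for name in [c.name for c in config.by_role("binary", "categorical")]:
        cols = [c for c, (src, kind) in enc.provenance.items()
                if src == name and kind == "onehot_level"]
        np.testing.assert_array_equal(enc.data[cols].sum(axis=1), 1.0)


def test_encoded_column_accounting(small_cohort):
    cohort, config = small_cohort
    enc, tf = fit_transform(cohort, config)
    n_numeric = len(config.by_role("continuous", "date"))
    n_flags = sum(st.has_flag for st in tf.numeric.values())
    n_onehot = sum(
        len(c.categories) + 1 for c in config.by_role("binary", "categorical")
    )
    assert enc.shape[1] == n_numeric + n_flags + n_onehot


def test_indicator_threshold_selects_high_missingness(small_cohort):
    cohort, config = small_cohort
    enc, tf = fit_transform(cohort, config, indicator_threshold=0.5)
    flagged = {n for n, st in tf.numeric.items() if st.has_flag}
    high = {
        c.name
        for c in config.by_role("continuous", "date")
        if cohort[c.name].isna().mean() >= 0.5
    }
    assert flagged == high


def test_all_missing_column_rejected(five_patient_config):
    df = pd.DataFrame(
        {
            "ID": ["1"],
            "diagnosis_date": pd.to_datetime([None]),
            "blood_pressure": [np.nan],
            "smoking_status": ["Never"],
        }
    )
    with pytest.raises(ValueError, match="no observed values"):
        fit_transform(df, five_patient_config)


def test_transform_json_round_trip(small_cohort):
    cohort, config = small_cohort
    enc, tf = fit_transform(cohort, config)
    tf2 = FittedTransform.from_dict(tf.to_dict())
    back = inverse_transform(enc, tf2, config)
    _assert_round_trip(cohort, back, config)


class TestLevel12:
    def _config(self):
        return StudyConfig(
            columns=[
                ColumnSpec("x", "continuous"),
                ColumnSpec("grp", "categorical", categories=("a", "b")),
            ]
        )

    def test_constant_imputation(self):
        df = pd.DataFrame({"x": [5.0, np.nan, 7.0], "grp": ["a", "b", None]})
        enc, tf = fit_transform_level12(df, self._config())
        assert enc.data["x"].tolist() == [5.0, -1.0, 7.0]
        assert enc.provenance["x"] == ("x", "passthrough")
        assert enc.data[f"grp={PLACEHOLDER}"].tolist() == [0.0, 0.0, 1.0]

    def test_no_missing_passthrough_identity(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "grp": ["a", "b", "a"]})
        enc, _ = fit_transform_level12(df, self._config())
        assert enc.data["x"].tolist() == [1.0, 2.0, 3.0]

    def test_inverse_maps_sentinel_back_to_missing(self):
        df = pd.DataFrame({"x": [5.0, np.nan, 7.0], "grp": ["a", "b", "b"]})
        cfg = self._config()
        enc, tf = fit_transform_level12(df, cfg)
        back = inverse_transform(enc, tf, cfg)
        assert np.isnan(back["x"].iloc[1])
        assert back["x"].iloc[0] == 5.0

    def test_sentinel_collision_declared_lossy(self):
        df = pd.DataFrame({"x": [-1.0, np.nan, 7.0], "grp": ["a", "b", "b"]})
        cfg = self._config()
        enc, tf = fit_transform_level12(df, cfg)
        assert tf.numeric["x"].lossy
        back = inverse_transform(enc, tf, cfg)
        # inversion keeps the observed −1 rather than faking missingness
        assert back["x"].iloc[0] == -1.0
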