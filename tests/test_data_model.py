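import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heckcrash.data_model import (IntersectionYearRecord, SelectionDesign,
                                  build_design, compute_crash_rate,
                                  compute_exposure, correlation_screen,
                                  count_observations, summarize)
from heckcrash.exceptions import (CollinearityError, ConfigError,
                                  InvalidInputError)


class TestExposureAndRate:
    @pytest.mark.parametrize("aadt, expected", [
        (903, 329_595.0),
        (1, 365.0),
        (121_221, 44_245_665.0),
    ])
    def test_exposure_is_aadt_times_365(self, aadt, expected):
        assert compute_exposure(aadt) == expected

    def test_exposure_rejects_nonpositive(self):
        with pytest.raises(InvalidInputError):
            compute_exposure(0)
        with pytest.raises(InvalidInputError):
            compute_exposure(-10)

    @pytest.mark.parametrize("count, exposure, expected", [
        (0, 1234.5, 0.0),
        (2, 1e6, 2.0),
        (3, 365 * 10_000, 0.8219),
    ])
    def test_rate_per_million_vehicles(self, count, exposure, expected):
        assert compute_crash_rate(count, exposure) == pytest.approx(
            expected, abs=5e-5)

    def test_rate_rejects_bad_input(self):
        with pytest.raises(InvalidInputError):
            compute_crash_rate(1, 0)
        with pytest.raises(InvalidInputError):
            compute_crash_rate(-1, 100)

    @given(count=st.integers(0, 50), exposure=st.floats(1e3, 1e8))
    @settings(max_examples=50, deadline=None)
    def test_rate_homogeneity(self, count, exposure):
        base = compute_crash_rate(count, exposure)
        assert compute_crash_rate(2 * count, exposure) == pytest.approx(
            2 * base)
        assert compute_crash_rate(count, 2 * exposure) == pytest.approx(
            base / 2)


class TestRecordValidation:
    def test_valid_record_accepted(self):
        r = IntersectionYearRecord("I1", 2002, aadt=30_000, slight_count=2,
                                   comveh=0.2, tramstop=1)
        assert r.aadt == 30_000

    @pytest.mark.parametrize("kwargs", [
        {"aadt": -1}, {"aadt": 30_000, "slight_count": -2},
        {"aadt": 30_000, "comveh": 1.5}, {"aadt": 30_000, "tramstop": 2},
    ])
    def test_invalid_record_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            IntersectionYearRecord("I1", 2002, **kwargs)


class TestCountObservations:
    def base_frame(self, slight, ksi):
        return pd.DataFrame({"intersection_id": ["a"], "aadt": [10_000.0],
                             "slight_count": [slight], "ksi_count": [ksi]})

    def test_zero_crash_year_is_single_observation(self):
        obs = count_observations(self.base_frame(0, 0))
        assert len(obs) == 1
        assert obs.loc[0, "severity"] is None
        assert obs.loc[0, "selected"] == 0

    def test_one_crash_yields_two_severity_observations(self):
        obs = count_observations(self.base_frame(1, 0))
        assert len(obs) == 2
        assert set(obs["severity"]) == {"slight", "ksi"}
        # the slight row is observed, the KSI row censored
        by_sev = obs.set_index("severity")
        assert by_sev.loc["slight", "selected"] == 1
        assert by_sev.loc["ksi", "selected"] == 0

    def test_multi_crash_year_yields_one_row_per_category(self):
        obs = count_observations(self.base_frame(3, 1))
        assert len(obs) == 2
        by_sev = obs.set_index("severity")
        assert by_sev.loc["slight", "selected"] == 1
        assert by_sev.loc["ksi", "selected"] == 1
        exposure = 10_000 * 365
        assert by_sev.loc["slight", "crash_rate"] == pytest.approx(
            3e6 / exposure)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            count_observations(self.base_frame(-1, 0))


class TestSummarize:
    def test_category_shares_round_to_integer_percent(self):
        df = pd.DataFrame({
            "aadt": np.full(555, 30_000.0),
            "severity": [None] * 134 + ["slight"] * 335 + ["ksi"] * 86,
        })
        summ = summarize(df)
        assert summ.n_observations == 555
        assert summ.percentages["zero_crash"] == 24
        assert summ.percentages["slight"] == 60

    def test_identical_records_have_zero_sd(self):
        df = pd.DataFrame({"aadt": [5_000.0] * 4, "cycletime": [90.0] * 4})
        summ = summarize(df)
        assert (summ.stats["sd"] == 0).all()

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize(pd.DataFrame())

    def test_partition_percentages_sum_to_100_within_rounding(self):
        df = pd.DataFrame({
            "aadt": np.full(101, 1000.0),
            "severity": [None] * 33 + ["slight"] * 35 + ["ksi"] * 33,
        })
        summ = summarize(df)
        total = (summ.percentages["zero_crash"] + summ.percentages["slight"]
                 + summ.percentages["ksi"])
        assert abs(total - 100) <= 1


class TestCorrelationScreen:
    def test_duplicated_column_flagged_at_unity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        flagged = correlation_screen(np.column_stack([x, x]),
                                     names=["a", "b"])
        assert flagged == [("a", "b", pytest.approx(1.0))]

    def test_sign_flip_flagged_at_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        flagged = correlation_screen(np.column_stack([x, -x]))
        assert flagged[0][2] == pytest.approx(-1.0)

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10_000, 4))
        assert correlation_screen(X, threshold=0.6) == []

    def test_zero_variance_column_warned_not_fatal(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=50), np.ones(50),
                             rng.normal(size=50)])
        with pytest.warns(UserWarning, match="zero-variance"):
            flagged = correlation_screen(X, threshold=0.99)
        assert flagged == []

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))
        X[:, 1] = 0.9 * X[:, 0] + 0.1 * X[:, 1]
        f1 = correlation_screen(X, threshold=0.5)
        X2 = X * np.array([3.0, 0.2, 10.0]) + np.array([1.0, -5.0, 0.0])
        f2 = correlation_screen(X2, threshold=0.5)
        assert [(a, b) for a, b, _ in f1] == [(a, b) for a, b, _ in f2]
        assert f1[0][2] == pytest.approx(f2[0][2])

    def test_too_few_rows_or_columns_rejected(self):
        with pytest.raises(InvalidInputError):
            correlation_screen(np.ones((10, 1)))
        with pytest.raises(InvalidInputError):
            correlation_screen(np.ones((2, 3)))


class TestDesign:
    def test_build_design_shapes_and_intercepts(self, intersection_frame):
        df = intersection_frame.copy()
        exposure = df["aadt"] * 365
        df["slight_rate"] = df["slight_count"] * 1e6 / exposure
        df["slight_obs"] = (df["slight_count"] > 0).astype(int)
        design = build_design(df, "slight_rate", "slight_obs",
                              ["reciprad", "cycletime"],
                              ["reciprad", "tramstop", "kln"])
        assert design.X.shape == (len(df), 3)
        assert design.Z.shape == (len(df), 4)
        assert design.x_names[0] == "const"
        assert (design.X[:, 0] == 1).all()

    def test_unknown_column_is_config_error(self, intersection_frame):
        with pytest.raises(ConfigError):
            build_design(intersection_frame, "slight_count", "kln",
                         ["nope"], ["reciprad"])

    def test_duplicate_column_raises_collinearity(self, intersection_frame):
        df = intersection_frame.copy()
        df["slight_obs"] = (df["slight_count"] > 0).astype(int)
        df["reciprad2"] = df["reciprad"]
        with pytest.raises(CollinearityError):
            build_design(df, "slight_count", "slight_obs",
                         ["reciprad", "reciprad2"], ["kln"])

    def test_missing_rows_dropped_with_warning(self, intersection_frame):
        df = intersection_frame.copy()
        df["slight_obs"] = (df["slight_count"] > 0).astype(int)
        df.loc[3, "reciprad"] = np.nan
        with pytest.warns(UserWarning, match="dropped 1 rows"):
            design = build_design(df, "slight_count", "slight_obs",
                                  ["reciprad"], ["kln"])
        assert design.n == len(df) - 1

    def test_design_requires_single_intercept(self):
        y = np.zeros(5)
        s = np.array([1, 0, 1, 0, 1])
        X_no_const = np.arange(10, dtype=float).reshape(5, 2)
        Z = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(InvalidInputError):
            SelectionDesign(y=y, X=X_no_const, Z=Z, s=s)
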