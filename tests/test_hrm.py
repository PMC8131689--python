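"""Heat-pulse velocity, flow conversion, corrections, daily integration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cacaoflow import hrm


GEOM = hrm.ProbeGeometry()  # k=0.0025 cm2/s, x=0.6 cm


class TestHeatPulseVelocity:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (1.0, 0.0),
            (1.2, 2.734823351909319),  # (0.0025/0.6)*ln(1.2)*3600
            (1 / 1.2, -2.734823351909319),
        ],
    )
    def test_reference_values(self, ratio, expected):
        assert hrm.heat_pulse_velocity(ratio, GEOM) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_ratio_names_timestamp(self):
        ts = pd.to_datetime(["2015-01-13 10:00", "2015-01-13 10:01"])
        with pytest.raises(ValueError, match="2015-01-13"):
            hrm.heat_pulse_velocity(np.array([1.1, -0.5]), GEOM, timestamps=ts)
        with pytest.raises(ValueError):
            hrm.heat_pulse_velocity(0.0, GEOM)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_under_ratio_inversion(self, r):
        v1 = hrm.heat_pulse_velocity(r, GEOM)
        v2 = hrm.heat_pulse_velocity(1.0 / r, GEOM)
        assert v1 == pytest.approx(-v2, abs=1e-9 * max(1.0, abs(v1)))


class TestFlowConversion:
    def test_unit_factor_collapses_to_one(self):
        wood = hrm.SapwoodProperties(rho_b=1000, rho_s=1000, m_c=1e-12, C_w=4186, C_s=4186, S=1000)
        assert hrm.sap_flow_rate(1.0, wood) == pytest.approx(1.0, rel=1e-9)

    def test_hand_computed_example(self):
        wood = hrm.SapwoodProperties(rho_b=500, rho_s=1000, m_c=1.0, C_w=1200, C_s=4186, S=40)
        # 0.5 * (1 + 1200/4186) * 2.7348 * 40 / 1000
        assert hrm.sap_flow_rate(2.7348, wood) == pytest.approx(0.070376, abs=1e-5)
        assert hrm.sap_flow_rate(0.0, wood) == 0.0

    @given(
        st.floats(min_value=-50, max_value=50, allow_subnormal=False),
        st.floats(min_value=-10, max_value=10, allow_subnormal=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_linear_and_sign_preserving(self, vh, a):
        wood = hrm.SapwoodProperties()
        assert hrm.sap_flow_rate(a * vh, wood) == pytest.approx(a * hrm.sap_flow_rate(vh, wood), abs=1e-9)
        if abs(vh) > 1e-12:
            assert np.sign(hrm.sap_flow_rate(vh, wood)) == np.sign(vh)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="rho_b"):
            hrm.SapwoodProperties(rho_b=0)
        with pytest.raises(ValueError, match="depths"):
            hrm.ProbeGeometry(depths=(20.0, 5.0))


class TestWoundCorrection:
    @pytest.mark.parametrize(
        "vh, coeffs, expected",
        [(5.0, (1, 0, 0), 5.0), (2.0, (1.1, 0, 0), 2.2), (0.0, (1.7, 0.3, -0.2), 0.0)],
    )
    def test_polynomial(self, vh, coeffs, expected):
        assert hrm.wound_correction(vh, coeffs) == pytest.approx(expected)


class TestZeroOffset:
    def _series(self, values):
        idx = pd.date_range("2015-01-13", periods=len(values), freq="1min")
        return pd.Series(values, index=idx)

    def test_constant_series_zeroed(self):
        s = self._series([0.5] * 5)
        out = hrm.zero_offset_correction(s, (s.index[0], s.index[-1] + pd.Timedelta("1min")))
        assert np.allclose(out, 0.0)

    def test_partial_window(self):
        s = self._series([1.0, 2.0, 3.0])
        out = hrm.zero_offset_correction(s, (s.index[0], s.index[2]))
        assert np.allclose(out, [-0.5, 0.5, 1.5])

    def test_idempotent_and_identity_on_zero_baseline(self):
        s = self._series([-1.0, 1.0, 5.0])
        win = (s.index[0], s.index[2])  # baseline mean already 0
        once = hrm.zero_offset_correction(s, win)
        assert np.allclose(once, s)
        assert np.allclose(hrm.zero_offset_correction(once, win), once)

    def test_empty_window_errors(self):
        s = self._series([1.0, 2.0])
        with pytest.raises(ValueError, match="baseline window"):
            hrm.zero_offset_correction(s, (s.index[0] - pd.Timedelta("2h"), s.index[0] - pd.Timedelta("1h")))


class TestCombineDepths:
    @pytest.mark.parametrize(
        "velocities, weights, expected",
        [
            ({5: 2.0, 20: 2.0}, None, 2.0),
            ({5: 3.0, 20: 1.0}, None, 2.0),
            ({5: 3.0, 20: 1.0}, {5: 1.0, 20: 0.0}, 3.0),
        ],
    )
    def test_weighted_mean(self, velocities, weights, expected):
        assert hrm.combine_depths(velocities, weights) == pytest.approx(expected)

    def test_mismatched_keys_error(self):
        with pytest.raises(ValueError, match="depth keys"):
            hrm.combine_depths({5: 1.0, 20: 2.0}, {5: 1.0, 25: 1.0})


class TestDailyCumulative:
    def _frame(self, start, periods, freq, value):
        ts = pd.date_range(start, periods=periods, freq=freq)
        v = np.full(periods, value) if np.isscalar(value) else np.asarray(value)
        return pd.DataFrame({"timestamp": ts, "plant_id": "p1", "vs_l_h": v})

    def test_constant_flow_full_day(self):
        df = self._frame("2015-01-13 00:00", 24 * 60 + 1, "1min", 0.1)
        out = hrm.daily_cumulative(df)
        day1 = out[out["date"] == pd.Timestamp("2015-01-13").date()]
        assert day1["cumulative_l"].iloc[0] == pytest.approx(2.4, abs=1e-9)
        assert not day1["gap_flag"].iloc[0]

    def test_negative_constant_half_day(self):
        df = self._frame("2015-01-13 00:00", 12 * 60 + 1, "1min", -0.04)
        out = hrm.daily_cumulative(df)
        assert out["cumulative_l"].iloc[0] == pytest.approx(-0.48, abs=1e-9)

    def test_empty_day_absent_and_gap_flagged(self):
        a = self._frame("2015-01-13 00:00", 60, "1min", 0.1)
        b = self._frame("2015-01-15 00:00", 60, "1min", 0.1)
        out = hrm.daily_cumulative(pd.concat([a, b], ignore_index=True))
        assert pd.Timestamp("2015-01-14").date() not in set(out["date"])
        assert out["gap_flag"].all()  # the 2-day hole straddles both days

    def test_unsorted_errors(self):
        df = self._frame("2015-01-13 00:00", 3, "1min", 0.1).iloc[[2, 0, 1]]
        with pytest.raises(ValueError, match="not sorted"):
            hrm.daily_cumulative(df)


class TestProcessRaw:
    def _raw(self):
        ts = pd.date_range("2015-01-13 10:00", periods=3, freq="1min")
        rows = []
        for depth in (5.0, 20.0):
            rows.append(pd.DataFrame({"timestamp": ts, "plant_id": "H_PAR_p1", "depth_mm": depth, "ratio": [1.0, 1.2, 1 / 1.2]}))
        return pd.concat(rows, ignore_index=True)

    def test_pipeline_with_identity_corrections(self):
        out = hrm.process_raw(self._raw(), {"H_PAR_p1": "H_PAR"})
        assert list(out.columns) == list(hrm.PROCESSED_COLUMNS)
        assert out["vh_cm_h"].to_numpy() == pytest.approx([0.0, 2.734823, -2.734823], abs=1e-5)
        assert np.sign(out["vs_l_h"]).tolist() == [0.0, 1.0, -1.0]

    def test_t1_t2_input_equivalent(self):
        raw = self._raw()
        raw["t1_c"] = raw["ratio"] * 2.0
        raw["t2_c"] = 2.0
        out_ratio = hrm.process_raw(raw.drop(columns=[]), {"H_PAR_p1": "H_PAR"})
        out_tt = hrm.process_raw(raw.drop(columns=["ratio"]), {"H_PAR_p1": "H_PAR"})
        assert np.allclose(out_ratio["vs_l_h"], out_tt["vs_l_h"])

    def test_unknown_plant_errors(self):
        with pytest.raises(ValueError, match="no AF label"):
            hrm.process_raw(self._raw(), {"other": "H_PAR"})
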