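"""Cohort-change ratio/difference/child-woman-ratio computations."""

import math

import numpy as np
import pytest

from cohortengine.cohort_change import (
    build_series,
    compute_ccd,
    compute_ccr,
    compute_cwr,
    compute_open_interval,
)
from cohortengine.panel import PanelValidationError
from conftest import make_panel, uniform_panel


def _value(df, **keys):
    sel = np.ones(len(df), dtype=bool)
    for k, v in keys.items():
        sel &= df[k] == v
    out = df.loc[sel, "value"]
    assert len(out) == 1
    return float(out.iloc[0])


class TestCCR:
    def test_printed_cohort_example(self, toy_panel):
        ccr = compute_ccr(toy_panel, t=2000, y=5)
        r = _value(ccr, age=3, sex=1)
        assert r == 1.25
        # applying the ratio to the current 5-9 population projects 10-14
        assert r * 90 == 112.5

    def test_shale_boom_cohort(self):
        panel = make_panel(
            [("38053", 1, 1, 4, 2010, 416.0), ("38053", 1, 1, 5, 2015, 1027.0)]
        )
        r = _value(compute_ccr(panel, t=2015, y=5), age=5, sex=1)
        assert r == 1027 / 416
        assert math.trunc(r * 100) / 100 == 2.46

    def test_identical_populations_give_unit_ratios(self):
        panel = uniform_panel()
        ccr = compute_ccr(panel, t=2000, y=5)
        assert np.allclose(ccr["value"].to_numpy(), 1.0)

    def test_zero_denominator_masked(self):
        panel = make_panel(
            [("01001", 1, 1, 2, 1995, 0.0), ("01001", 1, 1, 3, 2000, 10.0)]
        )
        assert np.isnan(_value(compute_ccr(panel, 2000), age=3, sex=1))

    def test_missing_earlier_census_is_error(self, toy_panel):
        with pytest.raises(KeyError, match="1990"):
            compute_ccr(toy_panel, t=1995, y=5)


class TestCCD:
    def test_printed_cohort_example(self, toy_panel):
        d = _value(compute_ccd(toy_panel, t=2000, y=5), age=3, sex=1)
        assert d == 25.0
        assert d + 90 == 115.0

    def test_shale_boom_difference(self):
        panel = make_panel(
            [("38053", 1, 1, 4, 2010, 416.0), ("38053", 1, 1, 5, 2015, 1027.0)]
        )
        assert _value(compute_ccd(panel, t=2015, y=5), age=5, sex=1) == 611.0

    def test_identical_populations_give_zero_differences(self):
        ccd = compute_ccd(uniform_panel(), t=2000, y=5)
        assert np.allclose(ccd["value"].to_numpy(), 0.0)


class TestOpenInterval:
    def _panel(self, p85_t, p80_prev, p85_prev):
        return make_panel(
            [
                ("01001", 1, 1, 17, 1995, p80_prev),
                ("01001", 1, 1, 18, 1995, p85_prev),
                ("01001", 1, 1, 18, 2000, p85_t),
            ]
        )

    def test_ratio_uses_pooled_80_plus(self):
        df = compute_open_interval(self._panel(50, 40, 60), 2000, kind="CCR")
        assert _value(df, sex=1) == 50 / 100

    def test_difference_uses_pooled_80_plus(self):
        df = compute_open_interval(self._panel(30, 100, 0), 2000, kind="CCD")
        assert _value(df, sex=1) == -70.0

    def test_stationary_pool(self):
        df = compute_open_interval(self._panel(100, 40, 60), 2000, kind="CCR")
        assert _value(df, sex=1) == 1.0
        df = compute_open_interval(self._panel(100, 40, 60), 2000, kind="CCD")
        assert _value(df, sex=1) == 0.0

    def test_zero_pool_masked_for_ratio(self):
        df = compute_open_interval(self._panel(10, 0, 0), 2000, kind="CCR")
        assert np.isnan(_value(df, sex=1))

    def test_empty_85_at_prior_census_reduces_to_plain_ratio(self):
        """With no 85+ population at t-y the open-interval ratio equals the
        ordinary cohort ratio from the 80-84 group alone."""
        df = compute_open_interval(self._panel(50, 40, 0.0), 2000, kind="CCR")
        assert _value(df, sex=1) == 50 / 40


class TestCWR:
    def test_direct_arithmetic(self):
        rows = [("01001", 1, s, 1, 2000, 25.0) for s in (1, 2)]
        rows += [("01001", 1, 2, g, 2000, 400.0 / 7) for g in range(4, 11)]
        df = compute_cwr(make_panel(rows), t=2000)
        assert _value(df, state="01", race=1) == pytest.approx(50 / 400, abs=1e-12)

    def test_single_county_state_pooling_identity(self):
        rows = [("01001", 1, s, 1, 2000, 10.0) for s in (1, 2)]
        rows += [("01001", 1, 2, g, 2000, 20.0) for g in range(4, 11)]
        df = compute_cwr(make_panel(rows), t=2000)
        assert _value(df, state="01", race=1) == pytest.approx(20 / 140, abs=1e-12)

    def test_pooled_sum_not_mean_of_ratios(self):
        """Two counties with 20/100 and 30/300: the state CWR is the pooled
        50/400 = 0.125, not the mean of the two county ratios (0.15)."""
        rows = []
        for area, ch, wo in (("01001", 20.0, 100.0), ("01002", 30.0, 300.0)):
            rows += [(area, 1, s, 1, 2000, ch / 2) for s in (1, 2)]
            rows += [(area, 1, 2, g, 2000, wo / 7) for g in range(4, 11)]
        df = compute_cwr(make_panel(rows), t=2000)
        assert _value(df, state="01", race=1) == pytest.approx(0.125, abs=1e-12)

    def test_childbearing_ages_are_15_to_49(self):
        # women outside codes 4-10 must not enter the denominator
        rows = [("01001", 1, s, 1, 2000, 10.0) for s in (1, 2)]
        rows += [("01001", 1, 2, g, 2000, 50.0) for g in range(4, 11)]
        rows += [("01001", 1, 2, 3, 2000, 999.0), ("01001", 1, 2, 11, 2000, 999.0)]
        df = compute_cwr(make_panel(rows), t=2000)
        assert _value(df, state="01", race=1) == pytest.approx(20 / 350, abs=1e-12)


class TestBuildSeries:
    def test_series_lengths_and_counts(self):
        panel = uniform_panel(years=(1990, 1995, 2000), areas=("01001", "01002"))
        coll = build_series(panel, y=5, kind="CCR")
        # 2 areas x 1 race x 2 sexes x 17 destination ages
        assert coll.n_ccr == 68
        s = coll.get("CCR", ("01001", 1, 1, 5))
        assert len(s) == 2
        assert list(s.times) == [1995, 2000]
        # CWR is defined at every census, so its series covers all 3 points
        assert len(coll.get("CWR", ("01", 1))) == 3

    def test_single_census_is_error(self):
        with pytest.raises(PanelValidationError, match="two"):
            build_series(uniform_panel(years=(2000,)), y=5)

    def test_unequal_spacing_is_error(self):
        panel = uniform_panel(years=(1990, 1995, 2005))
        with pytest.raises(PanelValidationError, match="spaced"):
            build_series(panel, y=5)

    def test_tidy_frame_round_trip(self):
        panel = uniform_panel(years=(1995, 2000))
        frame = build_series(panel, y=5, kind="both").frame()
        assert set(frame["kind"]) == {"CCR", "CCD", "CWR"}
        ccr = frame[frame["kind"] == "CCR"]
        # ordinary ages are stationary at ratio 1; the open interval is fed
        # by the doubled 80+ pool, so its stationary ratio is one half
        assert np.allclose(ccr.loc[ccr["age"] < 18, "value"], 1.0)
        assert np.allclose(ccr.loc[ccr["age"] == 18, "value"], 0.5)
        ccd = frame[frame["kind"] == "CCD"]
        assert np.allclose(ccd.loc[ccd["age"] < 18, "value"], 0.0)
        assert np.allclose(ccd.loc[ccd["age"] == 18, "value"], -100.0)


class TestAlgebraicIdentities:
    def test_ccd_equals_ccr_minus_one_times_denominator(self, ccr_fixture):
        """CCD = (CCR - 1) x source cohort, cell-wise, on positive panels."""
        _, panel, _ = ccr_fixture
        coll = build_series(panel, kind="both")
        dense = panel.to_dense()
        src = dense.values[..., :-1, :-1].copy()
        src[..., -1, :] = dense.values[..., 16, :-1] + dense.values[..., 17, :-1]
        lhs = coll.ccd
        rhs = (coll.ccr - 1.0) * src
        assert np.nanmax(np.abs(lhs - rhs) / np.maximum(np.abs(lhs), 1e-9)) < 1e-12

    def test_projection_inverse_consistency(self, ccr_fixture):
        """Applying the measured ratio (or difference) back to the source
        populations reproduces the destination populations exactly."""
        _, panel, _ = ccr_fixture
        coll = build_series(panel, kind="both")
        dense = panel.to_dense()
        src = dense.values[..., :-1, :-1].copy()
        src[..., -1, :] = dense.values[..., 16, :-1] + dense.values[..., 17, :-1]
        dest = dense.values[..., 1:, 1:]
        assert np.allclose(coll.ccr * src, dest, rtol=1e-12)
        assert np.allclose(coll.ccd + src, dest, rtol=1e-12)

    def test_parameter_recovery_from_clean_panel(self, ccr_fixture):
        spec, panel, truth = ccr_fixture
        coll = build_series(panel, kind="both")
        assert np.nanmax(np.abs(coll.ccr - truth.ccr[..., None])) < 1e-9
        assert np.nanmax(np.abs(coll.cwr - truth.cwr[..., None])) < 1e-9
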