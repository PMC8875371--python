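"""Wall averaging, RMSE metric, LBBB feature detection."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioem.errors import ValidationError
from cardioem.segments import LATERAL_WALL, SEPTAL_WALL
from cardioem.strain import (
    StrainTrace,
    WallCurve,
    detect_features,
    rmse,
    wall_average,
)


def make_trace(values: dict[str, np.ndarray], t=None) -> StrainTrace:
    n = len(next(iter(values.values())))
    t = np.arange(n) * 10.0 if t is None else t
    return StrainTrace(time=t, strain=pd.DataFrame(values))


def flat_curve(value: float, n: int = 50) -> WallCurve:
    return WallCurve("septal", np.arange(n) * 10.0, np.full(n, value))


class TestWallAverage:
    def test_five_identical_curves_average_to_themselves(self):
        curve = np.sin(np.linspace(0, 2 * np.pi, 80)) * 10
        trace = make_trace({s: curve.copy() for s in SEPTAL_WALL})
        wc = wall_average(trace, "septal")
        assert np.allclose(wc.strain, curve)
        assert wc.segments == SEPTAL_WALL

    def test_constant_curves_average_arithmetically(self):
        consts = [-10.0, -20.0, -15.0, -12.0, -18.0]
        trace = make_trace({s: np.full(30, c)
                            for s, c in zip(LATERAL_WALL, consts)})
        wc = wall_average(trace, "lateral")
        assert np.allclose(wc.strain, np.mean(consts))

    def test_average_is_permutation_invariant(self):
        rng = np.random.default_rng(7)
        data = {s: rng.normal(size=40) for s in SEPTAL_WALL}
        a = wall_average(make_trace(data), "septal").strain
        shuffled = {s: data[s] for s in reversed(SEPTAL_WALL)}
        b = wall_average(make_trace(shuffled), "septal").strain
        assert np.allclose(a, b)

    def test_septal_wall_uses_only_the_five_septal_segments(self):
        # lateral/free-wall columns present but must not contribute
        data = {s: np.full(20, -10.0) for s in SEPTAL_WALL}
        data |= {s: np.full(20, +99.0) for s in LATERAL_WALL}
        wc = wall_average(make_trace(data), "septal")
        assert np.allclose(wc.strain, -10.0)
        assert set(wc.segments) == set(SEPTAL_WALL)

    def test_missing_segment_is_named_in_the_error(self):
        data = {s: np.zeros(10) for s in SEPTAL_WALL[:-1]}
        with pytest.raises(ValidationError, match="basal_anteroseptal"):
            wall_average(make_trace(data), "septal")


class TestRmse:
    def test_identical_curves_give_zero(self):
        c = flat_curve(-12.0)
        assert rmse(c, c) == 0.0

    def test_constant_offset_gives_that_offset(self):
        assert rmse(flat_curve(-10.0), flat_curve(-12.0)) == pytest.approx(2.0)

    def test_gaussian_noise_rmse_matches_chi_expectation(self):
        rng = np.random.default_rng(1234)
        t = np.linspace(0.0, 900.0, 200)
        base = -18.0 * np.exp(-0.5 * ((t - 400) / 150.0) ** 2)
        a = WallCurve("septal", t, base)
        b = WallCurve("septal", t, base + rng.normal(0.0, 1.5, t.size))
        assert 1.2 <= rmse(a, b, n=200) <= 1.8

    def test_cycle_normalization_aligns_different_rr(self):
        t1 = np.linspace(0.0, 900.0, 120)
        t2 = np.linspace(0.0, 1000.0, 150)
        shape = lambda x: -15.0 * np.sin(np.pi * x) ** 2
        a = WallCurve("septal", t1, shape(t1 / 900.0))
        b = WallCurve("septal", t2, shape(t2 / 1000.0))
        assert rmse(a, b) < 0.05

    def test_non_overlapping_supports_rejected_without_normalization(self):
        a = WallCurve("septal", np.arange(0.0, 100.0, 10.0), np.zeros(10))
        b = WallCurve("septal", np.arange(500.0, 600.0, 10.0), np.zeros(10))
        with pytest.raises(ValidationError, match="non-overlapping"):
            rmse(a, b, normalize=False)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-30, 30), min_size=8, max_size=40),
           st.lists(st.floats(-30, 30), min_size=8, max_size=40),
           st.lists(st.floats(-30, 30), min_size=8, max_size=40))
    def test_rmse_is_a_metric(self, xs, ys, zs):
        def curve(vals):
            return WallCurve("septal", np.linspace(0, 900, len(vals)),
                             np.array(vals))
        a, b, c = curve(xs), curve(ys), curve(zs)
        assert rmse(a, b) == pytest.approx(rmse(b, a), rel=1e-12)  # symmetry
        assert rmse(a, a) == 0.0
        assert rmse(a, c) <= rmse(a, b) + rmse(b, c) + 1e-9  # triangle


class TestFeatures:
    def _dip_rebound(self, dip=5.0, rebound=4.0):
        t = np.linspace(0.0, 900.0, 181)
        s = (-dip * np.exp(-0.5 * ((t - 100) / 40.0) ** 2)
             + (rebound - dip) * np.exp(-0.5 * ((t - 320) / 60.0) ** 2)
             - 10.0 * np.exp(-0.5 * ((t - 600) / 120.0) ** 2))
        return WallCurve("septal", t, s)

    def test_monotone_shortening_has_no_flash(self):
        t = np.linspace(0.0, 900.0, 181)
        s = -18.0 * np.sin(np.pi * np.clip(t / 800.0, 0, 1)) ** 2
        f = detect_features(WallCurve("septal", t, s), (250.0, 550.0))
        assert not f.septal_flash
        assert f.rebound_stretch == 0.0

    def test_dip_plus_rebound_is_flagged(self):
        f = detect_features(self._dip_rebound(), (150.0, 500.0))
        assert f.septal_flash
        assert f.pre_ejection_shortening == pytest.approx(5.0, abs=0.3)
        assert f.rebound_stretch > 1.0

    def test_subthreshold_dip_not_flagged(self):
        f = detect_features(self._dip_rebound(dip=0.8), (150.0, 500.0))
        assert not f.septal_flash

    def test_amplifying_the_rebound_never_decreases_it(self):
        base = self._dip_rebound()
        f0 = detect_features(base, (150.0, 500.0))
        bumped = WallCurve("septal", base.time, base.strain
                           + 2.0 * np.exp(-0.5 * ((base.time - 350) / 50.0) ** 2))
        f1 = detect_features(bumped, (150.0, 500.0))
        assert f1.rebound_stretch >= f0.rebound_stretch

    def test_window_outside_support_rejected(self):
        with pytest.raises(ValidationError, match="window"):
            detect_features(self._dip_rebound(), (800.0, 1200.0))
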