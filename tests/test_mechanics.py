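"""Segment mechanics primitives and their coupling contracts."""

from __future__ import annotations

import numpy as np
import pytest

from cardioem.config import load_config
from cardioem.engine import run
from cardioem.errors import ValidationError
from cardioem.mechanics import (
    AtriumParams,
    SegmentParams,
    active_tension,
    atrial_pressure,
    emd_drive,
    passive_tension,
    segment_flow_dynamics,
    segment_strain,
    septal_load,
    twitch_peak_time,
)
from cardioem.segments import LV_SEGMENTS, RV_SEGMENTS, SEPTAL_WALL

ATRIUM = AtriumParams(e_min=0.1, e_max=0.3, v0=10.0, mu=80.0, sigma=45.0)
SEG = SegmentParams(name="mid_anterior")


class TestAtrium:
    def test_unstressed_volume_gives_zero_pressure(self):
        assert atrial_pressure(10.0, 500.0, 0.0, ATRIUM) == 0.0

    def test_gaussian_peak_gives_emax(self):
        p = atrial_pressure(60.0, 80.0, 0.0, ATRIUM)  # t - t_act = mu
        assert p == pytest.approx(0.3 * 50.0)

    def test_far_from_activation_gives_emin(self):
        p = atrial_pressure(60.0, 5000.0, 0.0, ATRIUM)
        assert p == pytest.approx(0.1 * 50.0, rel=1e-6)

    def test_invalid_elastances_rejected(self):
        with pytest.raises(ValidationError):
            AtriumParams(e_min=0.3, e_max=0.1, v0=10, mu=80, sigma=45).validate()


class TestDrive:
    def test_zero_before_mechanical_onset(self):
        t = np.array([0.0, 10.0, SEG.t_delay - 1.0])
        assert np.all(emd_drive(t, 0.0, SEG) == 0.0)

    def test_no_activation_means_zero_drive(self):
        assert np.all(emd_drive(np.arange(0.0, 500.0), None, SEG) == 0.0)

    def test_peak_is_normalized_to_one(self):
        t_peak = SEG.t_delay + twitch_peak_time(SEG.tau_c, SEG.tau_r)
        assert emd_drive(t_peak, 0.0, SEG) == pytest.approx(1.0)
        t = np.arange(0.0, 2000.0, 0.1)
        assert emd_drive(t, 0.0, SEG).max() == pytest.approx(1.0, abs=1e-4)

    def test_time_shift_equivariance(self):
        t = np.arange(0.0, 1500.0, 0.5)
        u0 = emd_drive(t, 100.0, SEG)
        u1 = emd_drive(t + 80.0, 180.0, SEG)
        assert np.allclose(u0, u1)


class TestTension:
    def test_active_tension_zero_drive_and_scar(self):
        assert active_tension(0.0, SEG.l0, SEG) == 0.0
        scar = SegmentParams(name="x", k_act=0.0)
        assert active_tension(1.0, scar.l0 * 1.1, scar) == 0.0

    def test_active_tension_linear_in_contractility(self):
        half = SegmentParams(name="x", k_act=0.5)
        full = SegmentParams(name="x", k_act=1.0)
        l = 0.95 * SEG.l0
        assert active_tension(0.7, l, half) == pytest.approx(
            0.5 * active_tension(0.7, l, full))

    def test_passive_tension_zero_at_reference(self):
        assert passive_tension(0.0, SEG) == 0.0

    def test_passive_tension_monotone_and_stiffening(self):
        eps = np.linspace(-0.3, 0.3, 61)
        tp = passive_tension(eps, SEG)
        assert np.all(np.diff(tp) > 0)
        d2 = np.diff(tp, 2)[eps[1:-1] > 0]
        assert np.all(d2 > 0)  # convex (stiffening) in stretch

    def test_passive_slope_continuous_at_zero(self):
        h = 1e-7
        left = (passive_tension(0.0, SEG) - passive_tension(-h, SEG)) / h
        right = (passive_tension(h, SEG) - passive_tension(0.0, SEG)) / h
        assert left == pytest.approx(SEG.k_p1 * SEG.k_p2, rel=1e-4)
        assert right == pytest.approx(SEG.k_p1 * SEG.k_p2, rel=1e-4)


class TestStrainAndFlow:
    @pytest.mark.parametrize("l, expected", [(3.0, 0.0), (2.4, -20.0), (3.3, 10.0)])
    def test_segment_strain_echo_convention(self, l, expected):
        assert segment_strain(l, 3.0) == pytest.approx(expected)

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValidationError):
            segment_strain(-1.0, 3.0)
        with pytest.raises(ValidationError):
            segment_strain(3.0, 0.0)

    def test_flow_equilibrium_and_resistive_limit(self):
        assert segment_flow_dynamics(0.0, 50.0, 50.0, SEG) == 0.0
        # dq/dt = 0  =>  q = (p_seg - p_load) / r_h
        q_ss = (80.0 - 50.0) / SEG.r_h
        assert segment_flow_dynamics(q_ss, 80.0, 50.0, SEG) == pytest.approx(0.0)

    def test_septal_load_routing_and_sign(self):
        loads = septal_load(p_lv=100.0, p_rv=30.0)
        for s in SEPTAL_WALL:
            assert loads[s] == 70.0
        for s in RV_SEGMENTS:
            assert loads[s] == 30.0
        assert loads["mid_anterior"] == 100.0
        # equal pressures -> zero trans-septal load
        assert septal_load(50.0, 50.0)["apical_septal"] == 0.0
        # raising p_rv monotonically decreases septal load
        l1 = septal_load(100.0, 10.0)["mid_inferoseptal"]
        l2 = septal_load(100.0, 40.0)["mid_inferoseptal"]
        assert l2 < l1


class TestCoupledBehaviour:
    def test_homogeneous_free_wall_strains_synchronous(self, baseline_result):
        """Equal parameters + equal load + simultaneous activation give
        pairwise-identical strain among the 11 uniformly loaded free-wall
        segments; septal segments carry a bounded trans-septal offset."""
        sl = baseline_result.final_cycle_slice()
        free = [s for s in LV_SEGMENTS if s not in SEPTAL_WALL]
        sf = baseline_result.strain[free].values[sl]
        assert (sf.max(axis=1) - sf.min(axis=1)).max() < 1.0
        s_all = baseline_result.strain[list(LV_SEGMENTS)].values[sl]
        assert (s_all.max(axis=1) - s_all.min(axis=1)).max() < 8.0

    def test_strain_returns_to_reference_between_cycles(self, baseline_result):
        refs = baseline_result.strain_ref_times[-3:]
        for seg in ("mid_anterior", "apical_septal", "rv_median"):
            col = baseline_result.strain[seg].to_numpy()
            vals = [col[int(round(t / baseline_result.dt))] for t in refs]
            assert max(vals) - min(vals) < 0.5

    def test_reducing_contractility_monotonically_reduces_peak_strain(self):
        peaks = []
        for k in (1.0, 0.6, 0.2):
            cfg = load_config({"mechanics": {"segments": {
                "mid_anterolateral": {"k_act": k}}}})
            res = run(cfg, n_cycles=6, dt=1.0)
            sl = res.final_cycle_slice()
            peaks.append(abs(res.strain["mid_anterolateral"].values[sl].min()))
        assert peaks[0] > peaks[1] > peaks[2]
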