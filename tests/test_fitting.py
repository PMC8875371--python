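"""Personalization: coordinate descent, recovery, concordance."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from cardioem.config import load_config
from cardioem.engine import run
from cardioem.errors import ValidationError
from cardioem.fitting import (
    FitParameter,
    FitSpec,
    calibrate_myocardial_delay,
    concordance,
    default_fitspec,
    fit_one_at_a_time,
    simulated_wall_curves,
)
from cardioem.segments import LATERAL_WALL, LV_SEGMENTS
from cardioem.strain import wall_average


def lateral_kact_spec(n_grid=6, n_refine=2, **kw) -> FitSpec:
    return FitSpec(parameters=[
        FitParameter("k_act", tuple(LATERAL_WALL), (0.05, 1.0),
                     n_grid=n_grid, n_refine=n_refine, label="k_act.lateral")],
        max_sweeps=2, tol=0.01, **kw)


@pytest.fixture(scope="module")
def lateral_truth_targets():
    """Forward-model targets with known lateral contractility 0.3."""
    truth = load_config({"mechanics": {"segments": {
        s: {"k_act": 0.3} for s in LATERAL_WALL}}})
    res = run(truth, n_cycles=8)
    return simulated_wall_curves(res)


class TestFitter:
    def test_noiseless_parameter_recovery(self, lateral_truth_targets):
        fr = fit_one_at_a_time(lateral_truth_targets, lateral_kact_spec())
        assert abs(fr.values["k_act.lateral"] - 0.3) <= 0.1
        assert fr.rmse_lateral < 0.5

    def test_recovery_with_one_percent_strain_noise(self, lateral_truth_targets):
        rng = np.random.default_rng(99)
        noisy = {}
        for wall, curve in lateral_truth_targets.items():
            noisy[wall] = type(curve)(wall, curve.time.copy(),
                                      curve.strain + rng.normal(0.0, 1.0,
                                                                curve.strain.size))
        fr = fit_one_at_a_time(noisy, lateral_kact_spec())
        assert abs(fr.values["k_act.lateral"] - 0.3) <= 0.15

    def test_baseline_target_is_a_fixed_point(self):
        res = run(load_config(None), n_cycles=8)
        targets = simulated_wall_curves(res)
        spec = lateral_kact_spec(n_grid=5, n_refine=1)
        fr = fit_one_at_a_time(targets, spec)
        assert fr.total_rmse < 0.2
        assert fr.values["k_act.lateral"] == pytest.approx(1.0, abs=0.05)

    def test_total_rmse_monotone_and_deterministic(self, lateral_truth_targets):
        fr1 = fit_one_at_a_time(lateral_truth_targets, lateral_kact_spec())
        fr2 = fit_one_at_a_time(lateral_truth_targets, lateral_kact_spec())
        conv = np.array(fr1.convergence)
        assert np.all(np.diff(conv) <= 1e-12)
        assert fr1.values == fr2.values
        assert fr1.rmse_septal == fr2.rmse_septal

    def test_empty_or_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            FitSpec(parameters=[]).validate()
        with pytest.raises(ValidationError):
            FitParameter("volume", ("mid_anterior",), (0, 1)).validate()
        with pytest.raises(ValidationError):
            FitParameter("k_act", ("mid_anterior",), (1.0, 0.0)).validate()

    def test_targets_must_cover_both_walls(self, lateral_truth_targets):
        with pytest.raises(ValidationError, match="lateral"):
            fit_one_at_a_time({"septal": lateral_truth_targets["septal"]},
                              lateral_kact_spec())


class TestQrsCalibration:
    def test_calibrated_delay_reproduces_target_qrs(self):
        myo = calibrate_myocardial_delay(150.0, 900.0)
        from cardioem.conduction import (build_network, measure_qrs,
                                         simulate_conduction, synthesize_ecg)
        net = build_network({"rr": 900.0, "lbbb": True, "myocardial_delay": myo})
        events = simulate_conduction(net, 20.0 + 2700.0)
        arp = {s: net.specs[s].t_udp + net.specs[s].t_arp for s in LV_SEGMENTS}
        qrs = measure_qrs(synthesize_ecg(events, arp_end_by_node=arp))
        assert qrs == pytest.approx(150.0, abs=6.0)


class TestConcordance:
    def test_perfect_anticorrelation_gives_rho_and_overlap_one(self):
        c = pd.Series(np.linspace(10, 90, 16), index=list(LV_SEGMENTS))
        t = 100.0 - c
        res = concordance(c, t, low_threshold=50.0, high_threshold=50.0)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.overlap_fraction == 1.0

    def test_independent_random_maps_average_near_zero(self):
        rhos = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c = pd.Series(rng.uniform(10, 100, 16), index=list(LV_SEGMENTS))
            t = pd.Series(rng.uniform(0, 90, 16), index=list(LV_SEGMENTS))
            rhos.append(concordance(c, t).spearman_rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_constant_map_reports_undefined_correlation(self):
        c = pd.Series(np.full(16, 80.0), index=list(LV_SEGMENTS))
        t = pd.Series(np.linspace(0, 90, 16), index=list(LV_SEGMENTS))
        res = concordance(c, t, high_threshold=45.0)
        assert math.isnan(res.spearman_rho)
        assert 0.0 <= res.overlap_fraction <= 1.0  # still computed

    def test_scarred_segments_are_exactly_the_overlap_set(self, model_fixtures):
        """End-to-end: LGE phantom + wall-group fit of the matching strain
        fixture; the intersection of low-contractility and high-
        transmurality sets is exactly the scarred territory."""
        from cardioem.lge import scar_analysis
        from cardioem.synthetic import fitting_base_config, make_lge_phantom

        scarred = LATERAL_WALL[:4]
        vol = make_lge_phantom(scarred, 60.0, seed=5)
        tmap, _ = scar_analysis(vol)

        ds = model_fixtures["lbbb_lateral_scar"]
        targets = {w: wall_average(ds.strain, w) for w in ("septal", "lateral")}
        spec = default_fitspec(("t_delay", "k_act"), n_grid=5, n_refine=1,
                               max_sweeps=2)
        fr = fit_one_at_a_time(targets, spec,
                               base_config=fitting_base_config(ds))
        res = concordance(fr.contractility, tmap,
                          low_threshold=50.0, high_threshold=50.0)
        assert set(res.overlap_set) == set(scarred)
        assert res.spearman_rho > 0.5
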