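"""Cellular-automata conduction: phases, propagation, ECG synthesis."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cardioem.conduction import (
    AutomatonSpec,
    ConductionNetwork,
    ConductionSimulator,
    ECGTrace,
    activation_times,
    build_network,
    cycle_starts,
    measure_qrs,
    simulate_conduction,
    synthesize_ecg,
)
from cardioem.errors import SimulationError, ValidationError
from cardioem.segments import LATERAL_WALL, LV_SEGMENTS, SEPTAL_WALL


def toy_network(**kwargs) -> ConductionNetwork:
    """Pacemaker A -> B -> C chain with 10/20 ms link delays."""
    specs = {
        "A": AutomatonSpec("A", t_sdd=100.0, t_udp=5.0, t_arp=80.0, t_rrp=40.0,
                           neighbors=(("B", 10.0),), is_pacemaker=True),
        "B": AutomatonSpec("B", 0.0, 5.0, 80.0, 40.0, (("C", 20.0),)),
        "C": AutomatonSpec("C", 0.0, 5.0, 80.0, 40.0),
    }
    return ConductionNetwork(specs, **kwargs)


class TestAutomata:
    def test_isolated_pacemaker_fires_with_its_intrinsic_period(self):
        spec = AutomatonSpec("A", 200.0, 10.0, 100.0, 50.0, is_pacemaker=True)
        net = ConductionNetwork({"A": spec})
        events = simulate_conduction(net, 2000.0, first_beat_at=20.0)
        times = [e.time for e in events]
        period = 200.0 + 10.0 + 100.0 + 50.0
        assert np.allclose(np.diff(times), period)

    def test_chain_propagation_delays_are_exact(self):
        events = simulate_conduction(toy_network(), 120.0, first_beat_at=0.0)
        onset = {e.node: e.time for e in events}
        # child onset - parent onset = parent UDP + link delay, exactly
        assert onset["B"] - onset["A"] == 5.0 + 10.0
        assert onset["C"] - onset["B"] == 5.0 + 20.0

    def test_stimulus_during_arp_is_ignored(self):
        net = toy_network()
        sim = ConductionSimulator(net, first_beat_at=0.0)
        sim._activate("B", 0.0)  # B enters UDP at t=0, ARP at t=5
        sim._push(30.0, sim._STIM_EVT, "A", ("stim", "B", "A"))
        sim.advance(60.0)
        b_events = [e for e in sim.activations if e.node == "B"]
        assert len(b_events) == 1  # the ARP stimulus produced nothing

    def test_simultaneous_stimuli_yield_single_activation(self):
        specs = {
            "P1": AutomatonSpec("P1", 50.0, 5.0, 80.0, 40.0, (("T", 10.0),),
                                is_pacemaker=True),
            "P2": AutomatonSpec("P2", 50.0, 5.0, 80.0, 40.0, (("T", 10.0),),
                                is_pacemaker=True),
            "T": AutomatonSpec("T", 0.0, 5.0, 80.0, 40.0),
        }
        net = ConductionNetwork(specs)
        events = simulate_conduction(net, 100.0, first_beat_at=0.0)
        t_events = [e for e in events if e.node == "T"]
        assert len(t_events) == 1
        assert t_events[0].time == 15.0  # first processed wins at 0 + 5 + 10

    def test_no_reactivation_within_udp_plus_arp_under_random_stimuli(self):
        """Refractory protection for arbitrary stimulus injection patterns."""
        net = toy_network()
        sim = ConductionSimulator(net, first_beat_at=0.0)
        rng = np.random.default_rng(42)
        for t in sorted(rng.uniform(0.0, 800.0, size=200)):
            target = rng.choice(["A", "B", "C"])
            sim._push(float(t), sim._STIM_EVT, "A", ("stim", str(target), "A"))
        sim.advance(1000.0)
        refractory = 5.0 + 80.0  # t_udp + t_arp, equal for all toy nodes
        for node in "ABC":
            onsets = [e.time for e in sim.activations if e.node == node]
            assert all(b - a >= refractory - 1e-9
                       for a, b in zip(onsets, onsets[1:]))

    def test_advance_backwards_rejected(self):
        sim = ConductionSimulator(toy_network())
        sim.advance(50.0)
        with pytest.raises(ValidationError):
            sim.advance(10.0)

    def test_event_cap_stops_runaway(self):
        # tight loop A<->B with zero refractoriness re-excites forever
        specs = {
            "A": AutomatonSpec("A", 10.0, 1.0, 0.0, 0.0, (("B", 1.0),),
                               is_pacemaker=True),
            "B": AutomatonSpec("B", 0.0, 1.0, 0.0, 0.0, (("A", 1.0),)),
        }
        net = ConductionNetwork(specs)
        sim = ConductionSimulator(net, event_cap=500)
        with pytest.raises(SimulationError, match="event cap"):
            sim.advance(1e6)


class TestHeartNetwork:
    def test_default_network_has_26_automata_16_lv_segments(self):
        net = build_network({})
        assert len(net.specs) == 26
        assert sum(1 for s in net.specs if s in LV_SEGMENTS) == 16

    def test_unknown_node_and_negative_duration_rejected(self):
        with pytest.raises(ValidationError, match="unknown node"):
            build_network({"link_delays": {"NSA->XX": 5.0}})
        with pytest.raises(ValidationError, match="t_arp"):
            build_network({"phases": {"RA": [0, 2, -5, 50]}})

    def test_rr_shorter_than_refractory_cycle_rejected(self):
        with pytest.raises(ValidationError, match="rr"):
            build_network({"rr": 300.0})

    def test_period_entrainment_matches_rr_exactly(self):
        net = build_network({"rr": 860.0})
        events = simulate_conduction(net, 20.0 + 5 * 860.0 - 1e-9)
        nsa = cycle_starts(events)
        assert np.allclose(np.diff(nsa), 860.0)

    @pytest.mark.parametrize("lbbb", [False, True])
    def test_activation_times_match_dijkstra_shortest_delay(self, lbbb):
        """First-cycle onsets equal shortest-delay paths from the pacemaker."""
        net = build_network({"lbbb": lbbb})
        events = simulate_conduction(net, 20.0 + 999.0)
        amap = activation_times(events, 0)
        dist = net.shortest_delay_from("NSA")
        for node, onset in amap.items():
            assert onset == pytest.approx(dist[node], abs=1e-9)

    def test_lbbb_septal_segments_activate_before_lateral(self):
        net = build_network({"lbbb": True})
        events = simulate_conduction(net, 1000.0)
        amap = activation_times(events, 0)
        sep = np.mean([amap[s] for s in SEPTAL_WALL])
        lat = np.mean([amap[s] for s in LATERAL_WALL])
        assert sep < lat
        assert all(amap[s] < amap[l] for s in SEPTAL_WALL for l in LATERAL_WALL
                   if "apical" not in s and "apical" not in l)

    def test_baseline_lv_activation_is_tight(self):
        net = build_network({})
        amap = activation_times(simulate_conduction(net, 1000.0), 0)
        lv = [amap[s] for s in LV_SEGMENTS]
        assert max(lv) - min(lv) <= 10.0

    def test_cycle_index_out_of_range(self):
        events = simulate_conduction(build_network({}), 1000.0)
        with pytest.raises(ValidationError, match="cycle_index"):
            activation_times(events, 5)


class TestECG:
    def test_no_events_gives_flat_zero_trace(self):
        ecg = synthesize_ecg([], sample_period=1.0, duration=500.0)
        assert np.all(ecg.voltage == 0.0)

    def test_one_qrs_complex_per_sinus_beat(self):
        net = build_network({})
        n_beats = 4
        events = simulate_conduction(net, 20.0 + n_beats * 1000.0 - 1e-9)
        ecg = synthesize_ecg(events)
        x = np.abs(ecg.voltage)
        above = x >= 0.5 * x.max()
        n_complexes = int(np.sum(np.diff(above.astype(int)) == 1) + above[0])
        assert n_complexes == n_beats == len(cycle_starts(events))

    def test_lbbb_broadens_qrs_on_identical_templates(self):
        def qrs(lbbb):
            net = build_network({"lbbb": lbbb})
            events = simulate_conduction(net, 20.0 + 3000.0)
            return measure_qrs(synthesize_ecg(events))
        assert qrs(True) > qrs(False) + 20.0

    def test_measure_qrs_on_rectangular_pulse(self):
        t = np.arange(0.0, 600.0, 1.0)
        v = np.where((t >= 200.0) & (t < 300.0), 1.0, 0.0)
        width = measure_qrs(ECGTrace(time=t, voltage=v, sample_period=1.0))
        assert width == pytest.approx(100.0, abs=1.0)

    def test_flat_trace_raises_detection_error(self):
        trace = ECGTrace(time=np.arange(100.0), voltage=np.zeros(100),
                         sample_period=1.0)
        with pytest.raises(SimulationError, match="no ventricular complex"):
            measure_qrs(trace)

    def test_qrs_width_matches_analytic_crossing_oracle(self):
        """Measured width agrees with the supra-threshold extent of the
        analytic sum of ventricular template waves (continuous-time oracle,
        independent of the sampled-trace run segmentation), within 5 ms;
        and the width tracks the configured LV dispersion."""
        from cardioem.conduction import ECGTemplates
        from cardioem.segments import ALL_SEGMENTS

        net = build_network({"lbbb": True, "myocardial_delay": 31.0})
        events = simulate_conduction(net, 20.0 + 3 * 900.0 - 1e-9)
        ecg = synthesize_ecg(events)
        measured = measure_qrs(ecg)

        amap = activation_times(events, 1)
        onsets = np.array([amap[s] for s in ALL_SEGMENTS])
        tpl = ECGTemplates().ventricular
        # analytic superposed complex on a 0.01 ms grid around one beat
        tt = np.arange(onsets.min() - 150.0, onsets.max() + 150.0, 0.01)
        f = sum(tpl.amp * np.exp(-0.5 * ((tt - t0) / tpl.sigma_l) ** 2)
                for t0 in onsets)
        thr = 0.05 * np.abs(ecg.voltage).max()
        above = f >= thr
        oracle = (np.flatnonzero(above)[-1] - np.flatnonzero(above)[0]) * 0.01
        assert measured == pytest.approx(oracle, abs=5.0)
        dispersion = onsets.max() - onsets.min()
        assert dispersion < measured < dispersion + 2.0 * tpl.width

    def test_bad_sample_period_rejected(self):
        with pytest.raises(ValidationError):
            synthesize_ecg([], sample_period=0.0)
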