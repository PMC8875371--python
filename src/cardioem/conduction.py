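"""Cellular-automata model of the cardiac conduction system.

The electrical activity of the heart is represented by 26 interacting
automata: the sinoatrial node (NSA), right and left atria (RA, LA), the
atrioventricular node (NAV), the upper bundle of His (UH), the right and
left bundle branches (RBB, LBB), three right-ventricular layers and the 16
AHA left-ventricular segments. Each automaton cycles through four phases —
slow diastolic depolarization (SDD), upstroke depolarization (UDP),
absolute refractory (ARP) and relative refractory (RRP) — and stimulates
its neighbours, after a per-link conduction delay, when its UDP ends.

Left bundle branch block (LBBB) is modelled by disabling (or delaying) the
LBB outgoing links, so that the left ventricle is activated through the
right ventricle and slow cell-to-cell myocardial spread across the septum.

The module also synthesizes a surface-ECG-like signal by summing parametric
waveform templates placed at each automaton's activation onset (and, for
ventricular automata, a repolarization wave at the end of the absolute
refractory period), and measures QRS width on such traces.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import SimulationError, ValidationError
from .segments import ALL_SEGMENTS, LV_SEGMENTS, lv_adjacency, rv_adjacency

# ---------------------------------------------------------------------------
# Automaton specification and network
# ---------------------------------------------------------------------------

CONDUCTION_NODES: tuple[str, ...] = ("NSA", "RA", "LA", "NAV", "UH", "RBB", "LBB")
ALL_NODES: tuple[str, ...] = CONDUCTION_NODES + ALL_SEGMENTS


class Phase(Enum):
    SDD = "SDD"
    UDP = "UDP"
    ARP = "ARP"
    RRP = "RRP"


@dataclass(frozen=True)
class AutomatonSpec:
    """Phase durations (ms) and outgoing links of one automaton."""

    id: str
    t_sdd: float
    t_udp: float
    t_arp: float
    t_rrp: float
    neighbors: tuple[tuple[str, float], ...] = ()  # (target id, link delay ms)
    is_pacemaker: bool = False

    def validate(self) -> None:
        for attr in ("t_sdd", "t_udp", "t_arp", "t_rrp"):
            v = getattr(self, attr)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"node {self.id}: {attr} = {v} must be >= 0")
        for tgt, delay in self.neighbors:
            if not math.isfinite(delay) or delay < 0:
                raise ValidationError(
                    f"node {self.id}: link delay to {tgt} = {delay} must be >= 0"
                )


@dataclass
class ConductionNetwork:
    """A validated set of automata with directed, delayed links."""

    specs: dict[str, AutomatonSpec]
    rrp_excitable: bool = True
    rrp_udp_scaling: bool = True

    def __post_init__(self) -> None:
        order = list(self.specs)
        for name, spec in self.specs.items():
            if spec.id != name:
                raise ValidationError(f"spec id {spec.id!r} filed under key {name!r}")
            spec.validate()
            for tgt, _ in spec.neighbors:
                if tgt not in self.specs:
                    raise ValidationError(f"node {name}: unknown link target {tgt!r}")
        if not any(s.is_pacemaker for s in self.specs.values()):
            raise ValidationError("network has no pacemaker node")
        self._order = {name: i for i, name in enumerate(order)}

    def node_order(self, name: str) -> int:
        return self._order[name]

    @property
    def pacemakers(self) -> list[str]:
        return [s.id for s in self.specs.values() if s.is_pacemaker]

    def reachable_from(self, source: str) -> set[str]:
        seen = {source}
        stack = [source]
        while stack:
            n = stack.pop()
            for tgt, _ in self.specs[n].neighbors:
                if tgt not in seen:
                    seen.add(tgt)
                    stack.append(tgt)
        return seen

    def shortest_delay_from(self, source: str) -> dict[str, float]:
        """Dijkstra shortest delay over (t_udp + link delay) edge weights.

        On acyclic stimulus regimes this is the oracle for activation times:
        a stimulus leaves a node when its UDP ends, so the effective edge
        weight from u to v is ``t_udp(u) + delay(u, v)``.
        """
        dist = {source: 0.0}
        pq = [(0.0, source)]
        while pq:
            d, u = heapq.heappop(pq)
            if d > dist.get(u, math.inf):
                continue
            w_u = self.specs[u].t_udp
            for v, delay in self.specs[u].neighbors:
                nd = d + w_u + delay
                if nd < dist.get(v, math.inf):
                    dist[v] = nd
                    heapq.heappush(pq, (nd, v))
        return dist


# --- default heart network --------------------------------------------------

#: Default phase durations (ms) by node. The printed sources for this model
#: give no timing table; these values are calibrated so that the synthesized
#: PR interval (~165 ms), baseline QRS (~85 ms) and refractory periods fall
#: in physiological ranges, and are exposed through the configuration file.
DEFAULT_PHASES: dict[str, tuple[float, float, float, float]] = {
    # (t_sdd, t_udp, t_arp, t_rrp) — NSA t_sdd is overwritten from RR.
    "NSA": (648.0, 2.0, 250.0, 100.0),
    "RA": (0.0, 2.0, 200.0, 50.0),
    "LA": (0.0, 2.0, 200.0, 50.0),
    "NAV": (0.0, 2.0, 250.0, 80.0),
    "UH": (0.0, 2.0, 250.0, 80.0),
    "RBB": (0.0, 2.0, 250.0, 80.0),
    "LBB": (0.0, 2.0, 250.0, 80.0),
}
_SEGMENT_PHASES = (0.0, 2.0, 250.0, 100.0)

#: Conduction-axis link delays (ms).
DEFAULT_LINK_DELAYS: dict[tuple[str, str], float] = {
    ("NSA", "RA"): 10.0,
    ("RA", "LA"): 30.0,
    ("RA", "NAV"): 50.0,
    ("NAV", "UH"): 90.0,
    ("UH", "RBB"): 15.0,
    ("UH", "LBB"): 15.0,
}
_RBB_TARGETS = ("rv_basal", "rv_median", "rv_apical")
_RBB_DELAY = 10.0

#: Intact-LBB endocardial insertion delays (ms) by ring: the left bundle's
#: fascicles and peripheral Purkinje network reach the whole LV endocardium
#: nearly simultaneously, so the healthy LV activates synchronously.
#: Under LBBB every one of these links is removed and the LV is reached only
#: through the right ventricle and slow trans-septal myocardial spread.
_LBB_RING_DELAYS = {"apical": 10.0, "mid": 10.0, "basal": 10.0}

DEFAULT_MYOCARDIAL_DELAY = 15.0  # ms per inter-segment (cell-to-cell) link
DEFAULT_TRANSSEPTAL_DELAY = 25.0  # ms per RV-to-septum link


def build_network(config: Mapping | None = None) -> ConductionNetwork:
    """Build the 26-automaton heart network.

    ``config`` keys (all optional, defaults in this module):

    - ``rr``: cycle length in ms; the pacemaker SDD is set to
      ``rr − (t_udp + t_arp + t_rrp)`` so heart rate is a single input.
    - ``lbbb``: if true, LBB outgoing links are removed (complete block).
    - ``lbb_extra_delay``: if set (ms), LBB links are delayed by this amount
      instead of removed (incomplete block), taking precedence over ``lbbb``.
    - ``myocardial_delay``: ms per inter-segment myocardial link.
    - ``transseptal_delay``: ms per RV-layer-to-septal-segment link.
    - ``phases``: mapping node -> [t_sdd, t_udp, t_arp, t_rrp] overrides.
    - ``link_delays``: mapping "SRC->DST" -> ms overrides.
    - ``rrp_excitable`` / ``rrp_udp_scaling``: relative-refractory behaviour.
    """
    cfg = dict(config or {})
    rr = float(cfg.get("rr", 1000.0))
    lbbb = bool(cfg.get("lbbb", False))
    lbb_extra = cfg.get("lbb_extra_delay")
    myo = float(cfg.get("myocardial_delay", DEFAULT_MYOCARDIAL_DELAY))
    trans = float(cfg.get("transseptal_delay", DEFAULT_TRANSSEPTAL_DELAY))

    phases: dict[str, tuple[float, float, float, float]] = {}
    for node in ALL_NODES:
        base = DEFAULT_PHASES.get(node, _SEGMENT_PHASES)
        override = (cfg.get("phases") or {}).get(node)
        phases[node] = tuple(float(x) for x in override) if override else base

    sdd, udp, arp, rrp = phases["NSA"]
    t_sdd_nsa = rr - (udp + arp + rrp)
    if t_sdd_nsa <= 0:
        raise ValidationError(
            f"rr = {rr} ms shorter than NSA refractory cycle ({udp + arp + rrp} ms)"
        )
    phases["NSA"] = (t_sdd_nsa, udp, arp, rrp)

    links: dict[str, list[tuple[str, float]]] = {n: [] for n in ALL_NODES}
    delays = dict(DEFAULT_LINK_DELAYS)
    for key, val in (cfg.get("link_delays") or {}).items():
        src, _, dst = key.partition("->")
        delays[(src.strip(), dst.strip())] = float(val)
    for (src, dst), d in delays.items():
        if src not in links or dst not in ALL_NODES:
            raise ValidationError(f"link {src}->{dst}: unknown node id")
        links[src].append((dst, d))
    for tgt in _RBB_TARGETS:
        links["RBB"].append((tgt, _RBB_DELAY))
    lbb_delays = {**_LBB_RING_DELAYS, **(cfg.get("lbb_ring_delays") or {})}
    if lbb_extra is not None or not lbbb:
        extra = float(lbb_extra) if lbb_extra is not None else 0.0
        for tgt in LV_SEGMENTS:
            ring = tgt.split("_", 1)[0]
            links["LBB"].append((tgt, lbb_delays[ring] + extra))
    for a, b in lv_adjacency():
        links[a].append((b, myo))
        links[b].append((a, myo))
    for a, b in rv_adjacency():
        d = trans if (a.startswith("rv") != b.startswith("rv")) else myo
        links[a].append((b, d))
        links[b].append((a, d))

    specs = {}
    for node in ALL_NODES:
        sdd, udp, arp, rrp = phases[node]
        specs[node] = AutomatonSpec(
            id=node,
            t_sdd=sdd,
            t_udp=udp,
            t_arp=arp,
            t_rrp=rrp,
            neighbors=tuple(links[node]),
            is_pacemaker=(node == "NSA"),
        )

    net = ConductionNetwork(
        specs,
        rrp_excitable=bool(cfg.get("rrp_excitable", True)),
        rrp_udp_scaling=bool(cfg.get("rrp_udp_scaling", True)),
    )
    if len(net.specs) != 26:
        raise ValidationError(f"heart network must have 26 automata, got {len(net.specs)}")
    reach = net.reachable_from("NSA")
    missing = [s for s in ALL_SEGMENTS if s not in reach]
    if missing:
        raise ValidationError(f"segments unreachable from NSA: {', '.join(missing)}")
    return net


# ---------------------------------------------------------------------------
# Discrete-event simulation
# ---------------------------------------------------------------------------


class ActivationEvent(NamedTuple):
    time: float
    node: str


@dataclass
class AutomatonState:
    phase: Phase
    phase_entry_time: float


class ConductionSimulator:
    """Deterministic discrete-event simulator over a ConductionNetwork.

    Events in the queue are ordered by (time, kind, source order, sequence):
    phase transitions are processed before stimuli at equal times, and
    simultaneous stimuli are broken by the order of the source node in the
    network specification, so simulations are exactly reproducible.
    """

    _PHASE_EVT = 0
    _STIM_EVT = 1

    def __init__(
        self,
        network: ConductionNetwork,
        first_beat_at: float = 20.0,
        event_cap: int = 1_000_000,
    ) -> None:
        self.network = network
        self.time = 0.0
        self.event_cap = int(event_cap)
        self._events_processed = 0
        self._seq = 0
        self._queue: list = []
        self.states: dict[str, AutomatonState] = {
            n: AutomatonState(Phase.SDD, 0.0) for n in network.specs
        }
        self.activations: list[ActivationEvent] = []
        for pm in network.pacemakers:
            self._push(first_beat_at, self._PHASE_EVT, pm, ("fire", pm))

    def _push(self, time: float, kind: int, source: str, payload) -> None:
        self._seq += 1
        heapq.heappush(
            self._queue, (time, kind, self.network.node_order(source), self._seq, payload)
        )

    # -- phase machinery ----------------------------------------------------

    def _activate(self, node: str, t: float, udp_override: float | None = None) -> None:
        """Enter UDP (activation onset); schedule stimulus emission at UDP end."""
        spec = self.network.specs[node]
        udp = spec.t_udp if udp_override is None else udp_override
        self.states[node] = AutomatonState(Phase.UDP, t)
        self.activations.append(ActivationEvent(t, node))
        self._push(t + udp, self._PHASE_EVT, node, ("udp_end", node, udp))

    def _handle(self, t: float, payload) -> None:
        kind = payload[0]
        if kind == "fire":  # pacemaker SDD elapsed
            node = payload[1]
            if self.states[node].phase is Phase.SDD:
                self._activate(node, t)
        elif kind == "udp_end":
            _, node, udp = payload
            spec = self.network.specs[node]
            st = self.states[node]
            if st.phase is Phase.UDP:
                for tgt, delay in spec.neighbors:
                    self._push(t + delay, self._STIM_EVT, node, ("stim", tgt, node))
                self.states[node] = AutomatonState(Phase.ARP, t)
                self._push(t + spec.t_arp, self._PHASE_EVT, node, ("arp_end", node))
        elif kind == "arp_end":
            node = payload[1]
            if self.states[node].phase is Phase.ARP:
                spec = self.network.specs[node]
                self.states[node] = AutomatonState(Phase.RRP, t)
                self._push(t + spec.t_rrp, self._PHASE_EVT, node, ("rrp_end", node))
        elif kind == "rrp_end":
            node = payload[1]
            if self.states[node].phase is Phase.RRP:
                spec = self.network.specs[node]
                self.states[node] = AutomatonState(Phase.SDD, t)
                if spec.is_pacemaker:
                    self._push(t + spec.t_sdd, self._PHASE_EVT, node, ("fire", node))
        elif kind == "stim":
            _, node, _source = payload
            st = self.states[node]
            spec = self.network.specs[node]
            if st.phase is Phase.SDD:
                self._activate(node, t)
            elif st.phase is Phase.RRP and self.network.rrp_excitable:
                udp = spec.t_udp
                if self.network.rrp_udp_scaling and spec.t_rrp > 0:
                    frac = (t - st.phase_entry_time) / spec.t_rrp
                    udp = spec.t_udp * (2.0 - min(max(frac, 0.0), 1.0))
                self._activate(node, t, udp_override=udp)
            # UDP/ARP: stimulus ignored (refractory protection)

    def advance(self, until_time: float) -> list[ActivationEvent]:
        """Process all events up to and including ``until_time``."""
        if until_time <= self.time:
            raise ValidationError(
                f"until_time = {until_time} not beyond current time {self.time}"
            )
        n_before = len(self.activations)
        while self._queue and self._queue[0][0] <= until_time:
            t, _kind, _src, _seq, payload = heapq.heappop(self._queue)
            self._events_processed += 1
            if self._events_processed > self.event_cap:
                raise SimulationError(
                    f"event cap {self.event_cap} exceeded at t = {t:.1f} ms "
                    "(runaway re-entry?)"
                )
            self.time = t
            self._handle(t, payload)
        self.time = until_time
        return self.activations[n_before:]


def simulate_conduction(
    network: ConductionNetwork, duration: float, first_beat_at: float = 20.0
) -> list[ActivationEvent]:
    """Run the automata for ``duration`` ms and return all activation events."""
    sim = ConductionSimulator(network, first_beat_at=first_beat_at)
    sim.advance(duration)
    return sim.activations


# ---------------------------------------------------------------------------
# Activation maps
# ---------------------------------------------------------------------------


def cycle_starts(events: Iterable[ActivationEvent], pacemaker: str = "NSA") -> list[float]:
    return [e.time for e in events if e.node == pacemaker]


def activation_times(
    events: Sequence[ActivationEvent],
    cycle_index: int,
    pacemaker: str = "NSA",
) -> dict[str, float]:
    """Per-node activation onset, in ms relative to the cycle's pacemaker firing.

    A cycle spans from the ``cycle_index``-th pacemaker firing to the next
    (or to the end of the event list for the last cycle). Nodes that never
    activate within the cycle are absent from the map.
    """
    starts = cycle_starts(events, pacemaker)
    if not starts:
        # single-node / pacemaker-free regimes: one cycle, absolute times
        if cycle_index != 0:
            raise ValidationError(f"cycle_index {cycle_index} beyond simulated horizon")
        return {e.node: e.time for e in reversed(events)} | {}
    if cycle_index < 0 or cycle_index >= len(starts):
        raise ValidationError(
            f"cycle_index {cycle_index} beyond simulated horizon ({len(starts)} cycles)"
        )
    t0 = starts[cycle_index]
    t1 = starts[cycle_index + 1] if cycle_index + 1 < len(starts) else math.inf
    out: dict[str, float] = {}
    for e in events:
        if t0 <= e.time < t1 and e.node not in out:
            out[e.node] = e.time - t0
    return out


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveTemplate:
    """Asymmetric Gaussian wave: amplitude, left/right widths (ms), polarity."""

    amp: float
    sigma_l: float
    sigma_r: float

    def render(self, t: np.ndarray, center: float) -> np.ndarray:
        dt = t - center
        sig = np.where(dt < 0, self.sigma_l, self.sigma_r)
        return self.amp * np.exp(-0.5 * (dt / sig) ** 2)

    @property
    def width(self) -> float:
        """Width of the wave above 5% of its own peak amplitude."""
        k = math.sqrt(2.0 * math.log(20.0))
        return k * (self.sigma_l + self.sigma_r)


@dataclass(frozen=True)
class ECGTemplates:
    """Per-node-class waveform templates for ECG synthesis."""

    atrial: WaveTemplate = WaveTemplate(0.08, 18.0, 18.0)
    ventricular: WaveTemplate = WaveTemplate(0.09, 15.0, 15.0)
    t_wave: WaveTemplate = WaveTemplate(0.008, 35.0, 35.0)
    #: repolarization wave offset after activation onset when the network's
    #: ARP end is not supplied
    t_wave_delay: float = 252.0


@dataclass
class ECGTrace:
    """Uniformly sampled ECG-like signal (arbitrary mV calibration)."""

    time: np.ndarray  # ms
    voltage: np.ndarray  # mV
    sample_period: float  # ms

    def to_text(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.time, self.voltage]),
            fmt="%.3f",
            header="time_ms\tamplitude_mV",
            delimiter="\t",
            comments="",
        )


def _node_class(node: str) -> str:
    if node in ("RA", "LA"):
        return "atrial"
    if node in ALL_SEGMENTS:
        return "ventricular"
    return "silent"


def synthesize_ecg(
    events: Sequence[ActivationEvent],
    templates: ECGTemplates | None = None,
    sample_period: float = 1.0,
    duration: float | None = None,
    arp_end_by_node: Mapping[str, float] | None = None,
) -> ECGTrace:
    """Sum per-node waveform templates placed at activation onsets.

    Ventricular nodes additionally contribute a repolarization wave at the
    end of their absolute refractory period (``arp_end_by_node`` gives
    t_udp + t_arp per node; otherwise ``templates.t_wave_delay`` is used).
    """
    if sample_period <= 0:
        raise ValidationError(f"sample_period = {sample_period} must be > 0")
    tpl = templates or ECGTemplates()
    if duration is None:
        duration = (max((e.time for e in events), default=0.0)) + 500.0
    t = np.arange(0.0, duration + 0.5 * sample_period, sample_period)
    v = np.zeros_like(t)
    for ev in events:
        cls = _node_class(ev.node)
        if cls == "atrial":
            v += tpl.atrial.render(t, ev.time)
        elif cls == "ventricular":
            v += tpl.ventricular.render(t, ev.time)
            if arp_end_by_node and ev.node in arp_end_by_node:
                t_rep = ev.time + arp_end_by_node[ev.node]
            else:
                t_rep = ev.time + tpl.t_wave_delay
            v += tpl.t_wave.render(t, t_rep)
    return ECGTrace(time=t, voltage=v, sample_period=sample_period)


def measure_qrs(ecg: ECGTrace, threshold_frac: float = 0.05) -> float:
    """QRS width (ms): supra-threshold width of the ventricular deflections.

    The trace is segmented into contiguous runs where |v| exceeds
    ``threshold_frac`` of the global peak |v|; runs that contain a sample of
    at least half the global peak are taken as ventricular complexes (P and
    T waves are synthesized at much lower amplitude) and their widths are
    averaged.
    """
    x = np.abs(np.asarray(ecg.voltage, dtype=float))
    peak = float(x.max(initial=0.0))
    if peak <= 0.0 or not np.isfinite(peak):
        raise SimulationError("no ventricular complex detected: flat trace")
    above = x >= threshold_frac * peak
    # run boundaries
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(x))
    widths = []
    for s, e in zip(starts, ends):
        if x[s:e].max(initial=0.0) >= 0.5 * peak:
            widths.append((e - s) * ecg.sample_period)
    if not widths:
        raise SimulationError("no ventricular complex detected above half-peak")
    return float(np.mean(widths))
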