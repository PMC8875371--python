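"""Closed-loop integration of the full electromechanical model.

The electrical automata are strictly upstream of the continuous mechanics
(one-way coupling), so each run first executes the discrete-event conduction
simulation over the whole horizon, then tabulates every segment's
electromechanical drive u(t) and both atrial elastances on the RK4 half-step
grid, and finally integrates the 48 continuous states (LV/RV blood volumes,
19 fibre lengths, 19 segment flows, 8 vascular/atrial volumes) with a fixed
step. Fixed-step RK4 with events quantized to the grid keeps runs bitwise
reproducible across platforms; there is no randomness anywhere in the
forward path.

State layout: y = [V_lv, V_rv, l[19], q[19], V_ao, V_sys_art, V_sys_ven,
V_vc, V_pa, V_pu, V_ra, V_la]; ms/mmHg/mL units with flows in mL/s
(the integrator converts the step to seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conduction import (
    ActivationEvent,
    ECGTrace,
    activation_times,
    build_network,
    simulate_conduction,
    synthesize_ecg,
)
from .config import ModelConfig
from .errors import SimulationError, ValidationError
from .mechanics import twitch_peak_time
from .segments import ALL_SEGMENTS, SEPTAL_SEGMENTS

_CHAMBER_ORDER = ("ao", "sys_art", "sys_ven", "vc", "pa", "pu")


def _maybe_jit(func):
    try:
        from numba import njit
    except Exception:  # pragma: no cover - numba is an optional accelerator
        return func
    return njit(cache=False)(func)


def _rhs_py(y, u, e_ra, e_la, A, l0, kat, kp1, kp2, fs, lmax, rh, lh, ltype,
            k_lv, k_rv, vc0_lv, vc0_rv, e_ch, v0_ch, v0_ra, v0_la,
            r_link, r_valve):
    n_seg = A.shape[0]
    dy = np.empty(y.shape[0])

    vw_lv = vc0_lv
    vw_rv = vc0_rv
    for i in range(n_seg):
        dvol = A[i] * (y[2 + i] - l0[i])
        if ltype[i] == 2:
            vw_rv += dvol
        else:
            vw_lv += dvol
    p_lv = k_lv * (y[0] - vw_lv)
    p_rv = k_rv * (y[1] - vw_rv)

    p_ao = e_ch[0] * (y[40] - v0_ch[0])
    p_sa = e_ch[1] * (y[41] - v0_ch[1])
    p_sv = e_ch[2] * (y[42] - v0_ch[2])
    p_vc = e_ch[3] * (y[43] - v0_ch[3])
    p_pa = e_ch[4] * (y[44] - v0_ch[4])
    p_pu = e_ch[5] * (y[45] - v0_ch[5])
    p_ra = e_ra * (y[46] - v0_ra)
    p_la = e_la * (y[47] - v0_la)

    q_mv = (p_la - p_lv) / r_valve[0] if p_la > p_lv else 0.0
    q_av = (p_lv - p_ao) / r_valve[1] if p_lv > p_ao else 0.0
    q_tv = (p_ra - p_rv) / r_valve[2] if p_ra > p_rv else 0.0
    q_pv = (p_rv - p_pa) / r_valve[3] if p_rv > p_pa else 0.0

    q0 = (p_ao - p_sa) / r_link[0]
    q1 = (p_sa - p_sv) / r_link[1]
    q2 = (p_sv - p_vc) / r_link[2]
    q3 = (p_vc - p_ra) / r_link[3]
    q4 = (p_pa - p_pu) / r_link[4]
    q5 = (p_pu - p_la) / r_link[5]

    for i in range(n_seg):
        li = y[2 + i]
        qi = y[21 + i]
        ratio = li / l0[i]
        eps = ratio - 1.0
        lam = 1.0 + fs[i] * (ratio - 1.0)
        if lam < 0.0:
            lam = 0.0
        elif lam > lmax[i]:
            lam = lmax[i]
        t_act = kat[i] * u[i] * lam
        if eps >= 0.0:
            t_pas = kp1[i] * math.expm1(kp2[i] * eps)
        else:
            t_pas = kp1[i] * kp2[i] * eps
        p_seg = (t_act + t_pas) / A[i]
        if ltype[i] == 0:
            load = p_lv
        elif ltype[i] == 1:
            load = p_lv - p_rv
        else:
            load = p_rv
        dy[21 + i] = (p_seg - load - rh[i] * qi) / lh[i]
        dy[2 + i] = -qi / A[i]

    dy[0] = q_mv - q_av
    dy[1] = q_tv - q_pv
    dy[40] = q_av - q0
    dy[41] = q0 - q1
    dy[42] = q1 - q2
    dy[43] = q2 - q3
    dy[44] = q_pv - q4
    dy[45] = q4 - q5
    dy[46] = q3 - q_tv
    dy[47] = q5 - q_mv
    return dy


def _integrate_py(y0, n_steps, dt_ms, u, era, ela, A, l0, kat, kp1, kp2, fs,
                  lmax, rh, lh, ltype, k_lv, k_rv, vc0_lv, vc0_rv, e_ch,
                  v0_ch, v0_ra, v0_la, r_link, r_valve):
    h = dt_ms * 1e-3  # seconds
    Y = np.empty((n_steps + 1, y0.shape[0]))
    Y[0] = y0
    y = y0.copy()
    for i in range(n_steps):
        j = 2 * i
        k1 = _rhs(y, u[:, j], era[j], ela[j], A, l0, kat, kp1, kp2, fs, lmax,
                  rh, lh, ltype, k_lv, k_rv, vc0_lv, vc0_rv, e_ch, v0_ch,
                  v0_ra, v0_la, r_link, r_valve)
        k2 = _rhs(y + 0.5 * h * k1, u[:, j + 1], era[j + 1], ela[j + 1], A,
                  l0, kat, kp1, kp2, fs, lmax, rh, lh, ltype, k_lv, k_rv,
                  vc0_lv, vc0_rv, e_ch, v0_ch, v0_ra, v0_la, r_link, r_valve)
        k3 = _rhs(y + 0.5 * h * k2, u[:, j + 1], era[j + 1], ela[j + 1], A,
                  l0, kat, kp1, kp2, fs, lmax, rh, lh, ltype, k_lv, k_rv,
                  vc0_lv, vc0_rv, e_ch, v0_ch, v0_ra, v0_la, r_link, r_valve)
        k4 = _rhs(y + h * k3, u[:, j + 2], era[j + 2], ela[j + 2], A, l0,
                  kat, kp1, kp2, fs, lmax, rh, lh, ltype, k_lv, k_rv,
                  vc0_lv, vc0_rv, e_ch, v0_ch, v0_ra, v0_la, r_link, r_valve)
        y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        Y[i + 1] = y
    return Y


_rhs = _maybe_jit(_rhs_py)
_integrate = _maybe_jit(_integrate_py)


# ---------------------------------------------------------------------------
# Drive tabulation
# ---------------------------------------------------------------------------


def _twitch_table(t_grid, onsets, t_delay, tau_c, tau_r):
    """Sum of normalized twitches from the given activation onsets."""
    u = np.zeros_like(t_grid)
    xp = twitch_peak_time(tau_c, tau_r)
    norm = (1.0 - math.exp(-xp / tau_c)) * math.exp(-xp / tau_r)
    dt_grid = t_grid[1] - t_grid[0] if len(t_grid) > 1 else 1.0
    span = t_delay + tau_c + 8.0 * tau_r
    for t_on in onsets:
        i0 = max(0, int((t_on + t_delay) / dt_grid))
        i1 = min(len(t_grid), int((t_on + span) / dt_grid) + 2)
        if i0 >= i1:
            continue
        x = t_grid[i0:i1] - t_on - t_delay
        w = (1.0 - np.exp(-x / tau_c)) * np.exp(-x / tau_r) / norm
        u[i0:i1] += np.where(x > 0.0, w, 0.0)
    return u


def _atrial_elastance_table(t_grid, onsets, params):
    g = np.zeros_like(t_grid)
    for t_on in onsets:
        g += np.exp(-0.5 * ((t_grid - t_on - params.mu) / params.sigma) ** 2)
    g = np.clip(g, 0.0, 1.0)
    return params.e_min + g * (params.e_max - params.e_min)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Synchronized time series of the full model over all simulated cycles."""

    time: np.ndarray                      # ms, uniform grid
    pressures: dict[str, np.ndarray]      # mmHg: lv, rv, ao, ..., ra, la
    volumes: dict[str, np.ndarray]        # mL
    flows: dict[str, np.ndarray]          # mL/s: mitral, aortic, tricuspid,
                                          # pulmonary, wall_lv_total
    strain: pd.DataFrame                  # time_ms + one % column per segment
    segment_lengths: pd.DataFrame         # cm
    segment_flows: pd.DataFrame           # mL/s
    ecg: ECGTrace
    activation: list[dict[str, float]]    # per-cycle activation maps, ms
    events: list[ActivationEvent]
    cycle_start_times: np.ndarray         # ms, one per cycle (pacemaker firing)
    strain_ref_times: np.ndarray          # ms, first ventricular activation per cycle
    rr: float
    n_transient: int
    dt: float

    def total_blood_volume(self) -> np.ndarray:
        keys = ("lv", "rv", "ra", "la") + _CHAMBER_ORDER
        return sum(self.volumes[k] for k in keys)

    def final_cycle_slice(self) -> slice:
        t0 = self.cycle_start_times[-1]
        i0 = int(np.searchsorted(self.time, t0))
        i1 = int(np.searchsorted(self.time, t0 + self.rr))
        return slice(i0, min(i1, len(self.time)))


@dataclass
class HemodynamicSummary:
    """Extrema over the final post-transient cycle."""

    peak_lv_pressure: float   # mmHg
    ao_pressure_max: float
    ao_pressure_min: float
    edv: float                # mL
    esv: float
    stroke_volume: float
    ejection_fraction: float  # %

    def validate(self) -> "HemodynamicSummary":
        if not self.edv > self.esv:
            raise SimulationError(
                f"degenerate cycle: EDV {self.edv:.2f} <= ESV {self.esv:.2f}"
            )
        if not (0.0 < self.ejection_fraction < 100.0):
            raise SimulationError(f"EF {self.ejection_fraction:.2f}% out of range")
        return self


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------


def run(config: ModelConfig | None = None, n_cycles: int | None = None,
        dt: float | None = None) -> SimulationResult:
    """Simulate the full closed-loop model.

    The forward path is fully deterministic: identical configs produce
    bitwise-identical results.
    """
    cfg = (config or ModelConfig()).validate()
    eng = cfg.engine
    n_cycles = int(n_cycles if n_cycles is not None else eng.n_cycles)
    dt = float(dt if dt is not None else eng.dt)
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    if not (0 < dt <= 1.0):
        raise ValidationError(f"dt = {dt} must be in (0, 1] ms")
    rr = cfg.rr
    t_first = eng.first_beat_at

    # --- electrical schedule ----------------------------------------------
    network = build_network(cfg.conduction)
    t_end = t_first + n_cycles * rr
    events = simulate_conduction(network, t_end - 1e-9, first_beat_at=t_first)

    onsets: dict[str, list[float]] = {n: [] for n in network.specs}
    for ev in events:
        onsets[ev.node].append(ev.time)

    never = [s for s in ALL_SEGMENTS if not onsets[s]]
    if never:
        raise SimulationError(f"segments never activated: {', '.join(never)}")

    # --- drive tables on the half-step grid -------------------------------
    n_steps = int(round(t_end / dt))
    t_grid = np.arange(n_steps + 1) * dt
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)

    seg_params = [cfg.segments[s] for s in ALL_SEGMENTS]
    u = np.empty((len(ALL_SEGMENTS), len(t_half)))
    for i, p in enumerate(seg_params):
        u[i] = _twitch_table(t_half, onsets[p.name], p.t_delay, p.tau_c, p.tau_r)

    era = _atrial_elastance_table(t_half, onsets["RA"], cfg.atria["RA"])
    ela = _atrial_elastance_table(t_half, onsets["LA"], cfg.atria["LA"])

    # --- packed parameters -------------------------------------------------
    A = np.array([p.area_w for p in seg_params])
    l0 = np.array([p.l0 for p in seg_params])
    kat = np.array([p.k_act * p.t_max for p in seg_params])
    kp1 = np.array([p.k_p1 for p in seg_params])
    kp2 = np.array([p.k_p2 for p in seg_params])
    fs = np.array([p.fs_slope for p in seg_params])
    lmax = np.array([p.lam_max for p in seg_params])
    rh = np.array([p.r_h for p in seg_params])
    lh = np.array([p.l_h for p in seg_params])
    ltype = np.array(
        [2 if s.startswith("rv") else (1 if s in SEPTAL_SEGMENTS else 0)
         for s in ALL_SEGMENTS],
        dtype=np.int64,
    )
    ch = cfg.circulation.chambers
    e_ch = np.array([ch[c].e for c in _CHAMBER_ORDER])
    v0_ch = np.array([ch[c].v0 for c in _CHAMBER_ORDER])
    r_link = np.array([cfg.circulation.links[k].r for k in (
        "ao_sys_art", "sys_art_sys_ven", "sys_ven_vc", "vc_ra", "pa_pu", "pu_la")])
    r_valve = np.array([cfg.circulation.valves[k].r_open for k in (
        "mitral", "aortic", "tricuspid", "pulmonary")])

    cav = cfg.cavity
    lv_mask = ltype <= 1
    l_init = np.where(lv_mask, l0 * cav.l_init_ratio_lv, l0 * cav.l_init_ratio_rv)
    y0 = np.zeros(48)
    y0[2:21] = l_init
    y0[0] = cav.v_c0_lv + float(np.sum(A[lv_mask] * (l_init - l0)[lv_mask])) \
        + cav.p_lv_init / cav.k_lv
    y0[1] = cav.v_c0_rv + float(np.sum(A[~lv_mask] * (l_init - l0)[~lv_mask])) \
        + cav.p_rv_init / cav.k_rv
    y0[40:46] = [ch[c].v for c in _CHAMBER_ORDER]
    y0[46] = cfg.atria_v_init["RA"]
    y0[47] = cfg.atria_v_init["LA"]

    # --- integrate ----------------------------------------------------------
    Y = _integrate(y0, n_steps, dt, u, era, ela, A, l0, kat, kp1, kp2, fs,
                   lmax, rh, lh, ltype, cav.k_lv, cav.k_rv, cav.v_c0_lv,
                   cav.v_c0_rv, e_ch, v0_ch, cfg.atria["RA"].v0,
                   cfg.atria["LA"].v0, r_link, r_valve)

    bad = ~np.isfinite(Y)
    if bad.any():
        i_bad = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise SimulationError(
            f"solver divergence: non-finite state at t = {i_bad * dt:.2f} ms "
            f"(state indices {np.flatnonzero(bad[i_bad])[:5].tolist()})"
        )
    lmin = Y[:, 2:21].min(axis=0)
    if (lmin <= 0.05 * l0).any():
        i = int(np.argmin(Y[:, 2:21].min(axis=1)))
        raise SimulationError(f"solver divergence: fibre collapse near t = {i * dt:.2f} ms")

    # --- derived series -----------------------------------------------------
    L = Y[:, 2:21]
    Q = Y[:, 21:40]
    vw_lv = cav.v_c0_lv + np.sum(A[lv_mask] * (L[:, lv_mask] - l0[lv_mask]), axis=1)
    vw_rv = cav.v_c0_rv + np.sum(A[~lv_mask] * (L[:, ~lv_mask] - l0[~lv_mask]), axis=1)
    p_lv = cav.k_lv * (Y[:, 0] - vw_lv)
    p_rv = cav.k_rv * (Y[:, 1] - vw_rv)
    p_chambers = {c: e_ch[j] * (Y[:, 40 + j] - v0_ch[j])
                  for j, c in enumerate(_CHAMBER_ORDER)}
    p_ra = era[::2] * (Y[:, 46] - cfg.atria["RA"].v0)
    p_la = ela[::2] * (Y[:, 47] - cfg.atria["LA"].v0)

    q_mv = np.where(p_la > p_lv, (p_la - p_lv) / r_valve[0], 0.0)
    q_av = np.where(p_lv > p_chambers["ao"], (p_lv - p_chambers["ao"]) / r_valve[1], 0.0)
    q_tv = np.where(p_ra > p_rv, (p_ra - p_rv) / r_valve[2], 0.0)
    q_pv = np.where(p_rv > p_chambers["pa"], (p_rv - p_chambers["pa"]) / r_valve[3], 0.0)

    pressures = {"lv": p_lv, "rv": p_rv, "ra": p_ra, "la": p_la, **p_chambers}
    volumes = {"lv": Y[:, 0], "rv": Y[:, 1], "ra": Y[:, 46], "la": Y[:, 47],
               **{c: Y[:, 40 + j] for j, c in enumerate(_CHAMBER_ORDER)}}
    flows = {"mitral": q_mv, "aortic": q_av, "tricuspid": q_tv,
             "pulmonary": q_pv,
             "wall_lv_total": np.sum(Q[:, lv_mask], axis=1)}

    # --- cycle bookkeeping and strain ---------------------------------------
    starts = np.array([t_first + k * rr for k in range(n_cycles)])
    ref_times = []
    for k, s in enumerate(starts):
        s1 = s + rr
        seg_onsets = [t for seg in ALL_SEGMENTS for t in onsets[seg] if s <= t < s1]
        ref_times.append(min(seg_onsets) if seg_onsets else s)
    ref_idx = np.clip(np.round(np.array(ref_times) / dt).astype(int), 0, n_steps)

    strain = np.empty_like(L)
    bounds = list(np.clip(np.round(starts / dt).astype(int), 0, n_steps)) + [n_steps + 1]
    for k in range(n_cycles):
        lref = L[ref_idx[k]]
        lo = 0 if k == 0 else bounds[k]
        strain[lo:bounds[k + 1]] = 100.0 * (L[lo:bounds[k + 1]] - lref) / lref

    strain_df = pd.DataFrame(strain, columns=list(ALL_SEGMENTS))
    strain_df.insert(0, "time_ms", t_grid)
    lengths_df = pd.DataFrame(L, columns=list(ALL_SEGMENTS))
    lengths_df.insert(0, "time_ms", t_grid)
    flows_df = pd.DataFrame(Q, columns=list(ALL_SEGMENTS))
    flows_df.insert(0, "time_ms", t_grid)

    arp_end = {s: network.specs[s].t_udp + network.specs[s].t_arp for s in ALL_SEGMENTS}
    ecg = synthesize_ecg(events, sample_period=eng.ecg_sample_period,
                         duration=t_end, arp_end_by_node=arp_end)
    act_maps = [activation_times(events, k) for k in range(n_cycles)]

    return SimulationResult(
        time=t_grid, pressures=pressures, volumes=volumes, flows=flows,
        strain=strain_df, segment_lengths=lengths_df, segment_flows=flows_df,
        ecg=ecg, activation=act_maps, events=list(events),
        cycle_start_times=starts, strain_ref_times=np.array(ref_times),
        rr=rr, n_transient=min(eng.n_transient, n_cycles - 1),
        dt=dt,
    )


def summarize(result: SimulationResult) -> HemodynamicSummary:
    """Hemodynamic extrema over the final cycle (post-transient)."""
    if len(result.cycle_start_times) <= result.n_transient:
        raise ValidationError("no post-transient cycle to summarize")
    sl = result.final_cycle_slice()
    if sl.stop - sl.start < 2:
        raise ValidationError("final cycle not covered by the simulated horizon")
    p_lv = result.pressures["lv"][sl]
    p_ao = result.pressures["ao"][sl]
    v_lv = result.volumes["lv"][sl]
    edv = float(v_lv.max())
    esv = float(v_lv.min())
    return HemodynamicSummary(
        peak_lv_pressure=float(p_lv.max()),
        ao_pressure_max=float(p_ao.max()),
        ao_pressure_min=float(p_ao.min()),
        edv=edv,
        esv=esv,
        stroke_volume=edv - esv,
        ejection_fraction=100.0 * (edv - esv) / edv,
    ).validate()
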