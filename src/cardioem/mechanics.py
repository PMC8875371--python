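"""Atrial elastance and segmental ventricular wall mechanics.

Atria
-----
Atrial pressure is a linear function of instantaneous volume through a
time-varying elastance, driven by a Gaussian activation function centred
``mu`` ms after the atrial automaton fires:

    P(t) = [e_min + g(t) (e_max - e_min)] (V - V0),
    g(t) = exp(-(t - t_act - mu)^2 / (2 sigma^2))

Ventricular wall segments
-------------------------
Each of the 19 wall segments (16 LV + 3 RV) is a piston of reference fibre
length ``l0`` and effective area ``area_w``. Total fibre tension is the sum
of an active twitch component

    T_a = k_act * t_max * u(t) * lambda(l / l0)

(where ``u`` is a normalized double-exponential drive triggered by the
segment's automaton, and ``lambda`` a clipped-linear length-tension factor
with lambda(1) = 1) and a passive component, exponential in positive strain
and linear in compression with a continuous slope at zero strain.

Tension couples to cavity pressure through the piston: the segment's
tension-equivalent pressure is ``p_seg = (T_a + T_p) / area_w``, and the
segment's hydraulic flow contribution obeys an inertial-resistive law

    dq/dt = (p_seg - p_load - r_h q) / l_h,

with q > 0 meaning inward wall motion (fibre shortening, dl/dt = -q/area_w).
Free-wall LV segments are loaded by LV cavity pressure, RV layers by RV
pressure, and septal segments by the trans-septal gradient p_lv - p_rv,
which is what permits pre-ejection septal motion (septal flash) when the
two ventricles are activated asynchronously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ValidationError
from .segments import ALL_SEGMENTS, RV_SEGMENTS, SEPTAL_SEGMENTS

# ---------------------------------------------------------------------------
# Atria
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtriumParams:
    """Atrial elastance bounds (mmHg/mL), unstressed volume (mL) and the
    Gaussian activation centre/width (ms after atrial activation)."""

    e_min: float
    e_max: float
    v0: float
    mu: float
    sigma: float

    def validate(self) -> None:
        if not (self.e_max >= self.e_min > 0):
            raise ValidationError(
                f"atrium: need e_max >= e_min > 0, got e_min={self.e_min}, e_max={self.e_max}"
            )
        if self.sigma <= 0:
            raise ValidationError(f"atrium: sigma = {self.sigma} must be > 0")


def atrial_drive(t, t_act: float, params: AtriumParams):
    """Gaussian activation g(t) in [0, 1]."""
    dt = np.asarray(t, dtype=float) - t_act - params.mu
    return np.exp(-0.5 * (dt / params.sigma) ** 2)


def atrial_elastance(t, t_act: float, params: AtriumParams):
    g = atrial_drive(t, t_act, params)
    return params.e_min + g * (params.e_max - params.e_min)


def atrial_pressure(v, t, t_act: float, params: AtriumParams):
    """P = [e_min + g(t)(e_max - e_min)] (v - v0), mmHg."""
    return atrial_elastance(t, t_act, params) * (np.asarray(v, dtype=float) - params.v0)


# ---------------------------------------------------------------------------
# Segment parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentParams:
    """Mechanical parameters of one wall segment.

    k_act is the contractility level as a fraction of the nominal peak
    active tension t_max (reported as % elsewhere); t_delay the
    electromechanical onset delay after electrical activation.
    """

    name: str
    l0: float = 3.0            # reference fibre length, cm
    k_act: float = 1.0         # contractility fraction of t_max, 0..1
    t_delay: float = 30.0      # electromechanical delay, ms
    tau_c: float = 80.0        # contraction time constant, ms
    tau_r: float = 180.0       # relaxation time constant, ms
    k_p1: float = 36.0         # passive stiffness scale, tension units
    k_p2: float = 18.0         # passive stiffness exponent
    r_h: float = 0.6           # hydraulic resistance, mmHg s/mL
    l_h: float = 5e-4          # hydraulic inertance, mmHg s^2/mL
    area_w: float = 6.0        # effective piston area, cm^2-equivalent
    t_max: float = 1200.0      # nominal peak active tension at k_act = 1
    fs_slope: float = 4.0      # slope of the clipped-linear length-tension factor
    lam_max: float = 1.5       # upper clip of the length-tension factor

    def validate(self) -> None:
        if self.l0 <= 0:
            raise ValidationError(f"segment {self.name}: l0 = {self.l0} must be > 0")
        if not (0.0 <= self.k_act <= 1.0):
            raise ValidationError(
                f"segment {self.name}: k_act = {self.k_act} outside [0, 1]"
            )
        if self.tau_c <= 0 or self.tau_r <= 0:
            raise ValidationError(f"segment {self.name}: tau_c/tau_r must be > 0")
        if self.r_h < 0 or self.l_h < 0:
            raise ValidationError(f"segment {self.name}: r_h/l_h must be >= 0")
        if self.area_w <= 0 or self.t_max < 0:
            raise ValidationError(f"segment {self.name}: area_w/t_max invalid")


@dataclass
class SegmentState:
    """Dynamic state of one segment."""

    l: float                   # current fibre length, cm
    q: float = 0.0             # hydraulic flow contribution, mL/s (q>0 shortening)
    u: float = 0.0             # drive level, 0..1
    t_act: float | None = None  # last electrical activation time, ms


# ---------------------------------------------------------------------------
# Drive, tension, strain
# ---------------------------------------------------------------------------


def twitch_peak_time(tau_c: float, tau_r: float) -> float:
    """Time from mechanical onset to the twitch peak."""
    return tau_c * math.log1p(tau_r / tau_c)


def emd_drive(t, t_act, params: SegmentParams):
    """Normalized electromechanical twitch u(t) in [0, 1].

    u = 0 before ``t_act + t_delay``; afterwards the product-of-exponentials
    (1 - exp(-x/tau_c)) exp(-x/tau_r), renormalized so the peak is 1.
    Returns 0 everywhere when ``t_act`` is None.
    """
    t = np.asarray(t, dtype=float)
    if t_act is None:
        return np.zeros_like(t)
    x = t - float(t_act) - params.t_delay
    xp = twitch_peak_time(params.tau_c, params.tau_r)
    norm = (1.0 - math.exp(-xp / params.tau_c)) * math.exp(-xp / params.tau_r)
    with np.errstate(over="ignore"):
        u = (1.0 - np.exp(-x / params.tau_c)) * np.exp(-x / params.tau_r) / norm
    return np.where(x > 0.0, u, 0.0)


def length_tension_factor(l_ratio, fs_slope: float = 4.0, lam_max: float = 1.5):
    """Clipped-linear length-tension factor lambda(l/l0), with lambda(1) = 1."""
    lam = 1.0 + fs_slope * (np.asarray(l_ratio, dtype=float) - 1.0)
    return np.clip(lam, 0.0, lam_max)


def active_tension(u, l, params: SegmentParams):
    """T_a = k_act * t_max * u * lambda(l/l0); linear in contractility."""
    lam = length_tension_factor(l / params.l0, params.fs_slope, params.lam_max)
    return params.k_act * params.t_max * np.asarray(u, dtype=float) * lam


def passive_tension(strain, params: SegmentParams):
    """Passive tension: k_p1 (exp(k_p2 eps) - 1) for eps >= 0, linear with
    the matching slope k_p1 k_p2 for eps < 0 (continuous first derivative)."""
    eps = np.asarray(strain, dtype=float)
    with np.errstate(over="ignore"):
        pos = params.k_p1 * np.expm1(params.k_p2 * eps)
    neg = params.k_p1 * params.k_p2 * eps
    return np.where(eps >= 0.0, pos, neg)


def segment_strain(l, l0: float):
    """Longitudinal strain in percent, echo convention (shortening < 0)."""
    if l0 <= 0:
        raise ValidationError(f"l0 = {l0} must be > 0")
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValidationError("fibre length must stay > 0")
    return 100.0 * (l - l0) / l0


# ---------------------------------------------------------------------------
# Hydraulics and coupling
# ---------------------------------------------------------------------------


def tension_pressure(t_total, params: SegmentParams):
    """Tension-equivalent pressure p_seg = T / area_w (piston coupling)."""
    return np.asarray(t_total, dtype=float) / params.area_w


def segment_flow_dynamics(q, p_seg, p_load, params: SegmentParams):
    """dq/dt = (p_seg - p_load - r_h q) / l_h.

    q > 0 is inward wall motion (shortening); at steady state the resistive
    limit q = (p_seg - p_load)/r_h holds.
    """
    if params.l_h <= 0:
        raise ValidationError(f"segment {params.name}: l_h must be > 0 for dynamics")
    return (np.asarray(p_seg, dtype=float) - p_load - params.r_h * q) / params.l_h


def septal_load(p_lv, p_rv) -> dict[str, float]:
    """External (distending) load per segment.

    Septal LV segments are loaded by the trans-septal gradient p_lv - p_rv,
    LV free-wall segments by p_lv, RV layers by p_rv.
    """
    out: dict[str, float] = {}
    for s in ALL_SEGMENTS:
        if s in SEPTAL_SEGMENTS:
            out[s] = p_lv - p_rv
        elif s in RV_SEGMENTS:
            out[s] = p_rv
        else:
            out[s] = p_lv
    return out


def cavity_flow(segment_flows: Mapping[str, float], q_in: float, q_out: float) -> float:
    """Net rate of change of cavity blood volume: valve inflow minus outflow.

    Wall-segment flows redistribute volume between segments (their sum is
    ~0 during isovolumic phases); the blood balance of the cavity is set by
    the valves: dV/dt = q_in - q_out.
    """
    return float(q_in - q_out)


# ---------------------------------------------------------------------------
# Default parameter tables
# ---------------------------------------------------------------------------

#: Effective piston areas: basal/mid segments equal, apical smaller, RV
#: layers large (fewer segments share the RV stroke volume). Calibrated so
#: an ~18% healthy fibre shortening yields a ~50 mL stroke volume.
_BASAL_MID_AREA = 6.3
_APICAL_AREA = 4.2
_RV_AREA = 30.0

#: Nominal peak active fibre stress (t_max / area), mmHg-equivalent.
_LV_SIGMA_MAX = 225.0
_RV_SIGMA_MAX = 50.0

#: Passive stiffness scale per unit area (mmHg-equivalent at the piston).
_KP1_SIGMA = 3.5
_RV_KP1_SIGMA = 4.0

#: Hydraulic constants are specified at the reference basal/mid area and
#: scaled inversely with area so that identical fibre stresses produce
#: identical strain dynamics regardless of segment size.
_RH_REF = 0.6      # mmHg s/mL at the reference area
_LH_REF = 5e-4     # mmHg s^2/mL at the reference area


def default_segment_params(overrides: Mapping[str, Mapping] | None = None) -> dict[str, SegmentParams]:
    """Baseline (healthy, homogeneous) parameter table for the 19 segments.

    ``overrides`` maps segment name -> field overrides.
    """
    table: dict[str, SegmentParams] = {}
    for name in ALL_SEGMENTS:
        if name in RV_SEGMENTS:
            area, smax, kp1s = _RV_AREA, _RV_SIGMA_MAX, _RV_KP1_SIGMA
        elif name.startswith("apical"):
            area, smax, kp1s = _APICAL_AREA, _LV_SIGMA_MAX, _KP1_SIGMA
        else:
            area, smax, kp1s = _BASAL_MID_AREA, _LV_SIGMA_MAX, _KP1_SIGMA
        p = SegmentParams(
            name=name,
            area_w=area,
            t_max=smax * area,
            k_p1=kp1s * area,
            r_h=_RH_REF * _BASAL_MID_AREA / area,
            l_h=_LH_REF * _BASAL_MID_AREA / area,
        )
        if overrides and name in overrides:
            p = replace(p, **dict(overrides[name]))
        p.validate()
        table[name] = p
    return table
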