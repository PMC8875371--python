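"""Synthetic patient fixtures: strain traces, ECG scalars, LGE phantoms.

No patient data ship with the package (clinical strain traces exist only
on request), so every pipeline stage is exercised against synthetic
patients built here. Four profiles mirror the canonical morphologies:

- ``healthy``: intact conduction, homogeneous contractility.
- ``lbbb_nonischemic``: complete LBB block, mild global hypocontractility
  with relatively preserved lateral wall; shows the classic septal flash
  (pre-ejection septal shortening + rebound stretch) and delayed lateral
  contraction.
- ``lbbb_lateral_scar``: LBB block plus severely reduced lateral-wall
  contractility; lateral strain is markedly reduced, the septal rebound is
  lost and septal deformation exaggerated.
- ``lbbb_anteroseptal_scar``: LBB block plus scarred anteroseptal/apical
  segments; the septal flash persists while septal/apical contractility is
  reduced.

QRS widths follow the three clinical LBBB profiles (136 / 157 / 152 ms);
the slow cell-to-cell conduction of each profile is set so the synthesized
ECG reproduces them. Strain fixtures can be produced either by running the
forward model with the profile's preset parameters (``mode="model"``, the
ground truth is retained for parameter-recovery tests) or as analytic
dip-rebound-plateau template curves (``mode="template"``) for I/O and
feature-detector tests. All randomness (additive Gaussian strain noise,
phantom image noise) is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ModelConfig, load_config
from .engine import SimulationResult, run
from .errors import ValidationError
from .lge import LGEVolume
from .segments import (
    ALL_SEGMENTS,
    LATERAL_WALL,
    LV_SEGMENTS,
    OTHER_LV,
    RV_SEGMENTS,
    SEPTAL_WALL,
    normalize_segment_name,
)
from .strain import StrainTrace

# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientProfile:
    """Preset describing one synthetic patient."""

    name: str
    rr: float                      # ms
    qrs: float                     # ms, target QRS width
    lbbb: bool
    myocardial_delay: float        # ms/link; sets the QRS width under LBBB
    k_act: Mapping[str, float]     # per-LV-segment contractility fraction
    t_delay: Mapping[str, float] | None = None  # per-LV-segment EM delay, ms
    tau_c: Mapping[str, float] | None = None    # per-segment contraction tau, ms
    tau_r: Mapping[str, float] | None = None    # per-segment relaxation tau, ms
    circulation: Mapping | None = None          # circulation-section overrides
    noise_sd: float = 1.0          # % strain, additive Gaussian
    seed: int = 0

    def validate(self) -> None:
        missing = [s for s in LV_SEGMENTS if s not in self.k_act]
        if missing:
            raise ValidationError(f"profile {self.name}: presets missing {missing}")
        if self.noise_sd < 0:
            raise ValidationError(f"profile {self.name}: noise_sd must be >= 0")


def _k_map(septal: float, lateral: float, other: float,
           special: Mapping[str, float] | None = None) -> dict[str, float]:
    out = {}
    for s in LV_SEGMENTS:
        if s in SEPTAL_WALL:
            out[s] = septal
        elif s in LATERAL_WALL:
            out[s] = lateral
        else:
            out[s] = other
    if special:
        out.update(special)
    return out


#: Anteroseptal infarct territory (LAD-type): anteroseptal + apical cap.
ANTEROSEPTAL_SCAR_SEGMENTS: tuple[str, ...] = (
    "basal_anteroseptal", "mid_anteroseptal", "apical_septal", "apical_anterior",
)

#: Lateral infarct territory (LCx-type): the five lateral segments.
LATERAL_SCAR_SEGMENTS: tuple[str, ...] = tuple(LATERAL_WALL)

#: Presets shared by the LBBB profiles: early septal mechanical onset with a
#: brisk, early-relaxing septal twitch, markedly delayed lateral contraction
#: (the septal-to-lateral activation pattern typical of LBBB), and an early,
#: brisk right ventricle — under LBBB the RV leads the LV, and its pressure
#: rise during the LV pre-ejection period pushes the septum leftward. The
#: early septal force decay is what lets the delayed lateral contraction
#: re-stretch the septum during ejection (rebound stretch).
_LBBB_DELAYS = _k_map(septal=0.0, lateral=115.0, other=85.0) | {
    s: 5.0 for s in RV_SEGMENTS}
_LBBB_TAU_C = {s: 30.0 for s in SEPTAL_WALL} | {s: 40.0 for s in RV_SEGMENTS}
_LBBB_TAU_R = {s: 70.0 for s in SEPTAL_WALL}

#: Heart-failure loading state shared by the LBBB profiles: moderately
#: reduced circulating volume (treated congestion) and elevated systemic
#: resistance (compensatory vasoconstriction maintaining arterial pressure
#: at low output). Raising aortic diastolic pressure lengthens the
#: pre-ejection period, the phase in which the septal flash develops.
_LBBB_CIRCULATION = {
    "chambers": {"sys_ven": {"v_init": 2750.0}},
    "links": {"sys_art_sys_ven": 2.0},
}

PROFILES: dict[str, PatientProfile] = {
    "healthy": PatientProfile(
        name="healthy", rr=1000.0, qrs=74.0, lbbb=False, myocardial_delay=15.0,
        k_act=_k_map(1.0, 1.0, 1.0),
    ),
    # QRS ~136 ms, reduced-EF class: dyssynchrony + global hypocontractility,
    # lateral wall relatively preserved -> septal flash with rebound.
    "lbbb_nonischemic": PatientProfile(
        name="lbbb_nonischemic", rr=900.0, qrs=136.0, lbbb=True,
        myocardial_delay=22.0,
        k_act=_k_map(septal=0.60, lateral=0.85, other=0.55),
        t_delay=_LBBB_DELAYS, tau_c=_LBBB_TAU_C, tau_r=_LBBB_TAU_R,
        circulation=_LBBB_CIRCULATION,
    ),
    # QRS ~157 ms: scarred lateral wall -> lateral strain collapses, septal
    # deformation exaggerated, rebound lost.
    "lbbb_lateral_scar": PatientProfile(
        name="lbbb_lateral_scar", rr=900.0, qrs=157.0, lbbb=True,
        myocardial_delay=31.0,
        k_act=_k_map(septal=0.90, lateral=0.22, other=0.55),
        t_delay=_LBBB_DELAYS, tau_c=_LBBB_TAU_C, tau_r=_LBBB_TAU_R,
        circulation=_LBBB_CIRCULATION,
    ),
    # QRS ~152 ms: anteroseptal/apical scar -> flash and rebound persist while
    # septal/apical contractility is reduced.
    "lbbb_anteroseptal_scar": PatientProfile(
        name="lbbb_anteroseptal_scar", rr=900.0, qrs=152.0, lbbb=True,
        myocardial_delay=29.0,
        k_act=_k_map(septal=0.60, lateral=0.80, other=0.55,
                     special={s: 0.32 for s in ANTEROSEPTAL_SCAR_SEGMENTS}),
        t_delay=_LBBB_DELAYS, tau_c=_LBBB_TAU_C, tau_r=_LBBB_TAU_R,
        circulation=_LBBB_CIRCULATION,
    ),
}


def profile_config(profile: PatientProfile) -> ModelConfig:
    """Model configuration implementing a profile's presets."""
    over = {
        "conduction": {
            "rr": profile.rr,
            "lbbb": profile.lbbb,
            "myocardial_delay": profile.myocardial_delay,
        },
    }
    seg_over: dict[str, dict] = {}
    for s in ALL_SEGMENTS:
        d: dict = {}
        if s in profile.k_act:
            d["k_act"] = profile.k_act[s]
        for fld, preset in (("t_delay", profile.t_delay),
                            ("tau_c", profile.tau_c),
                            ("tau_r", profile.tau_r)):
            if preset and s in preset:
                d[fld] = preset[s]
        if d:
            seg_over[s] = d
    over["mechanics"] = {"segments": seg_over}
    if profile.circulation:
        over["circulation"] = profile.circulation
    return load_config(over)


def fitting_base_config(dataset: "PatientDataset",
                        reset: tuple[str, ...] = ("k_act", "t_delay")) -> ModelConfig:
    """Base model for personalizing a patient dataset.

    Keeps the patient context that is known before fitting — conduction
    state (LBBB, RR, QRS-calibrated delays), loading conditions and twitch
    shape — while resetting the fields the fitter will estimate to their
    neutral defaults (contractility 1.0, electromechanical delay 30 ms), so
    the fit starts agnostic of the generating values.
    """
    if dataset.profile is None:
        raise ValidationError("dataset carries no profile to build a base from")
    neutral = {"k_act": 1.0, "t_delay": 30.0}
    unknown = [f for f in reset if f not in neutral]
    if unknown:
        raise ValidationError(f"no neutral default for fields {unknown}")
    cfg = profile_config(dataset.profile)
    over = {"mechanics": {"segments": {
        s: {f: neutral[f] for f in reset} for s in LV_SEGMENTS}}}
    return cfg.with_overrides(over)


# ---------------------------------------------------------------------------
# Strain fixtures
# ---------------------------------------------------------------------------


@dataclass
class PatientDataset:
    """The unit the personalization pipeline consumes."""

    name: str
    rr: float                       # ms
    qrs: float                      # ms
    strain: StrainTrace             # 16 LV segments, one cycle, cycle-relative time
    ejection_window: tuple[float, float]   # (t_open, t_close) ms, cycle-relative
    truth_k_act: dict[str, float] | None = None
    lge: LGEVolume | None = None
    profile: PatientProfile | None = None
    simulation: SimulationResult | None = None


def _rwave_slice(result: SimulationResult) -> slice:
    """Index window spanning the last full R-wave-to-R-wave cycle.

    Echo strain traces are gated on the R wave; the fixture cycle therefore
    runs from the first-ventricular-activation reference of the penultimate
    pacemaker cycle to that of the final one (so strain starts and ends
    near zero by construction).
    """
    if len(result.strain_ref_times) < 2:
        raise ValidationError("need at least two cycles for an R-gated trace")
    t0, t1 = result.strain_ref_times[-2], result.strain_ref_times[-1]
    i0 = int(np.searchsorted(result.time, t0))
    i1 = int(np.searchsorted(result.time, t1))
    return slice(i0, i1)


def _final_cycle_trace(result: SimulationResult, segments=LV_SEGMENTS) -> StrainTrace:
    sl = _rwave_slice(result)
    t = result.time[sl] - result.time[sl.start]
    df = result.strain[list(segments)].iloc[sl].reset_index(drop=True)
    return StrainTrace(time=t, strain=df)


def ejection_window_from(result: SimulationResult) -> tuple[float, float]:
    """Aortic valve opening/closing on the R-gated final cycle, relative ms."""
    sl = _rwave_slice(result)
    q = result.flows["aortic"][sl]
    open_idx = np.flatnonzero(q > 0.0)
    if open_idx.size == 0:
        raise ValidationError("no ejection detected on the final cycle")
    t = result.time[sl] - result.time[sl.start]
    return float(t[open_idx[0]]), float(t[open_idx[-1]])


def make_strain_fixture(profile: str | PatientProfile, mode: str = "model",
                        seed: int | None = None, n_cycles: int = 8,
                        dt: float = 0.5) -> PatientDataset:
    """Build a synthetic patient dataset.

    ``mode="model"`` runs the forward simulator with the profile presets and
    adds seeded Gaussian noise; the preset contractilities are kept as
    ground truth. ``mode="template"`` composes analytic curve shapes
    (no simulation) for I/O and feature-detection tests.
    """
    if isinstance(profile, str):
        if profile not in PROFILES:
            raise ValidationError(
                f"unknown profile {profile!r}; available: {sorted(PROFILES)}"
            )
        profile = PROFILES[profile]
    profile.validate()
    seed = profile.seed if seed is None else int(seed)

    if mode == "model":
        from .conduction import measure_qrs  # local import to avoid cycle at doc time

        cfg = profile_config(profile)
        result = run(cfg, n_cycles=n_cycles, dt=dt)
        trace = _final_cycle_trace(result)
        rng = np.random.default_rng(seed)
        noisy = trace.strain + rng.normal(0.0, profile.noise_sd,
                                          size=trace.strain.shape)
        qrs = float(measure_qrs(result.ecg))
        return PatientDataset(
            name=profile.name, rr=profile.rr, qrs=qrs,
            strain=StrainTrace(time=trace.time, strain=noisy),
            ejection_window=ejection_window_from(result),
            truth_k_act=dict(profile.k_act), profile=profile,
            simulation=result,
        )
    if mode == "template":
        return _template_fixture(profile, seed)
    raise ValidationError(f"unknown fixture mode {mode!r} (model|template)")


def _template_curve(t: np.ndarray, kind: str, rr: float) -> np.ndarray:
    """Analytic dip-rebound-plateau archetypes on cycle-relative time."""
    x = t / rr

    def bump(c, w, a):
        return a * np.exp(-0.5 * ((x - c) / w) ** 2)

    if kind == "septal_flash":
        # early dip, rebound above baseline, shallow late plateau
        return -bump(0.12, 0.05, 8.0) + bump(0.38, 0.10, 3.0) - bump(0.45, 0.22, 9.0)
    if kind == "septal_noflash":
        # deep monotone systolic shortening, no early dip
        return -bump(0.42, 0.16, 20.0)
    if kind == "lateral_delayed":
        return -bump(0.52, 0.15, 17.0)
    if kind == "lateral_scarred":
        return -bump(0.52, 0.17, 6.0)
    if kind == "normal":
        return -bump(0.40, 0.15, 18.0)
    raise ValidationError(f"unknown template kind {kind!r}")


def _template_fixture(profile: PatientProfile, seed: int) -> PatientDataset:
    rr = profile.rr
    t = np.arange(0.0, rr + 1e-9, 5.0)
    kinds = {
        "healthy": ("normal", "normal", "normal"),
        "lbbb_nonischemic": ("septal_flash", "lateral_delayed", "normal"),
        "lbbb_lateral_scar": ("septal_noflash", "lateral_scarred", "normal"),
        "lbbb_anteroseptal_scar": ("septal_flash", "lateral_delayed", "normal"),
    }[profile.name]
    sep_k, lat_k, other_k = kinds
    rng = np.random.default_rng(seed)
    cols = {}
    for s in LV_SEGMENTS:
        if s in SEPTAL_WALL:
            base = _template_curve(t, sep_k, rr)
        elif s in LATERAL_WALL:
            base = _template_curve(t, lat_k, rr)
        else:
            base = _template_curve(t, other_k, rr)
        scale = profile.k_act[s] / max(profile.k_act.values())
        cols[s] = base * (0.6 + 0.4 * scale) + rng.normal(0.0, profile.noise_sd, t.size)
    # nominal ejection window for the archetypes: 28%..55% of the cycle
    return PatientDataset(
        name=profile.name, rr=rr, qrs=profile.qrs,
        strain=StrainTrace(time=t, strain=pd.DataFrame(cols)),
        ejection_window=(0.28 * rr, 0.55 * rr),
        truth_k_act=dict(profile.k_act), profile=profile,
    )


# ---------------------------------------------------------------------------
# LGE phantoms
# ---------------------------------------------------------------------------

_RING_SLICES = ("basal", "mid", "apical")
_RING_SECTORS = {
    "basal": LV_SEGMENTS[0:6],
    "mid": LV_SEGMENTS[6:12],
    "apical": LV_SEGMENTS[12:16],
}


def make_lge_phantom(scarred_segments, transmurality: float,
                     contrast_ratio: float = 3.0, noise_sd: float = 10.0,
                     seed: int = 0, size: int = 96, r_endo: float = 18.0,
                     r_epi: float = 30.0) -> LGEVolume:
    """Annular short-axis phantom with a subendocardial scar band.

    Scarred segments receive a bright band from the endocardium outward
    occupying ``transmurality`` percent of the radial wall thickness, at
    ``contrast_ratio`` times the remote-myocardium intensity (base 100);
    i.i.d. Gaussian noise of absolute standard deviation ``noise_sd``
    intensity units is added everywhere inside the mask.
    """
    if not (0.0 <= transmurality <= 100.0):
        raise ValidationError(f"transmurality {transmurality} outside [0, 100]")
    scarred = [normalize_segment_name(s) for s in scarred_segments]
    if transmurality > 0 and not scarred:
        raise ValidationError("nonzero transmurality with an empty scar list")

    rng = np.random.default_rng(seed)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c, xx - c)
    ang = np.arctan2(xx - c, -(yy - c))  # 0 at 12 o'clock, clockwise, (-pi, pi]

    n_slices = len(_RING_SLICES)
    stack = np.zeros((n_slices, size, size))
    mask = np.zeros((n_slices, size, size), dtype=bool)
    labels = np.full((n_slices, size, size), -1, dtype=np.int64)

    base_int, scar_int = 100.0, 100.0 * contrast_ratio
    for k, ring in enumerate(_RING_SLICES):
        sectors = _RING_SECTORS[ring]
        width = 2.0 * np.pi / len(sectors)
        msk = (r >= r_endo) & (r <= r_epi)
        mask[k] = msk
        sector_idx = np.floor((ang + np.pi) / width).astype(int) % len(sectors)
        for j, seg in enumerate(sectors):
            sel = msk & (sector_idx == j)
            labels[k][sel] = LV_SEGMENTS.index(seg)
        img = np.where(msk, base_int, 0.0)
        if transmurality > 0:
            depth = r_endo + (transmurality / 100.0) * (r_epi - r_endo)
            for j, seg in enumerate(sectors):
                if seg in scarred:
                    band = msk & (sector_idx == j) & (r <= depth)
                    img[band] = scar_int
        img[msk] += rng.normal(0.0, noise_sd, size=int(msk.sum()))
        stack[k] = img

    truth = {s: (transmurality if s in scarred else 0.0) for s in LV_SEGMENTS}
    return LGEVolume(stack=stack, mask=mask, labels=labels, scar_truth=truth)
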