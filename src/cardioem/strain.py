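"""Wall-level strain curves, RMSE against observations, and LBBB pattern
feature detection.

The septal and lateral wall curves are the unweighted pointwise means of
five segments each, following the standard echo groupings: the septal wall
averages apical septal, mid/basal inferoseptal and mid/basal anteroseptal;
the lateral wall averages apical lateral, mid/basal inferolateral and
mid/basal anterolateral.

Curves are compared by root-mean-square error after resampling both onto a
common cycle-normalized grid (patients and model generally have different
RR intervals), and screened for the LBBB septal deformation pattern:
pre-ejection shortening followed by systolic re-lengthening (septal
rebound stretch) — together, the septal flash.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .segments import LATERAL_WALL, SEPTAL_WALL, normalize_segment_name

WALLS: dict[str, tuple[str, ...]] = {
    "septal": SEPTAL_WALL,
    "lateral": LATERAL_WALL,
}


@dataclass
class StrainTrace:
    """Per-segment longitudinal strain (%) on a common time grid (ms)."""

    time: np.ndarray
    strain: pd.DataFrame  # one column per AHA segment name

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or len(self.time) != len(self.strain):
            raise ValidationError("time grid and strain table lengths differ")
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("time grid must be strictly increasing")
        if not np.isfinite(self.strain.to_numpy()).all():
            raise ValidationError("strain values must be finite")

    @property
    def segments(self) -> list[str]:
        return list(self.strain.columns)


@dataclass
class WallCurve:
    """Averaged wall strain curve (%) vs time (ms, cycle-relative)."""

    wall: str
    time: np.ndarray
    strain: np.ndarray
    segments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        if self.time.shape != self.strain.shape:
            raise ValidationError("wall curve time/strain shape mismatch")


@dataclass
class PatternFeatures:
    """LBBB deformation pattern features of one wall curve."""

    septal_flash: bool
    pre_ejection_shortening: float   # % magnitude (>= 0)
    rebound_stretch: float           # % magnitude (>= 0)
    peak_strain: float               # most negative strain, %
    time_to_peak: float              # ms from cycle start to peak strain


def wall_average(trace: StrainTrace, wall: str) -> WallCurve:
    """Pointwise unweighted mean of the wall's five segments."""
    if wall not in WALLS:
        raise ValidationError(f"unknown wall {wall!r}; expected one of {list(WALLS)}")
    names = WALLS[wall]
    cols = {normalize_segment_name(c): c for c in trace.strain.columns}
    missing = [s for s in names if s not in cols]
    if missing:
        raise ValidationError(
            f"{wall} wall average: missing segments {', '.join(missing)}"
        )
    data = trace.strain[[cols[s] for s in names]].to_numpy()
    return WallCurve(wall=wall, time=trace.time.copy(),
                     strain=data.mean(axis=1), segments=tuple(names))


def resample_to_cycle(curve: WallCurve, n: int = 200,
                      normalize: bool = True) -> np.ndarray:
    """Linear resampling onto n points spanning the curve's support.

    With ``normalize`` the abscissa is the fraction of the cycle, which is
    how curves with different RR intervals are aligned before comparison.
    """
    t = curve.time
    if normalize:
        x = (t - t[0]) / (t[-1] - t[0])
        xi = np.linspace(0.0, 1.0, n)
    else:
        x = t
        xi = np.linspace(t[0], t[-1], n)
    return np.interp(xi, x, curve.strain)


def rmse(sim: WallCurve, obs: WallCurve, n: int = 200,
         normalize: bool = True) -> float:
    """Root-mean-square error between two wall curves, in % strain.

    Both curves are resampled to a common cycle-normalized grid (N points,
    linear interpolation) before the pointwise comparison. Without
    normalization the curves must overlap in absolute time.
    """
    if len(sim.time) < 2 or len(obs.time) < 2:
        raise ValidationError("rmse needs at least two samples per curve")
    if not normalize:
        lo = max(sim.time[0], obs.time[0])
        hi = min(sim.time[-1], obs.time[-1])
        if hi <= lo:
            raise ValidationError("curves have non-overlapping time supports")
        xi = np.linspace(lo, hi, n)
        a = np.interp(xi, sim.time, sim.strain)
        b = np.interp(xi, obs.time, obs.strain)
    else:
        a = resample_to_cycle(sim, n)
        b = resample_to_cycle(obs, n)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def detect_features(curve: WallCurve, ejection_window: tuple[float, float],
                    flash_threshold: float = 1.5,
                    rebound_threshold: float = 1.0) -> PatternFeatures:
    """Detect pre-ejection shortening and rebound stretch on a wall curve.

    ``ejection_window`` is (t_open, t_close) of the aortic valve, on the
    curve's own time axis. Pre-ejection shortening is the magnitude of the
    strain minimum before t_open, counted only when that minimum is a true
    local dip; rebound stretch is the largest re-lengthening above that
    minimum achieved before t_close. The flash flag requires both to exceed
    their thresholds (defaults 1.5% and 1.0%).
    """
    t_open, t_close = ejection_window
    t = curve.time
    if t_open <= t[0] or t_close > t[-1] + 1e-9 or t_close <= t_open:
        raise ValidationError(
            f"ejection window [{t_open}, {t_close}] outside curve support "
            f"[{t[0]}, {t[-1]}]"
        )
    s = curve.strain
    pre = s[t <= t_open]
    i_min = int(np.argmin(pre))
    pre_min = float(pre[i_min])
    pre_shortening = max(0.0, -pre_min)
    # a dip at the very first sample is baseline, not pre-ejection contraction
    is_local_dip = 0 < i_min and pre_min < 0.0
    sys_mask = (t >= t[i_min]) & (t <= t_close)
    rebound = max(0.0, float(s[sys_mask].max() - pre_min)) if is_local_dip else 0.0
    flash = bool(
        is_local_dip
        and pre_shortening >= flash_threshold
        and rebound >= rebound_threshold
    )
    i_peak = int(np.argmin(s))
    return PatternFeatures(
        septal_flash=flash,
        pre_ejection_shortening=pre_shortening if is_local_dip else 0.0,
        rebound_stretch=rebound,
        peak_strain=float(s[i_peak]),
        time_to_peak=float(t[i_peak] - t[0]),
    )
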