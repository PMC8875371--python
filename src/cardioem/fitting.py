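"""Personalization: one-at-a-time fitting of segment parameters to strain.

The clinical workflow this encodes adjusts one model parameter at a time
(depolarization delays, contractility, electromechanical driving time
constants, passive stiffness — in that declared order) until the simulated
septal and lateral wall strain curves match the patient-derived targets.
Here that manual loop is made deterministic: cyclic coordinate descent
where each free parameter is grid-scanned within bounds (with optional
zoom refinement around the best grid point) and the value minimizing the
summed septal + lateral RMSE is kept; a full sweep that improves total
RMSE by less than the tolerance stops the fit.

Parameters are tied per segment group (septal 5 / lateral 5 / remaining 6
by default) to keep the problem identifiable from two target curves;
per-segment freeing is available when 16 target traces exist.

The output mirrors the clinical maps: per-segment contractility (% of
nominal) and electrical activation delay (ms), serialized in AHA order for
bull's-eye display, plus per-wall RMSEs (%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, load_config
from .engine import SimulationResult, run
from .errors import SimulationError, ValidationError
from .segments import LATERAL_WALL, LV_SEGMENTS, OTHER_LV, SEPTAL_WALL
from .strain import WallCurve, rmse, wall_average

_FREE_FIELDS = ("k_act", "t_delay", "tau_c", "tau_r", "k_p1")
#: declared coordinate-descent order over parameter classes
_FIELD_ORDER = {"t_delay": 0, "k_act": 1, "tau_c": 2, "tau_r": 3, "k_p1": 4}

_DEFAULT_BOUNDS = {
    "k_act": (0.05, 1.0),
    "t_delay": (0.0, 150.0),
    "tau_c": (20.0, 140.0),
    "tau_r": (50.0, 300.0),
    "k_p1": (5.0, 80.0),
}


@dataclass(frozen=True)
class FitParameter:
    """One free parameter: a SegmentParams field tied across a segment group."""

    fld: str
    segments: tuple[str, ...]
    bounds: tuple[float, float]
    n_grid: int = 5
    n_refine: int = 1
    label: str = ""

    def validate(self) -> None:
        if self.fld not in _FREE_FIELDS:
            raise ValidationError(f"cannot free field {self.fld!r} ({_FREE_FIELDS})")
        lo, hi = self.bounds
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValidationError(f"{self.name}: bounds {self.bounds} invalid")
        if self.n_grid < 2:
            raise ValidationError(f"{self.name}: grid must have >= 2 points")
        if not self.segments:
            raise ValidationError(f"{self.name}: empty segment group")

    @property
    def name(self) -> str:
        return self.label or f"{self.fld}[{self.segments[0]}+{len(self.segments) - 1}]"


@dataclass
class FitSpec:
    """Free parameters, scan resolution and stopping rule."""

    parameters: list[FitParameter]
    max_sweeps: int = 3
    tol: float = 0.05        # stop when a sweep improves total RMSE by less (%)
    n_cycles: int = 8        # forward-run length per evaluation
    dt: float = 0.5          # forward-run step, ms
    rmse_points: int = 200

    def validate(self) -> "FitSpec":
        if not self.parameters:
            raise ValidationError("fit spec has no free parameters")
        for p in self.parameters:
            p.validate()
        if self.max_sweeps < 1:
            raise ValidationError("max_sweeps must be >= 1")
        return self

    def ordered(self) -> list[FitParameter]:
        return sorted(self.parameters, key=lambda p: _FIELD_ORDER[p.fld])


WALL_GROUPS: dict[str, tuple[str, ...]] = {
    "septal": SEPTAL_WALL,
    "lateral": LATERAL_WALL,
    "other": OTHER_LV,
}


def default_fitspec(free_fields: Sequence[str] = ("t_delay", "k_act"),
                    groups: Mapping[str, Sequence[str]] | None = None,
                    n_grid: int = 5, n_refine: int = 1,
                    bounds: Mapping[str, tuple[float, float]] | None = None,
                    **kwargs) -> FitSpec:
    """Wall-group FitSpec: each free field is tied per wall group."""
    groups = {k: tuple(v) for k, v in (groups or WALL_GROUPS).items()}
    params = []
    for fld in free_fields:
        b = (bounds or {}).get(fld, _DEFAULT_BOUNDS[fld])
        for gname, segs in groups.items():
            params.append(FitParameter(fld=fld, segments=segs, bounds=b,
                                       n_grid=n_grid, n_refine=n_refine,
                                       label=f"{fld}.{gname}"))
    return FitSpec(parameters=params, **kwargs).validate()


def per_segment_fitspec(free_fields: Sequence[str] = ("k_act",),
                        segments: Sequence[str] = LV_SEGMENTS,
                        **kwargs) -> FitSpec:
    """One free parameter per segment (needs 16 target traces to identify)."""
    return default_fitspec(free_fields,
                           groups={s: (s,) for s in segments}, **kwargs)


@dataclass
class FitResult:
    """Fitted parameters and the clinical-style output maps."""

    values: dict[str, float]            # parameter label -> fitted value
    segment_table: pd.DataFrame         # per LV segment: fitted fields
    rmse_septal: float                  # %
    rmse_lateral: float                 # %
    contractility: pd.Series            # % of nominal, 16 LV segments, AHA order
    delays: pd.Series                   # electrical activation delay (ms)
    convergence: list[float]            # total RMSE after each accepted move
    failures: list[str]                 # grid points where the model diverged
    config: ModelConfig                 # fitted configuration
    n_evaluations: int = 0

    @property
    def total_rmse(self) -> float:
        return self.rmse_septal + self.rmse_lateral


def _wall_targets_ok(targets: Mapping[str, WallCurve]) -> None:
    for wall in ("septal", "lateral"):
        if wall not in targets:
            raise ValidationError(f"fit targets must include the {wall} wall curve")


def simulated_wall_curves(result: SimulationResult) -> dict[str, WallCurve]:
    """R-gated final-cycle septal and lateral wall curves of a simulation."""
    from .synthetic import _final_cycle_trace  # deferred: synthetic imports engine

    trace = _final_cycle_trace(result)
    return {w: wall_average(trace, w) for w in ("septal", "lateral")}


def activation_delay_map(result: SimulationResult) -> pd.Series:
    """Electrical activation delay per LV segment (ms after the earliest)."""
    amap = result.activation[-1]
    onsets = {s: amap.get(s, np.nan) for s in LV_SEGMENTS}
    t0 = np.nanmin(list(onsets.values()))
    return pd.Series({s: onsets[s] - t0 for s in LV_SEGMENTS}, name="delay_ms")


def calibrate_myocardial_delay(qrs_ms: float, rr_ms: float, lbbb: bool = True,
                               lo: float = 5.0, hi: float = 60.0,
                               n_iter: int = 12) -> float:
    """Set the cell-to-cell conduction delay from a measured QRS width.

    The patient's two ECG scalars (RR interval and QRS width) personalize
    the conduction model: the inter-segment myocardial delay is bisected
    until the synthesized QRS width of a conduction-only simulation matches
    the measurement. QRS width grows monotonically with the delay under
    LBBB, so bisection converges.
    """
    from .conduction import build_network, measure_qrs, simulate_conduction, synthesize_ecg

    def qrs_of(myo: float) -> float:
        net = build_network({"rr": rr_ms, "lbbb": lbbb, "myocardial_delay": myo})
        events = simulate_conduction(net, 20.0 + 3 * rr_ms)
        arp = {s: net.specs[s].t_udp + net.specs[s].t_arp for s in LV_SEGMENTS}
        return measure_qrs(synthesize_ecg(events, arp_end_by_node=arp))

    if qrs_of(lo) >= qrs_ms:
        return lo
    if qrs_of(hi) <= qrs_ms:
        return hi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if qrs_of(mid) < qrs_ms:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fit_one_at_a_time(targets: Mapping[str, WallCurve], spec: FitSpec,
                      base_config: ModelConfig | Mapping | None = None,
                      verbose: bool = False) -> FitResult:
    """Cyclic one-at-a-time coordinate descent on wall-curve RMSE.

    Deterministic: identical targets, spec and base configuration give an
    identical result. A simulation failure at a grid point scores +inf and
    is logged in ``failures`` rather than aborting the fit.
    """
    spec = spec.validate()
    _wall_targets_ok(targets)
    if base_config is None or isinstance(base_config, Mapping):
        base = load_config(base_config)
    else:
        base = base_config.validate()

    params = spec.ordered()
    # start from the base configuration's values (group mean)
    values: dict[str, float] = {}
    for p in params:
        values[p.name] = float(np.mean([getattr(base.segments[s], p.fld)
                                        for s in p.segments]))
        lo, hi = p.bounds
        values[p.name] = min(max(values[p.name], lo), hi)

    cache: dict[tuple, tuple[float, float, float]] = {}
    failures: list[str] = []
    n_eval = 0

    def build_config(vals: Mapping[str, float]) -> ModelConfig:
        seg_over: dict[str, dict] = {}
        for p in params:
            for s in p.segments:
                seg_over.setdefault(s, {})[p.fld] = vals[p.name]
        return base.with_overrides({"mechanics": {"segments": seg_over}})

    def score(vals: Mapping[str, float]) -> tuple[float, float, float]:
        nonlocal n_eval
        key = tuple(round(vals[p.name], 10) for p in params)
        if key in cache:
            return cache[key]
        n_eval += 1
        try:
            res = run(build_config(vals), n_cycles=spec.n_cycles, dt=spec.dt)
            curves = simulated_wall_curves(res)
            r_sep = rmse(curves["septal"], targets["septal"], n=spec.rmse_points)
            r_lat = rmse(curves["lateral"], targets["lateral"], n=spec.rmse_points)
            out = (r_sep + r_lat, r_sep, r_lat)
        except SimulationError as e:
            failures.append(f"{dict(vals)}: {e}")
            out = (math.inf, math.inf, math.inf)
        cache[key] = out
        return out

    best_total, best_sep, best_lat = score(values)
    convergence = [best_total]

    for sweep in range(spec.max_sweeps):
        sweep_start = best_total
        for p in params:
            lo, hi = p.bounds
            for level in range(p.n_refine + 1):
                grid = np.linspace(lo, hi, p.n_grid)
                trial = dict(values)
                results = []
                for g in grid:
                    trial[p.name] = float(g)
                    results.append(score(trial)[0])
                j = int(np.argmin(results))
                if results[j] < best_total:
                    values[p.name] = float(grid[j])
                    best_total, best_sep, best_lat = score(values)
                    convergence.append(best_total)
                # zoom around the best value seen for this parameter
                centre = values[p.name]
                step = (hi - lo) / (p.n_grid - 1)
                lo = max(p.bounds[0], centre - step)
                hi = min(p.bounds[1], centre + step)
            if verbose:
                print(f"  sweep {sweep} {p.name} -> {values[p.name]:.4g} "
                      f"(total RMSE {best_total:.3f})")
        if sweep_start - best_total < spec.tol:
            break

    cfg = build_config(values)
    res = run(cfg, n_cycles=spec.n_cycles, dt=spec.dt)
    table = pd.DataFrame(
        {fld: [getattr(cfg.segments[s], fld) for s in LV_SEGMENTS]
         for fld in _FREE_FIELDS},
        index=list(LV_SEGMENTS),
    )
    return FitResult(
        values=values,
        segment_table=table,
        rmse_septal=best_sep,
        rmse_lateral=best_lat,
        contractility=contractility_bullseye_from_config(cfg),
        delays=activation_delay_map(res),
        convergence=convergence,
        failures=failures,
        config=cfg,
        n_evaluations=n_eval,
    )


def contractility_bullseye_from_config(cfg: ModelConfig) -> pd.Series:
    return pd.Series({s: 100.0 * cfg.segments[s].k_act for s in LV_SEGMENTS},
                     name="contractility_pct")


def contractility_bullseye(result: FitResult) -> pd.Series:
    """Fitted contractility (%) per LV segment in AHA order."""
    return result.contractility.copy()


@dataclass
class ConcordanceResult:
    """Agreement between low contractility and high LGE transmurality."""

    spearman_rho: float                # NaN when a map is constant
    overlap_fraction: float            # Jaccard overlap of the two sets
    low_contractility_set: tuple[str, ...]
    high_transmurality_set: tuple[str, ...]
    overlap_set: tuple[str, ...]       # intersection, AHA order


def concordance(contractility: pd.Series, transmurality: pd.Series,
                low_threshold: float = 50.0,
                high_threshold: float = 50.0) -> ConcordanceResult:
    """Rank agreement between contractility deficit and scar transmurality.

    Returns the Spearman correlation between (100 - contractility) and
    transmurality over the 16 segments (NaN when either map is constant),
    and the Jaccard overlap between {contractility <= low_threshold} and
    {transmurality >= high_threshold} (1.0 when both sets are empty).
    """
    c = contractility.reindex(LV_SEGMENTS)
    t = transmurality.reindex(LV_SEGMENTS)
    if c.isna().any() or t.isna().any():
        raise ValidationError("concordance requires both maps on all 16 segments")
    deficit = 100.0 - c.to_numpy()
    tv = t.to_numpy()
    if np.ptp(deficit) == 0.0 or np.ptp(tv) == 0.0:
        rho = math.nan
    else:
        rho = float(stats.spearmanr(deficit, tv).statistic)
    low = {s for s in LV_SEGMENTS if c[s] <= low_threshold}
    high = {s for s in LV_SEGMENTS if t[s] >= high_threshold}
    union = low | high
    overlap = 1.0 if not union else len(low & high) / len(union)
    return ConcordanceResult(
        spearman_rho=rho,
        overlap_fraction=float(overlap),
        low_contractility_set=tuple(s for s in LV_SEGMENTS if s in low),
        high_transmurality_set=tuple(s for s in LV_SEGMENTS if s in high),
        overlap_set=tuple(s for s in LV_SEGMENTS if s in low & high),
    )
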