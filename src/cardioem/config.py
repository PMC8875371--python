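"""Model configuration: schema, defaults, loading and validation.

A single sectioned configuration file (YAML or JSON; YAML is a superset of
JSON so one loader handles both) describes the whole model:

.. code-block:: yaml

    conduction:
      rr: 1000            # cycle length, ms
      lbbb: false         # disable LBB outgoing links (complete block)
      lbb_extra_delay: null   # ms; incomplete block instead of removal
      myocardial_delay: 15    # ms per inter-segment link
      transseptal_delay: 25   # ms per RV->septum link
      phases: {}          # node -> [t_sdd, t_udp, t_arp, t_rrp]
      link_delays: {}     # "SRC->DST" -> ms
    mechanics:
      segments:           # per-segment overrides of SegmentParams fields
        basal_anterolateral: {k_act: 0.9, t_delay: 40}
      atria:
        RA: {e_min: 0.06, e_max: 0.18, v0: 10, mu: 80, sigma: 45}
        LA: {e_min: 0.10, e_max: 0.30, v0: 10, mu: 80, sigma: 45}
    cavity:
      k_lv: 40.0          # cavity coupling stiffness, mmHg/mL
      k_rv: 25.0
      v_c0_lv: 68.0       # cavity volume at reference fibre lengths, mL
      v_c0_rv: 80.0
    circulation:
      chambers: {ao: {e: 2.2, v0: 60, v_init: 100}, ...}
      links: {ao_sys_art: 0.05, ...}
      valves: {mitral: 0.010, ...}
    engine:
      dt: 0.5             # integration step, ms
      n_cycles: 15
      n_transient: 5

Every field has a shipped default (the calibrated baseline); an empty file
yields the baseline model. All units are normalized to ms, mmHg, mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .circulation import CirculationParams
from .errors import ValidationError
from .mechanics import AtriumParams, SegmentParams, default_segment_params
from .segments import ALL_SEGMENTS, normalize_segment_name

DEFAULT_ATRIA: dict[str, AtriumParams] = {
    "RA": AtriumParams(e_min=0.06, e_max=0.18, v0=10.0, mu=80.0, sigma=45.0),
    "LA": AtriumParams(e_min=0.10, e_max=0.30, v0=10.0, mu=80.0, sigma=45.0),
}

DEFAULT_ATRIAL_V_INIT = {"RA": 193.2, "LA": 161.3}


@dataclass
class CavityParams:
    """Cavity-wall volume coupling and initial ventricular states."""

    k_lv: float = 40.0      # mmHg/mL: stiffness tying blood volume to wall volume
    k_rv: float = 25.0
    v_c0_lv: float = 68.0   # mL: LV cavity volume when all fibres are at l0
    v_c0_rv: float = 80.0
    l_init_ratio_lv: float = 0.9905   # initial fibre stretch l/l0 (cycle-start state)
    l_init_ratio_rv: float = 1.059
    p_lv_init: float = 14.1          # initial cavity pressures, mmHg
    p_rv_init: float = 10.7

    def validate(self) -> None:
        if self.k_lv <= 0 or self.k_rv <= 0:
            raise ValidationError("cavity: k_lv and k_rv must be > 0")
        if self.v_c0_lv <= 0 or self.v_c0_rv <= 0:
            raise ValidationError("cavity: v_c0 must be > 0")


@dataclass
class EngineParams:
    dt: float = 0.5
    n_cycles: int = 15
    n_transient: int = 5
    first_beat_at: float = 20.0
    ecg_sample_period: float = 1.0

    def validate(self) -> None:
        if not (0 < self.dt <= 1.0):
            raise ValidationError(f"engine.dt = {self.dt} must be in (0, 1] ms")
        if self.n_cycles < 1:
            raise ValidationError("engine.n_cycles must be >= 1")
        if not (0 <= self.n_transient < self.n_cycles):
            raise ValidationError("engine.n_transient must be in [0, n_cycles)")


@dataclass
class ModelConfig:
    """Validated, fully-defaulted model description."""

    conduction: dict[str, Any] = field(default_factory=dict)
    segments: dict[str, SegmentParams] = field(default_factory=default_segment_params)
    atria: dict[str, AtriumParams] = field(default_factory=lambda: dict(DEFAULT_ATRIA))
    atria_v_init: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATRIAL_V_INIT)
    )
    cavity: CavityParams = field(default_factory=CavityParams)
    circulation: CirculationParams = field(default_factory=CirculationParams)
    engine: EngineParams = field(default_factory=EngineParams)

    @property
    def rr(self) -> float:
        return float(self.conduction.get("rr", 1000.0))

    def validate(self) -> "ModelConfig":
        for name, p in self.segments.items():
            p.validate()
        missing = [s for s in ALL_SEGMENTS if s not in self.segments]
        if missing:
            raise ValidationError(f"mechanics.segments: missing segments {missing}")
        for a in self.atria.values():
            a.validate()
        self.cavity.validate()
        self.circulation.validate()
        self.engine.validate()
        return self

    def with_overrides(self, raw: Mapping[str, Any]) -> "ModelConfig":
        """Return a new config with the raw-dict overrides applied."""
        return _apply_raw(self, raw)


def _section(raw: Mapping, key: str) -> Mapping:
    val = raw.get(key) or {}
    if not isinstance(val, Mapping):
        raise ValidationError(f"config section {key!r} must be a mapping")
    return val


def _apply_raw(base: ModelConfig, raw: Mapping[str, Any]) -> ModelConfig:
    known = {"conduction", "mechanics", "cavity", "circulation", "engine"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")

    conduction = {**base.conduction, **dict(_section(raw, "conduction"))}

    mech = _section(raw, "mechanics")
    segments = dict(base.segments)
    for name, over in (mech.get("segments") or {}).items():
        try:
            canon = normalize_segment_name(name)
        except KeyError as e:
            raise ValidationError(f"mechanics.segments: {e.args[0]}") from None
        try:
            segments[canon] = replace(segments[canon], **dict(over))
        except TypeError as e:
            raise ValidationError(f"mechanics.segments.{canon}: {e}") from None
    atria = dict(base.atria)
    for aname, over in (mech.get("atria") or {}).items():
        if aname not in ("RA", "LA"):
            raise ValidationError(f"mechanics.atria: unknown atrium {aname!r}")
        try:
            atria[aname] = replace(atria[aname], **dict(over))
        except TypeError as e:
            raise ValidationError(f"mechanics.atria.{aname}: {e}") from None

    cav = _section(raw, "cavity")
    try:
        cavity = replace(base.cavity, **dict(cav))
    except TypeError as e:
        raise ValidationError(f"cavity: {e}") from None

    circ_raw = _section(raw, "circulation")
    chambers = {k: replace(v) for k, v in base.circulation.chambers.items()}
    for cname, over in (circ_raw.get("chambers") or {}).items():
        if cname not in chambers:
            raise ValidationError(f"circulation.chambers: unknown chamber {cname!r}")
        over = dict(over)
        v_init = over.pop("v_init", None)
        try:
            chambers[cname] = replace(chambers[cname], **over)
        except TypeError as e:
            raise ValidationError(f"circulation.chambers.{cname}: {e}") from None
        if v_init is not None:
            chambers[cname].v = float(v_init)
    links = dict(base.circulation.links)
    for lname, r in (circ_raw.get("links") or {}).items():
        if lname not in links:
            raise ValidationError(f"circulation.links: unknown link {lname!r}")
        links[lname] = replace(links[lname], r=float(r))
    valves = dict(base.circulation.valves)
    for vname, r in (circ_raw.get("valves") or {}).items():
        if vname not in valves:
            raise ValidationError(f"circulation.valves: unknown valve {vname!r}")
        valves[vname] = replace(valves[vname], r_open=float(r))
    circulation = CirculationParams(chambers=chambers, links=links, valves=valves)

    eng = _section(raw, "engine")
    try:
        engine = replace(base.engine, **dict(eng))
    except TypeError as e:
        raise ValidationError(f"engine: {e}") from None

    cfg = ModelConfig(
        conduction=conduction,
        segments=segments,
        atria=atria,
        atria_v_init=dict(base.atria_v_init),
        cavity=cavity,
        circulation=circulation,
        engine=engine,
    )
    return cfg.validate()


def load_config(path_or_dict: str | Path | Mapping | None = None) -> ModelConfig:
    """Load a config file (YAML/JSON), merge over defaults, and validate.

    ``None`` or an empty file yields the shipped baseline configuration.
    """
    if path_or_dict is None:
        return ModelConfig().validate()
    if isinstance(path_or_dict, Mapping):
        raw = path_or_dict
    else:
        path = Path(path_or_dict)
        if not path.exists():
            raise ValidationError(f"config file not found: {path}")
        text = path.read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise ValidationError(f"cannot parse config {path}: {e}") from None
        if raw is None:
            raw = {}
        if not isinstance(raw, Mapping):
            raise ValidationError(f"config root in {path} must be a mapping")
    return ModelConfig().with_overrides(raw)
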