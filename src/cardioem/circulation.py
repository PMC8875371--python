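"""Lumped-parameter closed-loop systemic and pulmonary circulation.

Each vascular chamber relates pressure to volume through a linear
elastance, P = e (V - V0). Flow between chambers follows the pressure
gradient across a resistance; the four cardiac valves are perfect diodes
(conducting through a small open resistance only down their gradient, with
no regurgitation).

Loop topology: LV -> aorta -> systemic arteries -> systemic veins ->
vena cava -> RA -> RV -> pulmonary artery -> (capillary resistance) ->
pulmonary veins -> LA -> LV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

CHAMBER_NAMES = ("ao", "sys_art", "sys_ven", "vc", "pa", "pu")


@dataclass
class ComplianceChamber:
    """Linear-elastance chamber: P = e (v - v0)."""

    name: str
    e: float      # elastance, mmHg/mL
    v0: float     # unstressed volume, mL
    v: float = 0.0  # current volume, mL

    def validate(self) -> None:
        if self.e <= 0:
            raise ValidationError(f"chamber {self.name}: elastance {self.e} must be > 0")
        if self.v < 0:
            raise ValidationError(f"chamber {self.name}: volume {self.v} must be >= 0")


def chamber_pressure(chamber: ComplianceChamber):
    """P = e (v - v0), mmHg."""
    return chamber.e * (chamber.v - chamber.v0)


@dataclass(frozen=True)
class ResistiveLink:
    """Bidirectional resistive connection between two chambers."""

    src: str
    dst: str
    r: float  # mmHg s/mL

    def validate(self) -> None:
        if self.r <= 0:
            raise ValidationError(f"link {self.src}->{self.dst}: r must be > 0")


def link_flow(p_up, p_down, r: float):
    """q = (p_up - p_down) / r, mL/s (bidirectional)."""
    if r <= 0:
        raise ValidationError(f"link resistance {r} must be > 0")
    return (np.asarray(p_up, dtype=float) - p_down) / r


@dataclass(frozen=True)
class Valve:
    """Perfect-diode valve with open resistance r_open."""

    name: str
    r_open: float

    def validate(self) -> None:
        if self.r_open <= 0:
            raise ValidationError(f"valve {self.name}: r_open must be > 0")


def valve_flow(p_up, p_down, valve: Valve):
    """q = (p_up - p_down)/r_open when p_up > p_down, else exactly 0."""
    if valve.r_open <= 0:
        raise ValidationError(f"valve {valve.name}: r_open must be > 0")
    dp = np.asarray(p_up, dtype=float) - p_down
    return np.where(dp > 0.0, dp / valve.r_open, 0.0)


@dataclass
class CirculationParams:
    """Shipped baseline vascular bed.

    Elastances/resistances are calibrated once so the closed loop, coupled
    to the baseline heart, reproduces normal systemic pressures (aorta
    ~60-130 mmHg) and a ~5 L/min-class output at 60 bpm; the chambers'
    initial volumes below put the loop close to its limit cycle so short
    transients suffice.
    """

    chambers: dict[str, ComplianceChamber] = field(default_factory=lambda: {
        "ao": ComplianceChamber("ao", e=2.45, v0=60.0, v=88.7),
        "sys_art": ComplianceChamber("sys_art", e=4.9, v0=220.0, v=234.1),
        "sys_ven": ComplianceChamber("sys_ven", e=0.03, v0=2300.0, v=2970.4),
        "vc": ComplianceChamber("vc", e=0.06, v0=250.0, v=495.9),
        "pa": ComplianceChamber("pa", e=0.40, v0=50.0, v=102.7),
        "pu": ComplianceChamber("pu", e=0.08, v0=400.0, v=635.6),
    })
    links: dict[str, ResistiveLink] = field(default_factory=lambda: {
        "ao_sys_art": ResistiveLink("ao", "sys_art", 0.05),
        "sys_art_sys_ven": ResistiveLink("sys_art", "sys_ven", 1.40),
        "sys_ven_vc": ResistiveLink("sys_ven", "vc", 0.10),
        "vc_ra": ResistiveLink("vc", "RA", 0.06),
        "pa_pu": ResistiveLink("pa", "pu", 0.12),
        "pu_la": ResistiveLink("pu", "LA", 0.06),
    })
    valves: dict[str, Valve] = field(default_factory=lambda: {
        "mitral": Valve("mitral", 0.010),
        "aortic": Valve("aortic", 0.008),
        "tricuspid": Valve("tricuspid", 0.010),
        "pulmonary": Valve("pulmonary", 0.012),
    })

    def validate(self) -> None:
        for ch in self.chambers.values():
            ch.validate()
        for lk in self.links.values():
            lk.validate()
        for vv in self.valves.values():
            vv.validate()
        missing = [n for n in CHAMBER_NAMES if n not in self.chambers]
        if missing:
            raise ValidationError(f"missing circulation chambers: {missing}")
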