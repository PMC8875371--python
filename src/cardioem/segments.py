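"""Ventricular segment naming, ordering, and adjacency.

The left-ventricular wall follows the standardized AHA 16-segment scheme:
six basal segments, six mid-cavity segments, and four apical segments. The
right-ventricular wall is treated as three stacked layers (basal, median,
apical). Segment numbers 1-19 follow the conventional AHA numbering for the
LV plus 17-19 for the RV layers.

Wall groups used throughout the package (septal and lateral, five segments
each) are the standard groupings used when septal and lateral strain curves
are averaged from apical echocardiographic views.
"""

from __future__ import annotations

# --- canonical segment names, in AHA numbering order -----------------------

LV_SEGMENTS: tuple[str, ...] = (
    "basal_anterior",        # 1
    "basal_anteroseptal",    # 2
    "basal_inferoseptal",    # 3
    "basal_inferior",        # 4
    "basal_inferolateral",   # 5
    "basal_anterolateral",   # 6
    "mid_anterior",          # 7
    "mid_anteroseptal",      # 8
    "mid_inferoseptal",      # 9
    "mid_inferior",          # 10
    "mid_inferolateral",     # 11
    "mid_anterolateral",     # 12
    "apical_anterior",       # 13
    "apical_septal",         # 14
    "apical_inferior",       # 15
    "apical_lateral",        # 16
)

RV_SEGMENTS: tuple[str, ...] = (
    "rv_basal",              # 17
    "rv_median",             # 18
    "rv_apical",             # 19
)

ALL_SEGMENTS: tuple[str, ...] = LV_SEGMENTS + RV_SEGMENTS

SEGMENT_NUMBER: dict[str, int] = {name: i + 1 for i, name in enumerate(ALL_SEGMENTS)}

#: Septal wall: the five septal segments averaged into the septal strain curve.
SEPTAL_WALL: tuple[str, ...] = (
    "apical_septal",
    "mid_inferoseptal",
    "basal_inferoseptal",
    "mid_anteroseptal",
    "basal_anteroseptal",
)

#: Lateral wall: the five lateral segments averaged into the lateral strain curve.
LATERAL_WALL: tuple[str, ...] = (
    "apical_lateral",
    "mid_inferolateral",
    "basal_inferolateral",
    "mid_anterolateral",
    "basal_anterolateral",
)

#: Remaining LV free-wall segments (anterior/inferior, not in either wall group).
OTHER_LV: tuple[str, ...] = tuple(
    s for s in LV_SEGMENTS if s not in SEPTAL_WALL and s not in LATERAL_WALL
)

#: LV segments loaded by the trans-septal pressure gradient rather than LV
#: pressure alone (the septum separates the two cavities).
SEPTAL_SEGMENTS: tuple[str, ...] = tuple(SEPTAL_WALL)

_BASAL_RING = LV_SEGMENTS[0:6]
_MID_RING = LV_SEGMENTS[6:12]
_APICAL_RING = LV_SEGMENTS[12:16]


def _ring_pairs(ring: tuple[str, ...]) -> list[tuple[str, str]]:
    return [(ring[i], ring[(i + 1) % len(ring)]) for i in range(len(ring))]


def lv_adjacency() -> list[tuple[str, str]]:
    """Undirected adjacency between AHA LV segments.

    Circumferential neighbours within each ring, longitudinal neighbours
    between rings (basal<->mid on the same wall; each mid segment maps onto
    the apical segment of its quadrant).
    """
    pairs: list[tuple[str, str]] = []
    pairs += _ring_pairs(_BASAL_RING)
    pairs += _ring_pairs(_MID_RING)
    pairs += _ring_pairs(_APICAL_RING)
    # basal <-> mid, same wall
    pairs += [(b, m) for b, m in zip(_BASAL_RING, _MID_RING)]
    # mid -> apical quadrant mapping
    pairs += [
        ("mid_anterior", "apical_anterior"),
        ("mid_anteroseptal", "apical_septal"),
        ("mid_inferoseptal", "apical_septal"),
        ("mid_inferior", "apical_inferior"),
        ("mid_inferolateral", "apical_lateral"),
        ("mid_anterolateral", "apical_lateral"),
    ]
    return pairs


def rv_adjacency() -> list[tuple[str, str]]:
    """RV layer stack plus trans-septal contact with the facing LV septum."""
    return [
        ("rv_basal", "rv_median"),
        ("rv_median", "rv_apical"),
        ("rv_basal", "basal_anteroseptal"),
        ("rv_basal", "basal_inferoseptal"),
        ("rv_median", "mid_anteroseptal"),
        ("rv_median", "mid_inferoseptal"),
        ("rv_apical", "apical_septal"),
    ]


def normalize_segment_name(name: str) -> str:
    """Map common spellings of AHA segment names onto the canonical names.

    Accepts e.g. ``"Basal Anteroseptal"``, ``"basal-anteroseptal"``,
    ``"ApS"``-free long forms, and the basal/mid/apical + wall word order
    used by echo vendors. Raises ``KeyError`` listing accepted names if the
    name cannot be resolved.
    """
    key = name.strip().lower().replace("-", "_").replace(" ", "_")
    key = key.replace("__", "_")
    aliases = {
        "apical_lat": "apical_lateral",
        "apical_sept": "apical_septal",
        "apical_septum": "apical_septal",
        "mid_septal": "mid_inferoseptal",
        "rv_base": "rv_basal",
        "rv_mid": "rv_median",
        "rv_medium": "rv_median",
        "rv_apex": "rv_apical",
    }
    key = aliases.get(key, key)
    if key not in SEGMENT_NUMBER:
        raise KeyError(
            f"unknown segment name {name!r}; accepted names: {', '.join(ALL_SEGMENTS)}"
        )
    return key
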