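"""Arena zone geometries for the behavioral assays.

All coordinates are millimetres with the origin at the arena centre,
x rightward and y upward.  Zones are shapely polygons; neighbouring zones
share boundaries but do not overlap.

Built-in arenas
---------------
``epm``
    Elevated plus maze: two open arms (250 x 50 mm) along the x axis, two
    closed arms (250 x 50 mm) along the y axis, and a 50 x 50 mm centre
    square at the junction.
``open_field``
    600 x 600 mm square with a central 300 x 300 mm ``center`` zone and the
    surrounding ``periphery``.
``two_chamber``
    500 x 400 mm box split into ``chamber_left`` and ``chamber_right``.
``three_chamber``
    500 x 400 mm box split into ``chamber_left``, ``chamber_center`` and
    ``chamber_right`` thirds.
"""

from __future__ import annotations

from shapely.geometry import Polygon, box

__all__ = [
    "EPM_ARM_LENGTH_MM",
    "EPM_ARM_WIDTH_MM",
    "make_arena",
    "ARENA_NAMES",
    "OPEN_ZONES",
    "CLOSED_ZONES",
]

EPM_ARM_LENGTH_MM = 250.0
EPM_ARM_WIDTH_MM = 50.0

OPEN_ZONES = ("open_arm_1", "open_arm_2")
CLOSED_ZONES = ("closed_arm_1", "closed_arm_2")


def _epm() -> dict[str, Polygon]:
    half = EPM_ARM_WIDTH_MM / 2.0
    far = half + EPM_ARM_LENGTH_MM
    return {
        "center": box(-half, -half, half, half),
        "open_arm_1": box(half, -half, far, half),     # +x
        "open_arm_2": box(-far, -half, -half, half),   # -x
        "closed_arm_1": box(-half, half, half, far),   # +y
        "closed_arm_2": box(-half, -far, half, -half),  # -y
    }


def _open_field(side_mm: float = 600.0, center_frac: float = 0.5) -> dict[str, Polygon]:
    h = side_mm / 2.0
    c = h * center_frac
    outer = box(-h, -h, h, h)
    center = box(-c, -c, c, c)
    return {"center": center, "periphery": outer.difference(center)}


def _chambers(n: int, length_mm: float = 500.0, width_mm: float = 400.0) -> dict[str, Polygon]:
    names = {
        2: ["chamber_left", "chamber_right"],
        3: ["chamber_left", "chamber_center", "chamber_right"],
    }[n]
    w = length_mm / n
    x0 = -length_mm / 2.0
    return {
        name: box(x0 + i * w, -width_mm / 2.0, x0 + (i + 1) * w, width_mm / 2.0)
        for i, name in enumerate(names)
    }


_BUILDERS = {
    "epm": _epm,
    "open_field": _open_field,
    "two_chamber": lambda: _chambers(2),
    "three_chamber": lambda: _chambers(3),
}

ARENA_NAMES = tuple(_BUILDERS)


def make_arena(name: str) -> dict[str, Polygon]:
    """Return the named arena as a dict of zone-name -> polygon.

    Raises
    ------
    ValueError
        If ``name`` is not a known arena.
    """
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise ValueError(f"unknown arena {name!r}; choose from {ARENA_NAMES}") from None
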