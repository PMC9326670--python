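"""The 20 construction elements: 5 shape families x 4 rotation orbits.

Every family is closed under 90-degree clockwise rotation about the centre
of the unit cell, so the rotation rule can act on any family.  Orbit ``k+1``
of a family is, by construction, orbit ``k`` rotated one step clockwise; the
geometry of orbits 1-3 is derived from orbit 0, which makes the closure
exact to floating-point rounding.

Element ids are ``family_id * 4 + orbit_index`` with ``family_id`` in 0-4
and ``orbit_index`` in 0-3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

N_FAMILIES = 5
ORBIT_LEN = 4
N_ELEMENTS = N_FAMILIES * ORBIT_LEN

CW = "CW"
CCW = "CCW"

Point = tuple[float, float]


@dataclass(frozen=True)
class Primitive:
    """One drawing primitive in the unit cell frame [0,1]^2.

    ``kind`` is one of ``segment``, ``polyline``, ``polygon``, ``arc``.
    For arcs, ``points`` holds (start, end) and ``radius``/``sweep``
    complete the circular-arc description.
    """

    kind: str
    points: tuple[Point, ...]
    radius: float | None = None
    sweep: int | None = None

    def __post_init__(self):
        if self.kind not in ("segment", "polyline", "polygon", "arc"):
            raise ValueError(f"unknown primitive kind {self.kind!r}")
        if self.kind == "arc" and (self.radius is None or self.sweep is None):
            raise ValueError("arc primitive requires radius and sweep")


@dataclass(frozen=True)
class GlyphElement:
    element_id: int
    family_id: int
    orbit_index: int
    geometry: tuple[Primitive, ...]


def rotate_point_cw(p: Point) -> Point:
    """Rotate a point 90 degrees clockwise (screen coords) about (0.5, 0.5)."""
    x, y = p
    return (1.0 - y, x)


def rotate_primitive_cw(prim: Primitive) -> Primitive:
    return Primitive(
        kind=prim.kind,
        points=tuple(rotate_point_cw(p) for p in prim.points),
        radius=prim.radius,
        sweep=prim.sweep,
    )


# Orbit-0 geometry per family.  Families: corner squares, edge bars,
# half-diagonal strokes, corner quarter-arcs, offset dots.
_FAMILY_SEEDS: tuple[tuple[Primitive, ...], ...] = (
    # family 0: small square in the top-left corner
    (
        Primitive(
            "polygon",
            ((0.06, 0.06), (0.26, 0.06), (0.26, 0.26), (0.06, 0.26)),
        ),
    ),
    # family 1: bar along the top edge
    (
        Primitive(
            "polygon",
            ((0.35, 0.04), (0.65, 0.04), (0.65, 0.12), (0.35, 0.12)),
        ),
    ),
    # family 2: stroke from the centre toward the top-left corner
    (Primitive("segment", ((0.5, 0.5), (0.14, 0.14))),),
    # family 3: quarter-arc spanning the top-left corner
    (
        Primitive(
            "arc",
            ((0.42, 0.06), (0.06, 0.42)),
            radius=0.36,
            sweep=0,
        ),
    ),
    # family 4: small diamond above the centre
    (
        Primitive(
            "polygon",
            ((0.5, 0.16), (0.56, 0.22), (0.5, 0.28), (0.44, 0.22)),
        ),
    ),
)


def _build_elements() -> tuple[GlyphElement, ...]:
    out: list[GlyphElement] = []
    for fam, seed_geometry in enumerate(_FAMILY_SEEDS):
        geometry = tuple(seed_geometry)
        for orbit in range(ORBIT_LEN):
            out.append(
                GlyphElement(
                    element_id=fam * ORBIT_LEN + orbit,
                    family_id=fam,
                    orbit_index=orbit,
                    geometry=geometry,
                )
            )
            geometry = tuple(rotate_primitive_cw(p) for p in geometry)
    return tuple(out)


ELEMENTS: tuple[GlyphElement, ...] = _build_elements()
ALL_ELEMENT_IDS: frozenset[int] = frozenset(range(N_ELEMENTS))


def family_of(element_id: int) -> int:
    if not 0 <= element_id < N_ELEMENTS:
        raise ValueError(f"element id {element_id} outside 0-{N_ELEMENTS - 1}")
    return element_id // ORBIT_LEN


def orbit_of(element_id: int) -> int:
    if not 0 <= element_id < N_ELEMENTS:
        raise ValueError(f"element id {element_id} outside 0-{N_ELEMENTS - 1}")
    return element_id % ORBIT_LEN


def family_members(family_id: int) -> frozenset[int]:
    if not 0 <= family_id < N_FAMILIES:
        raise ValueError(f"family id {family_id} outside 0-{N_FAMILIES - 1}")
    return frozenset(range(family_id * ORBIT_LEN, (family_id + 1) * ORBIT_LEN))


def rotate_element(element_id: int, direction: str = CW, steps: int = 1) -> int:
    """Advance an element ``steps`` positions along its family's orbit."""
    if direction not in (CW, CCW):
        raise ValueError(f"direction must be CW or CCW, got {direction!r}")
    fam = family_of(element_id)
    delta = steps if direction == CW else -steps
    return fam * ORBIT_LEN + (orbit_of(element_id) + delta) % ORBIT_LEN


def rotate_set(elements: Iterable[int], direction: str = CW, steps: int = 1) -> frozenset[int]:
    return frozenset(rotate_element(e, direction, steps) for e in elements)
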