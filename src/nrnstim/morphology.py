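"""SWC morphology parsing, validation and geometry.

An SWC file describes a digitally reconstructed neuron as a list of points
(id, type, x, y, z, radius, parent).  NEURON, by contrast, builds cells from
line *sections*: here each SWC point together with its parent defines one
section, grouped into per-compartment arrays (``soma[0..]``, ``axon[0..]``,
``basal[0..]``, ``apical[0..]``) in file order.

Lengths are measured between a point and its parent.  The default is the
planar (x, y) distance; full 3D distance is available via ``use_3d=True``
everywhere a length is computed.  Diameter of a section is twice the radius
of its defining point.  No repair of discontinuities is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "Compartment",
    "SwcPoint",
    "SegmentRef",
    "SectionGeometry",
    "Morphology",
    "SwcParseError",
    "SwcStructureError",
    "parse_swc",
    "write_swc",
    "section_geometry",
    "euclidean_distance",
    "branch_points",
    "segments_intersecting_line",
]

# SWC type codes for the four canonical compartments.
SWC_TYPE_CODES = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
COMPARTMENT_CODES = {v: k for k, v in SWC_TYPE_CODES.items()}


class Compartment(str, Enum):
    soma = "soma"
    axon = "axon"
    basal = "basal"
    apical = "apical"

    @property
    def code(self) -> int:
        return COMPARTMENT_CODES[self.value]


class SwcParseError(ValueError):
    """A line of SWC text could not be parsed (names the line number)."""


class SwcStructureError(ValueError):
    """The SWC point list violates structural invariants (ids, parents)."""


@dataclass(frozen=True)
class SwcPoint:
    """One SWC record: a point of the reconstruction."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def compartment(self) -> Compartment | None:
        name = SWC_TYPE_CODES.get(self.type_code)
        return Compartment(name) if name is not None else None

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class SegmentRef:
    """Reference to one section: compartment, 0-based index, position in [0,1]."""

    compartment: Compartment
    index: int
    position: float = 0.5

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"section index must be >= 0, got {self.index}")
        if not (0.0 <= self.position <= 1.0):
            raise ValueError(f"position must be in [0, 1], got {self.position}")


@dataclass(frozen=True)
class SectionGeometry:
    length: float  # um
    diameter: float  # um


class Morphology:
    """Parsed SWC morphology: ordered points, per-type counts, child graph.

    ``sections[compartment]`` lists point ids of that compartment in file
    order; position in that list is the section index used by
    :class:`SegmentRef` and by the generated hoc arrays.
    """

    def __init__(self, points: list[SwcPoint], warnings: list[str] | None = None):
        self.points: list[SwcPoint] = list(points)
        self.warnings: list[str] = list(warnings or [])
        self._by_id: dict[int, SwcPoint] = {}
        self.children: dict[int, list[int]] = {}
        self.sections: dict[Compartment, list[int]] = {c: [] for c in Compartment}
        self._ref_of_id: dict[int, SegmentRef] = {}
        for p in self.points:
            if p.id in self._by_id:
                raise SwcStructureError(f"duplicate id {p.id}")
            if p.parent_id != -1 and p.parent_id not in self._by_id:
                raise SwcStructureError(
                    f"point {p.id} references parent {p.parent_id} "
                    "which does not appear earlier in the file"
                )
            self._by_id[p.id] = p
            self.children.setdefault(p.id, [])
            if p.parent_id != -1:
                self.children[p.parent_id].append(p.id)
            comp = p.compartment
            if comp is not None:
                self._ref_of_id[p.id] = SegmentRef(comp, len(self.sections[comp]))
                self.sections[comp].append(p.id)

    @property
    def counts(self) -> dict[str, int]:
        return {c.value: len(ids) for c, ids in self.sections.items()}

    def point(self, point_id: int) -> SwcPoint:
        try:
            return self._by_id[point_id]
        except KeyError:
            raise SwcStructureError(f"no point with id {point_id}") from None

    def point_of_ref(self, ref: SegmentRef) -> SwcPoint:
        ids = self.sections[Compartment(ref.compartment)]
        if ref.index >= len(ids):
            raise LookupError(
                f"{ref.compartment.value}[{ref.index}] out of range "
                f"(only {len(ids)} sections)"
            )
        return self._by_id[ids[ref.index]]

    def ref_of_id(self, point_id: int) -> SegmentRef:
        self.point(point_id)
        try:
            return self._ref_of_id[point_id]
        except KeyError:
            raise LookupError(f"point {point_id} has no canonical compartment") from None

    def parent_of(self, p: SwcPoint) -> SwcPoint | None:
        return None if p.parent_id == -1 else self._by_id[p.parent_id]

    def iter_refs(self, compartments: Iterable[Compartment] | None = None):
        comps = list(compartments) if compartments is not None else list(Compartment)
        for c in comps:
            for i in range(len(self.sections[Compartment(c)])):
                yield SegmentRef(Compartment(c), i)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Morphology) and self.points == other.points

    def __repr__(self) -> str:
        return f"<Morphology {len(self.points)} points {self.counts}>"


def parse_swc(text: str) -> Morphology:
    """Parse SWC text into a :class:`Morphology`.

    Lines starting with ``#`` and blank lines are skipped.  Each data line
    must have exactly 7 whitespace-separated fields.  Points with a type code
    outside {1, 2, 3, 4} are retained but flagged in ``warnings``, as are
    non-positive radii.
    """
    points: list[SwcPoint] = []
    warnings: list[str] = []
    if not text.strip():
        raise SwcParseError("empty SWC text")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SwcParseError(
                f"line {lineno}: expected 7 fields, got {len(fields)}"
            )
        try:
            pid = int(fields[0])
            type_code = int(fields[1])
            x, y, z, radius = (float(v) for v in fields[2:6])
            parent = int(fields[6])
        except ValueError as exc:
            raise SwcParseError(f"line {lineno}: non-numeric field ({exc})") from None
        if type_code not in SWC_TYPE_CODES:
            warnings.append(
                f"line {lineno}: point {pid} has unassigned type code {type_code}"
            )
        if radius <= 0:
            warnings.append(f"line {lineno}: point {pid} has non-positive radius")
        points.append(SwcPoint(pid, type_code, x, y, z, radius, parent))
    return Morphology(points, warnings)


def _fmt(v: float) -> str:
    return format(v, ".10g")


def write_swc(m: Morphology) -> str:
    """Serialize a morphology back to SWC text (round-trips with parse_swc)."""
    lines = [
        f"{p.id} {p.type_code} {_fmt(p.x)} {_fmt(p.y)} {_fmt(p.z)} "
        f"{_fmt(p.radius)} {p.parent_id}"
        for p in m.points
    ]
    return "\n".join(lines) + "\n"


def section_geometry(
    point: SwcPoint, parent: SwcPoint | None, use_3d: bool = False
) -> SectionGeometry:
    """Length and diameter of the section defined by ``point`` and its parent.

    Length is the planar (x, y) distance by default; ``use_3d=True`` includes
    z.  Diameter is twice the point's radius.  A root point (``parent`` None)
    uses the sphere-equivalent convention length = diameter = 2*radius.
    """
    diam = 2.0 * point.radius
    if parent is None:
        return SectionGeometry(length=diam, diameter=diam)
    dx, dy = point.x - parent.x, point.y - parent.y
    if use_3d:
        length = math.sqrt(dx * dx + dy * dy + (point.z - parent.z) ** 2)
    else:
        length = math.hypot(dx, dy)
    return SectionGeometry(length=length, diameter=diam)


def euclidean_distance(m: Morphology, a: SegmentRef, b: SegmentRef) -> float:
    """Straight-line 3D distance (um) between two sections' own SWC points."""
    pa, pb = m.point_of_ref(a), m.point_of_ref(b)
    return math.dist(pa.xyz, pb.xyz)


def branch_points(m: Morphology) -> list[int]:
    """Ids of points whose parent id is non-sequential (and not the root)."""
    return [
        p.id
        for p in m.points
        if p.parent_id != -1 and p.parent_id != p.id - 1
    ]


def _orient(ax, ay, bx, by, cx, cy) -> float:
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


def _on_segment(ax, ay, bx, by, px, py) -> bool:
    return (
        min(ax, bx) - 1e-12 <= px <= max(ax, bx) + 1e-12
        and min(ay, by) - 1e-12 <= py <= max(ay, by) + 1e-12
    )


def _segments_intersect(p1, p2, q1, q2) -> bool:
    """Finite 2D segment intersection; collinear overlap counts as a hit."""
    o1 = _orient(*p1, *p2, *q1)
    o2 = _orient(*p1, *p2, *q2)
    o3 = _orient(*q1, *q2, *p1)
    o4 = _orient(*q1, *q2, *p2)
    if ((o1 > 0) != (o2 > 0) and o1 != 0 and o2 != 0) and (
        (o3 > 0) != (o4 > 0) and o3 != 0 and o4 != 0
    ):
        return True
    # Collinear / endpoint-touching cases.
    for (a, b, p) in ((p1, p2, q1), (p1, p2, q2), (q1, q2, p1), (q1, q2, p2)):
        if _orient(*a, *b, *p) == 0 and _on_segment(*a, *b, *p):
            return True
    return False


def segments_intersecting_line(
    m: Morphology,
    p1: tuple[float, float],
    p2: tuple[float, float],
) -> list[SegmentRef]:
    """Sections whose 2D (x, y) projection intersects the probe segment p1-p2.

    A section is the chord from a point to its parent; root points and
    zero-length chords never intersect.  Collinear overlap counts.
    """
    if p1 == p2:
        raise ValueError("probe endpoints must differ")
    hits: list[SegmentRef] = []
    for p in m.points:
        parent = m.parent_of(p)
        if parent is None or p.compartment is None:
            continue
        a = (p.x, p.y)
        b = (parent.x, parent.y)
        if a == b:
            continue  # degenerate section: never intersects by convention
        if _segments_intersect(a, b, p1, p2):
            hits.append(m.ref_of_id(p.id))
    return hits
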