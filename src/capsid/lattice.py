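"""Quasi-equivalent capsid lattices for ssRNA-phage coat proteins.

Builds explicit polyhedral cages of pentamer/hexamer sites for the capsid
forms observed in Qβ: icosahedral (T = h² + hk + k²), 5-fold elongated
prolate/oblate (caps of triangulation number T joined by a tube whose
elongation number Q counts the lattice area of the body facets), and the
D3-symmetric small prolate built from two T = 1 caps joined by rings of six
hexamers.  Every cage carries capsomer sites, dimer edges (classified A/B or
C/C), triangular facets, and per-coat-protein pseudo-subunit frames, plus a
2D unwrapping into a planar net.

Construction strategy: a cage is a triangulated sphere whose vertices are
capsomers.  For icosahedral and 5-fold forms the cage is generated by laying
hexagonal-lattice tiles onto the faces of an underlying polyhedron
(icosahedron, or the two pentagonal caps plus ten elongated body triangles of
a 5-fold prolate); because each 3D face is congruent to its lattice tile,
capsomer adjacency is recovered metrically and then audited combinatorially
(exactly 12 pentamers, degrees 5/6, V − E + F = 2).  The D3 form is wired
combinatorially from two 4-facet caps and hexamer rings, and audited the same
way.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from math import gcd, sqrt

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger("capsid.lattice")

# geometry of the axial hexagonal lattice: basis a1=(1,0), a2=(1/2, √3/2)
_AXIAL = np.array([[1.0, 0.0], [0.5, sqrt(3.0) / 2.0]])

#: fraction of the site→edge-midpoint vector at which a CP subunit sits
SUBUNIT_INSET = 0.35

#: merge tolerance for capsomer points shared between polyhedron faces
_MERGE_TOL = 1e-6

#: capsomer pairs closer than this (in lattice units) are adjacent; within a
#: face the spacing is exactly 1, folds only shorten it, and the nearest
#: non-adjacent pair on any supported form is > 1.4
_ADJ_THRESHOLD = 1.2

ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII"]


def _cart(p) -> np.ndarray:
    """Axial lattice coordinates -> Cartesian 2D."""
    return np.asarray(p, dtype=float) @ _AXIAL


def _cross(u, v) -> int:
    """Lattice area (in unit triangles) of the triangle (0, u, v), signed."""
    return u[0] * v[1] - u[1] * v[0]


def _rot60(u):
    return (-u[1], u[0] + u[1])


def _rot_minus60(u):
    return (u[0] + u[1], -u[0])


def _ccw(verts, triple, center=None):
    """Order a face triple counterclockwise as seen from outside."""
    p0, p1, p2 = (np.asarray(verts[i]) for i in triple)
    centroid = (p0 + p1 + p2) / 3.0
    out = centroid - (center if center is not None else 0.0)
    if np.dot(np.cross(p1 - p0, p2 - p0), out) < 0:
        return (triple[0], triple[2], triple[1])
    return triple


def is_triangulation_number(T: int) -> bool:
    return hk_from_T(T) is not None


def hk_from_T(T: int):
    """Canonical (h, k), h ≥ k ≥ 0, with h²+hk+k² = T; None if T is invalid."""
    if T < 1:
        return None
    for k in range(int(sqrt(T)) + 1):
        for h in range(k, int(sqrt(T)) + 1):
            if h * h + h * k + k * k == T:
                return (h, k)
    return None


def nearest_triangulation_numbers(T: int, n: int = 4) -> list[int]:
    out = []
    for cand in sorted(range(1, max(2 * T + 4, 16)), key=lambda c: (abs(c - T), c)):
        if hk_from_T(cand) is not None:
            out.append(cand)
        if len(out) >= n:
            break
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CapsidArchitecture:
    """Symbolic descriptor of a capsid form.

    symmetry_class is one of ``icosahedral``, ``elongated_5fold``,
    ``elongated_3fold``.  T is the cap triangulation number; Q the 5-fold
    elongation number (present iff 5-fold elongated); Q1/Q2 the 3-fold
    elongation numbers (present iff 3-fold elongated).
    """

    symmetry_class: str
    T: int
    Q: int | None = None
    Q1: int | None = None
    Q2: int | None = None
    name: str = ""

    def __post_init__(self):
        if self.symmetry_class not in ("icosahedral", "elongated_5fold", "elongated_3fold"):
            raise ValueError(f"unknown symmetry class {self.symmetry_class!r}")
        if hk_from_T(self.T) is None:
            raise ValueError(
                f"T={self.T} is not a triangulation number (h²+hk+k²); "
                f"nearest valid values: {nearest_triangulation_numbers(self.T)}"
            )
        if (self.Q is not None) != (self.symmetry_class == "elongated_5fold"):
            raise ValueError("Q must be present exactly for 5-fold elongated forms")
        has_q12 = self.Q1 is not None and self.Q2 is not None
        if has_q12 != (self.symmetry_class == "elongated_3fold"):
            raise ValueError("Q1/Q2 must be present exactly for 3-fold elongated forms")

    def label(self) -> str:
        if self.name:
            return self.name
        if self.symmetry_class == "icosahedral":
            return f"T={self.T}"
        if self.symmetry_class == "elongated_5fold":
            return f"5-fold T={self.T} Q={self.Q}"
        return f"3-fold T={self.T} Q1={self.Q1} Q2={self.Q2}"


@dataclass
class Site:
    """One capsomer: a pentamer or hexamer of coat proteins."""

    id: int
    position: np.ndarray
    kind: str  # "pentamer" | "hexamer"
    zone: str  # "cap_north" | "tube" | "cap_south" | "equator"


@dataclass
class Edge:
    """Adjacency between two capsomers; carries exactly one CP dimer."""

    id: int
    site_a: int
    site_b: int
    dimer_class: str  # "A/B" | "C/C"
    subunits: tuple[int, int] = (0, 0)


@dataclass
class SubunitPlacement:
    """Pseudo coat-protein frame: origin plus orthonormal triad.

    Each subunit belongs to one capsomer and sits on one dimer edge; the
    quasi-equivalence label is A (pentamer side of a mixed dimer), B (hexamer
    side, or the partner of an A in a pentamer-pentamer contact) or C
    (either half of a hexamer-hexamer dimer).
    """

    id: int
    site: int
    edge: int
    origin: np.ndarray
    triad: np.ndarray  # rows: x (toward partner), y (in-surface), z (outward)
    label: str  # "A" | "B" | "C"


@dataclass
class Composition:
    n_cp: int
    n_pentamer: int
    n_hexamer: int
    n_dimer_total: int
    n_dimer_AB: int
    n_dimer_CC: int
    n_dimer_capsid_after_mat: int | None = None
    n_dimer_with_internal: int | None = None


@dataclass
class LatticeCage:
    """Explicit polyhedral cage of capsomers with dimer edges and facets."""

    architecture: CapsidArchitecture
    sites: list[Site]
    edges: list[Edge]
    facets: list[tuple[int, int, int]]
    subunit_placements: list[SubunitPlacement]
    surface: dict = field(default_factory=dict)

    # -- counts ------------------------------------------------------------
    @property
    def n_pentamer(self) -> int:
        return sum(1 for s in self.sites if s.kind == "pentamer")

    @property
    def n_hexamer(self) -> int:
        return sum(1 for s in self.sites if s.kind == "hexamer")

    @property
    def n_cp(self) -> int:
        return len(self.subunit_placements)

    def neighbors(self, site_id: int) -> list[int]:
        out = []
        for e in self.edges:
            if e.site_a == site_id:
                out.append(e.site_b)
            elif e.site_b == site_id:
                out.append(e.site_a)
        return out

    def site_edges(self, site_id: int) -> list[Edge]:
        return [e for e in self.edges if site_id in (e.site_a, e.site_b)]

    def hexamer_subunits(self, site_id: int) -> list[SubunitPlacement]:
        return [p for p in self.subunit_placements if p.site == site_id]

    # -- serialization -----------------------------------------------------
    def to_json_dict(self) -> dict:
        a = self.architecture
        return {
            "architecture": {
                "symmetry_class": a.symmetry_class,
                "T": a.T,
                "Q": a.Q,
                "Q1": a.Q1,
                "Q2": a.Q2,
                "name": a.name,
            },
            "surface": self.surface,
            "sites": [
                {
                    "id": s.id,
                    "position": [float(x) for x in s.position],
                    "kind": s.kind,
                    "zone": s.zone,
                }
                for s in self.sites
            ],
            "edges": [
                {
                    "id": e.id,
                    "site_a": e.site_a,
                    "site_b": e.site_b,
                    "dimer_class": e.dimer_class,
                    "subunits": list(e.subunits),
                }
                for e in self.edges
            ],
            "facets": [list(f) for f in self.facets],
            "subunit_placements": [
                {
                    "id": p.id,
                    "site": p.site,
                    "edge": p.edge,
                    "origin": [float(x) for x in p.origin],
                    "triad": [[float(x) for x in row] for row in p.triad],
                    "label": p.label,
                }
                for p in self.subunit_placements
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def from_json_dict(cls, d: dict) -> "LatticeCage":
        a = d["architecture"]
        arch = CapsidArchitecture(
            symmetry_class=a["symmetry_class"],
            T=a["T"],
            Q=a.get("Q"),
            Q1=a.get("Q1"),
            Q2=a.get("Q2"),
            name=a.get("name", ""),
        )
        sites = [
            Site(s["id"], np.array(s["position"]), s["kind"], s["zone"]) for s in d["sites"]
        ]
        edges = [
            Edge(e["id"], e["site_a"], e["site_b"], e["dimer_class"], tuple(e["subunits"]))
            for e in d["edges"]
        ]
        facets = [tuple(f) for f in d["facets"]]
        placements = [
            SubunitPlacement(
                p["id"], p["site"], p["edge"], np.array(p["origin"]), np.array(p["triad"]), p["label"]
            )
            for p in d["subunit_placements"]
        ]
        return cls(arch, sites, edges, facets, placements, d.get("surface", {}))

    @classmethod
    def from_json(cls, path) -> "LatticeCage":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# generic assembly from tiled polyhedron faces
# ---------------------------------------------------------------------------


def _tile_points(l0, l1, l2):
    """Integer axial points inside or on the lattice triangle (l0, l1, l2)."""
    c0, c1, c2 = _cart(l0), _cart(l1), _cart(l2)
    M = np.column_stack([c1 - c0, c2 - c0])
    Minv = np.linalg.inv(M)
    lo = np.floor(np.min([l0, l1, l2], axis=0)).astype(int)
    hi = np.ceil(np.max([l0, l1, l2], axis=0)).astype(int)
    eps = 1e-9
    pts = []
    for i in range(lo[0], hi[0] + 1):
        for j in range(lo[1], hi[1] + 1):
            lam = Minv @ (_cart((i, j)) - c0)
            if lam[0] >= -eps and lam[1] >= -eps and lam[0] + lam[1] <= 1 + eps:
                pts.append(((i, j), lam))
    return pts


def _assemble_from_faces(arch, faces, poly_vertices, surface):
    """Merge per-face lattice points into a cage; faces are congruent to
    their lattice tiles so adjacency is metric (spacing 1)."""
    key_of = {}
    positions = []

    def intern(p3):
        key = tuple(np.round(np.asarray(p3) / _MERGE_TOL).astype(np.int64))
        if key not in key_of:
            key_of[key] = len(positions)
            positions.append(np.asarray(p3, dtype=float))
        return key_of[key]

    vertex_ids = set()
    for v in poly_vertices:
        vertex_ids.add(intern(v))

    for (P0, P1, P2), (l0, l1, l2) in faces:
        P0, P1, P2 = map(np.asarray, (P0, P1, P2))
        for _, lam in _tile_points(l0, l1, l2):
            p3 = P0 + lam[0] * (P1 - P0) + lam[1] * (P2 - P0)
            intern(p3)

    pos = np.array(positions)
    tree = cKDTree(pos)
    pairs = sorted(tree.query_pairs(_ADJ_THRESHOLD))
    adjacency = {i: set() for i in range(len(pos))}
    for a, b in pairs:
        adjacency[a].add(b)
        adjacency[b].add(a)
    kinds = ["pentamer" if i in vertex_ids else "hexamer" for i in range(len(pos))]
    return _finalize_cage(arch, pos, kinds, adjacency, surface)


def _finalize_cage(arch, pos, kinds, adjacency, surface):
    n = len(pos)
    n_pent = kinds.count("pentamer")
    if n_pent != 12:
        raise RuntimeError(f"cage audit failed: {n_pent} pentamers (expected 12)")
    for i in range(n):
        want = 5 if kinds[i] == "pentamer" else 6
        if len(adjacency[i]) != want:
            raise RuntimeError(
                f"cage audit failed: site {i} ({kinds[i]}) has degree {len(adjacency[i])}"
            )
    edges_raw = sorted({(min(a, b), max(a, b)) for a in adjacency for b in adjacency[a]})
    n_e = len(edges_raw)
    # triangular facets = edges' common neighbors
    facets = set()
    for a, b in edges_raw:
        for c in adjacency[a] & adjacency[b]:
            facets.add(tuple(sorted((a, b, c))))
    facets = sorted(facets)
    if n - n_e + len(facets) != 2:
        raise RuntimeError(
            f"cage audit failed: Euler V-E+F = {n}-{n_e}+{len(facets)} != 2"
        )

    # zones
    zmax = pos[:, 2].max()
    zs = surface.get("ring_z", None)
    sites = []
    for i in range(n):
        z = pos[i][2]
        if abs(z) < 1e-6 * max(1.0, abs(zmax)):
            zone = "equator"
        elif zs is not None and zs[1] + 1e-9 < z < zs[0] - 1e-9:
            zone = "tube"
        elif z > 0:
            zone = "cap_north"
        else:
            zone = "cap_south"
        sites.append(Site(i, pos[i], kinds[i], zone))

    center = pos.mean(axis=0)
    edges = []
    placements = []
    for eid, (a, b) in enumerate(edges_raw):
        ka, kb = kinds[a], kinds[b]
        if ka == "pentamer" and kb == "pentamer":
            dclass, labels = "A/B", ("A", "B")
        elif ka == "hexamer" and kb == "hexamer":
            dclass, labels = "C/C", ("C", "C")
        else:
            dclass = "A/B"
            labels = ("A", "B") if ka == "pentamer" else ("B", "A")
        sub_ids = []
        for (site, other), lab in zip(((a, b), (b, a)), labels):
            mid = 0.5 * (pos[site] + pos[other])
            origin = pos[site] + SUBUNIT_INSET * (mid - pos[site])
            origin = _project_to_surface(origin, surface)
            x = mid - pos[site]
            zax = _outward_normal(origin, surface, center)
            x = x - np.dot(x, zax) * zax
            x /= np.linalg.norm(x)
            y = np.cross(zax, x)
            pid = len(placements)
            placements.append(
                SubunitPlacement(pid, site, eid, origin, np.array([x, y, zax]), lab)
            )
            sub_ids.append(pid)
        edges.append(Edge(eid, a, b, dclass, tuple(sub_ids)))

    # project capsomer sites onto the smooth surface
    for s in sites:
        s.position = _project_to_surface(s.position, surface)

    cage = LatticeCage(arch, sites, edges, facets, placements, surface)
    logger.info(
        "built %s: %d CP, %d pentamers, %d hexamers, %d dimers",
        arch.label(), cage.n_cp, cage.n_pentamer, cage.n_hexamer, len(edges),
    )
    return cage


def _project_to_surface(p, surface):
    """Radial projection onto the sphere / sphero-cylinder embedding."""
    p = np.asarray(p, dtype=float)
    kind = surface.get("kind")
    if kind == "sphere":
        r = surface["radius"]
        nrm = np.linalg.norm(p)
        return p * (r / nrm) if nrm > 0 else p
    if kind == "spherocylinder":
        z_hi, z_lo = surface["ring_z"]
        rho = surface["rho"]
        if z_lo <= p[2] <= z_hi:
            r2 = math.hypot(p[0], p[1])
            if r2 == 0:
                return p
            return np.array([p[0] * rho / r2, p[1] * rho / r2, p[2]])
        c = np.array([0.0, 0.0, surface["cap_center_north" if p[2] > z_hi else "cap_center_south"]])
        R = surface["cap_radius"]
        d = p - c
        return c + d * (R / np.linalg.norm(d))
    return p


def _outward_normal(p, surface, center):
    kind = surface.get("kind")
    if kind == "sphere":
        return p / np.linalg.norm(p)
    if kind == "spherocylinder":
        z_hi, z_lo = surface["ring_z"]
        if z_lo <= p[2] <= z_hi:
            n = np.array([p[0], p[1], 0.0])
        else:
            c = np.array(
                [0.0, 0.0, surface["cap_center_north" if p[2] > z_hi else "cap_center_south"]]
            )
            n = p - c
        return n / np.linalg.norm(n)
    n = p - center
    return n / np.linalg.norm(n)


# ---------------------------------------------------------------------------
# icosahedral builder
# ---------------------------------------------------------------------------


def _icosahedron_vertices(edge: float):
    """Vertices of an icosahedron with the given edge, 5-fold axis on z."""
    circ = edge / (4.0 / sqrt(10.0 + 2.0 * sqrt(5.0)))
    zr, rr = 1.0 / sqrt(5.0), 2.0 / sqrt(5.0)
    verts = [np.array([0.0, 0.0, 1.0])]
    for i in range(5):
        a = math.radians(72 * i)
        verts.append(np.array([rr * math.cos(a), rr * math.sin(a), zr]))
    for i in range(5):
        a = math.radians(72 * i + 36)
        verts.append(np.array([rr * math.cos(a), rr * math.sin(a), -zr]))
    verts.append(np.array([0.0, 0.0, -1.0]))
    return [v * circ for v in verts]


def _icosahedron_faces():
    N, S = 0, 11
    R = lambda i: 1 + (i % 5)
    Sv = lambda i: 6 + (i % 5)
    faces = []
    for i in range(5):
        faces.append((N, R(i), R(i + 1)))
        faces.append((R(i), R(i + 1), Sv(i)))
        faces.append((Sv(i), Sv(i + 1), R(i + 1)))
        faces.append((S, Sv(i), Sv(i + 1)))
    return faces


def build_icosahedral(T: int, radius: float | None = None) -> LatticeCage:
    """Caspar–Klug icosahedral cage: 60·T coat proteins, 12 pentamers,
    10·(T−1) hexamers."""
    hk = hk_from_T(T)
    if hk is None:
        raise ValueError(
            f"T={T} is not a triangulation number; nearest valid: "
            f"{nearest_triangulation_numbers(T)}"
        )
    arch = CapsidArchitecture("icosahedral", T, name=f"T={T}")
    C = hk
    tile = ((0, 0), C, _rot60(C))
    s = float(np.linalg.norm(_cart(C)))
    verts = _icosahedron_vertices(s)
    # consistent outward-CCW orientation keeps the (possibly chiral) lattice
    # glued coherently across every fold
    faces = [
        ((verts[a], verts[b], verts[c]), tile)
        for a, b, c in (_ccw(verts, f) for f in _icosahedron_faces())
    ]
    circ = float(np.linalg.norm(verts[0]))
    surface = {"kind": "sphere", "radius": circ}
    cage = _assemble_from_faces(arch, faces, verts, surface)
    if radius is not None:
        _rescale(cage, radius / circ)
    return cage


def _rescale(cage: LatticeCage, f: float) -> None:
    for s in cage.sites:
        s.position = s.position * f
    for p in cage.subunit_placements:
        p.origin = p.origin * f
    for k in ("radius", "rho", "cap_radius", "cap_center_north", "cap_center_south"):
        if k in cage.surface:
            cage.surface[k] = cage.surface[k] * f
    if "ring_z" in cage.surface:
        cage.surface["ring_z"] = [z * f for z in cage.surface["ring_z"]]


# ---------------------------------------------------------------------------
# 5-fold elongated (prolate / oblate) builder
# ---------------------------------------------------------------------------


def _body_offset_vector(C, Q, T):
    """Axial vector B to the southern pentamer ring in the unrolled tube
    strip: cross(C, B) = Q, reducing to rot60(C) when Q = T."""
    h, k = C
    g = gcd(h, k)
    n = Q - T
    if n % g != 0:
        raise ValueError(
            f"Q={Q} is incompatible with the cap lattice vector (h,k)=({h},{k}): "
            f"Q−T must be a multiple of gcd(h,k)={g}"
        )
    # u with cross(C,u) = h*u1 - k*u0 = g (extended Euclid)
    if h == 0:
        u = (-1, 0)
    else:
        # find x,y: h*y - k*x = g
        a, b = h, k
        # gcd(h,k): find s,t with h*s + k*t = g  ->  y=s, x=-t
        s, t = _ext_gcd(a, b)
        u = (-t, s)
    assert _cross(C, u) == g
    m = n // g
    # offset laid clockwise (cross(C,B) = −Q) so the tube strip shares the
    # caps' lattice handedness when all faces are oriented outward-CCW
    r = _rot_minus60(C)
    B = (r[0] - m * u[0], r[1] - m * u[1])
    # reduce the circumferential component modulo C (pure relabeling of the
    # southern ring) so each body facet pairs with its nearest ring vertex
    s2 = float(np.dot(_cart(C), _cart(C)))
    shift = math.floor(float(np.dot(_cart(B), _cart(C))) / s2)
    B = (B[0] - shift * C[0], B[1] - shift * C[1])
    assert _cross(C, B) == -Q
    return B


def _ext_gcd(a, b):
    if b == 0:
        return (1, 0)
    s, t = _ext_gcd(b, a % b)
    return (t, s - (a // b) * t)


def build_elongated_5fold(T: int, Q: int, radius: float | None = None) -> LatticeCage:
    """D5 cage with two T-caps joined by a 5-fold tube of elongation number Q:
    30·(T+Q) coat proteins.  Q > T is prolate, Q < T oblate, Q = T the
    icosahedral composition."""
    hk = hk_from_T(T)
    if hk is None:
        raise ValueError(
            f"T={T} is not a triangulation number; nearest valid: "
            f"{nearest_triangulation_numbers(T)}"
        )
    if Q < 1:
        raise ValueError("Q must be a positive integer")
    name = "prolate" if Q > T else ("oblate" if Q < T else "isometric")
    arch = CapsidArchitecture("elongated_5fold", T, Q=Q, name=f"{name} T={T} Q={Q}")
    C = hk
    B = _body_offset_vector(C, Q, T)
    s = float(np.linalg.norm(_cart(C)))
    L1 = float(np.linalg.norm(_cart(B)))
    L2 = float(np.linalg.norm(_cart(B) - _cart(C)))

    rho = s / (2.0 * math.sin(math.radians(36)))
    zN = sqrt(max(s * s - rho * rho, 0.0))
    # southern ring twist tau and axial drop d:
    #   2ρ²(1−cos τ) + d² = L1²;  2ρ²(1−cos(τ−72°)) + d² = L2²
    K = (L1 * L1 - L2 * L2) / (2.0 * rho * rho)
    c72, s72 = math.cos(math.radians(72)), math.sin(math.radians(72))
    A_, B_ = (c72 - 1.0), s72  # A cosτ + B sinτ = K
    Rab = math.hypot(A_, B_)
    if abs(K) > Rab + 1e-12:
        raise ValueError(f"(T={T}, Q={Q}) cannot close a 5-fold tube (ring equation)")
    phi = math.atan2(B_, A_)
    base = math.acos(max(-1.0, min(1.0, K / Rab)))
    # the unrolled strip predicts the twist: circumferential advance of B
    # over the 5-edge circumference (chord equations admit a mirror root)
    proj = float(np.dot(_cart(B), _cart(C))) / s
    tau_pred = 2.0 * math.pi * proj / (5.0 * s)
    candidates = []
    for cand in (phi + base, phi - base):
        d2 = L1 * L1 - 2.0 * rho * rho * (1.0 - math.cos(cand))
        if d2 > 1e-9:
            err = abs(math.remainder(cand - tau_pred, 2.0 * math.pi))
            candidates.append((err, cand % (2 * math.pi), sqrt(d2)))
    if not candidates:
        raise ValueError(f"(T={T}, Q={Q}) cannot close a 5-fold tube (no axial solution)")
    _, tau, d = min(candidates)

    def ring(z, a0):
        return [
            np.array([rho * math.cos(math.radians(72 * i) + a0),
                      rho * math.sin(math.radians(72 * i) + a0), z])
            for i in range(5)
        ]

    Rv = ring(0.0, 0.0)
    Sv = ring(-d, tau)
    Np = np.array([0.0, 0.0, zN])
    Sp = np.array([0.0, 0.0, -d - zN])
    verts = [Np] + Rv + Sv + [Sp]

    # all faces outward-CCW with CCW lattice tiles (cross(C,B) = −Q, so
    # (0, B, C) and (B, B+C, C) are CCW)
    cap_tile = ((0, 0), C, _rot60(C))
    up_tile = ((0, 0), B, C)
    dn_tile = (B, (B[0] + C[0], B[1] + C[1]), C)
    faces = []
    for i in range(5):
        j = (i + 1) % 5
        faces.append(((Np, Rv[i], Rv[j]), cap_tile))
        faces.append(((Sp, Sv[j], Sv[i]), cap_tile))
        faces.append(((Rv[i], Sv[i], Rv[j]), up_tile))
        faces.append(((Sv[i], Sv[j], Rv[j]), dn_tile))

    cap_c = (zN * zN - rho * rho) / (2.0 * zN)  # cap-sphere center (north)
    cap_R = zN - cap_c
    surface = {
        "kind": "spherocylinder",
        "rho": rho,
        "ring_z": [0.0, -d],
        "cap_center_north": cap_c,
        "cap_center_south": -d - cap_c,
        "cap_radius": cap_R,
    }
    cage = _assemble_from_faces(arch, faces, verts, surface)
    # recenter on the equator so zones/equator labels are symmetric
    shift = d / 2.0
    for s_ in cage.sites:
        s_.position = s_.position + np.array([0, 0, shift])
    for p in cage.subunit_placements:
        p.origin = p.origin + np.array([0, 0, shift])
    cage.surface["ring_z"] = [shift, -d + shift]
    cage.surface["cap_center_north"] += shift
    cage.surface["cap_center_south"] += shift
    _relabel_zones(cage)
    if radius is not None:
        _rescale(cage, radius / rho)
    return cage


def _relabel_zones(cage: LatticeCage) -> None:
    z_hi, z_lo = cage.surface.get("ring_z", (0.0, 0.0))
    span = max(abs(z_hi), abs(z_lo), 1.0)
    for s in cage.sites:
        z = s.position[2]
        if abs(z) < 1e-6 * span:
            s.zone = "equator"
        elif z_lo + 1e-9 < z < z_hi - 1e-9:
            s.zone = "tube"
        elif z > 0:
            s.zone = "cap_north"
        else:
            s.zone = "cap_south"


# ---------------------------------------------------------------------------
# 3-fold elongated (D3 small prolate) builder
# ---------------------------------------------------------------------------


def _glue_band(cycle_a, stubs_a, cycle_b, b_offset=0):
    """Triangulated band between two 6-cycles.

    ``stubs_a[i]`` crossing edges leave cycle_a vertex i; consecutive
    crossings share a vertex, so the band closes with 12 triangles.  Returns
    (crossing edges, triangles, stub counts induced on cycle_b).
    """
    assert sum(stubs_a) == 12 and len(cycle_a) == len(cycle_b) == 6
    crossings = []
    j = b_offset
    for i in range(6):
        for t in range(stubs_a[i]):
            crossings.append((cycle_a[i], cycle_b[j % 6]))
            if t < stubs_a[i] - 1:
                j += 1
    triangles = []
    for k in range(len(crossings)):
        (a1, b1) = crossings[k]
        (a2, b2) = crossings[(k + 1) % len(crossings)]
        if a1 == a2:
            triangles.append((a1, b1, b2))
        else:
            triangles.append((a1, a2, b1))
    stubs_b = {v: 0 for v in cycle_b}
    for _, b in crossings:
        stubs_b[b] += 1
    return crossings, triangles, [stubs_b[v] for v in cycle_b]


def build_elongated_3fold(T: int, Q1: int, Q2: int, radius: float | None = None) -> LatticeCage:
    """D3 cage: two T = 1 caps (6 pentamers each) joined by rings of six
    hexamers along the 3-fold axis.

    The published small prolate (T=1, Q1=2, Q2=3) has 132 coat proteins,
    12 pentamers and 12 hexamers; that composition is reproduced by two
    hexamer rings.  The elongation labels map to the ring count as
    r = Q1 + Q2 − 2T − 1, with Q1 = Q2 = T the degenerate icosahedron (r=0).
    """
    if hk_from_T(T) is None:
        raise ValueError(
            f"T={T} is not a triangulation number; nearest valid: "
            f"{nearest_triangulation_numbers(T)}"
        )
    if T != 1:
        raise ValueError(
            "3-fold elongated cages are constructed for T=1 caps (the observed "
            f"small-prolate architecture); got T={T}"
        )
    if Q1 < 1 or Q2 < 1:
        raise ValueError("Q1 and Q2 must be positive integers")
    arch = CapsidArchitecture(
        "elongated_3fold", T, Q1=Q1, Q2=Q2, name=f"small prolate T={T} Q1={Q1} Q2={Q2}"
    )
    if Q1 == T and Q2 == T:
        r = 0
    else:
        r = Q1 + Q2 - 2 * T - 1
        if r < 1:
            raise ValueError(
                f"(T,Q1,Q2)=({T},{Q1},{Q2}) cannot close a 3-fold elongated polyhedron"
            )

    # --- combinatorics ---------------------------------------------------
    # north cap: t0..t2 (top facet), r0..r2; boundary cycle alternates t,r
    ids = {}

    def new(name):
        ids[name] = len(ids)
        return ids[name]

    tn = [new(f"tn{i}") for i in range(3)]
    rn = [new(f"rn{i}") for i in range(3)]
    rings = [[new(f"h{j}_{k}") for k in range(6)] for j in range(r)]
    ts = [new(f"ts{i}") for i in range(3)]
    rs = [new(f"rs{i}") for i in range(3)]

    adjacency = {i: set() for i in range(len(ids))}

    def add_edge(a, b):
        adjacency[a].add(b)
        adjacency[b].add(a)

    def cap_edges(t, rr):
        for i in range(3):
            add_edge(t[i], t[(i + 1) % 3])
            add_edge(rr[i], t[i])
            add_edge(rr[i], t[(i + 1) % 3])

    cap_edges(tn, rn)
    cap_edges(ts, rs)
    north_cycle = [tn[0], rn[0], tn[1], rn[1], tn[2], rn[2]]
    south_cycle = [ts[0], rs[0], ts[1], rs[1], ts[2], rs[2]]
    cap_stubs = [1, 3, 1, 3, 1, 3]  # t pentamers take 1 belt edge, r take 3

    cycles = [north_cycle] + rings + [south_cycle]
    for ring in rings:
        for k in range(6):
            add_edge(ring[k], ring[(k + 1) % 6])

    stubs = cap_stubs
    all_triangles = []
    for lvl in range(len(cycles) - 1):
        a, b = cycles[lvl], cycles[lvl + 1]
        if lvl == len(cycles) - 2:
            # final interface: the induced stub counts must put 1 belt edge
            # on each southern t pentamer and 3 on each r; rotate the south
            # boundary into register
            for rot in range(6):
                cyc = south_cycle[rot:] + south_cycle[:rot]
                crossings, tris, sb = _glue_band(a, stubs, cyc)
                if all((sb[i] == 1) == (cyc[i] in ts) for i in range(6)):
                    break
            else:
                raise RuntimeError("3-fold belt closure failed")
        else:
            crossings, tris, sb = _glue_band(a, stubs, b)
            # next cycle's remaining stubs: ring vertices have degree 6 with
            # 2 ring edges, so the far side gets 4 − (near-side count)
            stubs = [4 - c for c in sb]
        for x, y in crossings:
            add_edge(x, y)
        all_triangles.extend(tris)

    # --- geometry ---------------------------------------------------------
    # icosahedron oriented with a 3-fold axis on z supplies the cap shapes
    iverts = _icosahedron_vertices(1.0)
    ifaces = _icosahedron_faces()
    f0 = ifaces[0]
    axis = sum(iverts[v] for v in f0) / 3.0
    axis /= np.linalg.norm(axis)
    Rm = _rotation_onto_z(axis)
    iv = [Rm @ v for v in iverts]
    north6 = sorted(range(12), key=lambda i: -iv[i][2])[:6]
    topz = sorted(north6, key=lambda i: -iv[i][2])
    top3, ring3 = topz[:3], topz[3:]
    top3 = sorted(top3, key=lambda i: math.atan2(iv[i][1], iv[i][0]))
    ring3 = sorted(ring3, key=lambda i: math.atan2(iv[i][1], iv[i][0]))

    dz_ring = sqrt(3.0) / 2.0
    belt_h = dz_ring * (r + 1)
    z_cut = (iv[top3[0]][2] + iv[ring3[0]][2]) / 2.0  # nominal boundary height
    pos = np.zeros((len(ids), 3))
    shift = belt_h / 2.0 - iv[ring3[0]][2]
    for i in range(3):
        pos[tn[i]] = iv[top3[i]] + [0, 0, shift]
        pos[rn[i]] = iv[ring3[i]] + [0, 0, shift]
        pos[ts[i]] = np.array([iv[top3[i]][0], -iv[top3[i]][1], -iv[top3[i]][2] - shift])
        pos[rs[i]] = np.array([iv[ring3[i]][0], -iv[ring3[i]][1], -iv[ring3[i]][2] - shift])
    rho6 = 1.0  # ring of six with unit chord
    for j, ring in enumerate(rings):
        z = belt_h / 2.0 - dz_ring * (j + 1)
        for k in range(6):
            a = math.radians(60 * k + 30 * (j % 2))
            pos[ring[k]] = [rho6 * math.cos(a), rho6 * math.sin(a), z]

    kinds = ["hexamer"] * len(ids)
    for v in tn + rn + ts + rs:
        kinds[v] = "pentamer"
    surface = {"kind": "none", "ring_z": [belt_h / 2.0, -belt_h / 2.0]}
    cage = _finalize_cage(arch, pos, kinds, adjacency, surface)
    _relabel_zones(cage)
    if radius is not None:
        _rescale(cage, radius)
    return cage


def _rotation_onto_z(axis):
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    c = float(np.dot(axis, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


# ---------------------------------------------------------------------------
# operations on cages
# ---------------------------------------------------------------------------


def enumerate_dimers(cage: LatticeCage) -> list[Edge]:
    """Every capsomer-adjacency edge carries one CP dimer: pentamer-hexamer
    edges are A/B, hexamer-hexamer edges C/C, and pentamer-pentamer contacts
    (T=1-like caps) A/B by convention."""
    return list(cage.edges)


def composition(
    cage: LatticeCage, mat_substituted: bool = False, internal_dimer: bool = False
) -> Composition:
    """Dimer bookkeeping, optionally with the maturation-protein substitution
    (one C/C dimer on the shell replaced by Mat) and the internal dimer."""
    n_ab = sum(1 for e in cage.edges if e.dimer_class == "A/B")
    n_cc = sum(1 for e in cage.edges if e.dimer_class == "C/C")
    total = len(cage.edges)
    comp = Composition(
        n_cp=cage.n_cp,
        n_pentamer=cage.n_pentamer,
        n_hexamer=cage.n_hexamer,
        n_dimer_total=total,
        n_dimer_AB=n_ab,
        n_dimer_CC=n_cc,
    )
    if mat_substituted:
        if n_cc == 0:
            raise ValueError(
                "Mat substitution requires a C/C dimer (hexamer-hexamer edge); "
                f"{cage.architecture.label()} has none"
            )
        comp.n_dimer_capsid_after_mat = total - 1
        if internal_dimer:
            comp.n_dimer_with_internal = comp.n_dimer_capsid_after_mat + 1
    elif internal_dimer:
        comp.n_dimer_with_internal = total + 1
    return comp


def elongate_by_ring(cage: LatticeCage) -> LatticeCage:
    """Insert a ring of five hexamers at the 5-fold equator.

    Realized by cutting the cage perpendicular to the 5-fold axis and
    re-deriving the closed lattice with elongation number Q+1; the two
    hemispheres of the result are rotated 36° relative to their input
    orientation (staggered and eclipsed ring registries alternate).
    Oblate(3,2) becomes the T=3 composition; T=3 becomes prolate(3,4).
    """
    a = cage.architecture
    if a.symmetry_class == "icosahedral":
        T, Q = a.T, a.T
    elif a.symmetry_class == "elongated_5fold":
        T, Q = a.T, a.Q
    else:
        raise ValueError("cage has no 5-fold symmetry axis to elongate about")
    return build_elongated_5fold(T, Q + 1)


def hemisphere_twist(cage: LatticeCage) -> float:
    """Relative azimuthal registry (degrees, in [0, 36]) of the two polar
    pentamer rings about the 5-fold axis; 36° for icosahedral/staggered,
    0° for eclipsed tubes."""
    pents = [s for s in cage.sites if s.kind == "pentamer"]
    zs = sorted(pents, key=lambda s: -s.position[2])
    north_ring = zs[1:6]
    south_ring = zs[6:11]
    az = lambda s: math.degrees(math.atan2(s.position[1], s.position[0])) % 72.0
    an = sorted(az(s) for s in north_ring)
    asouth = sorted(az(s) for s in south_ring)
    d = abs(an[0] - asouth[0]) % 72.0
    return min(d, 72.0 - d)


# ---------------------------------------------------------------------------
# 2D unwrapping (net map)
# ---------------------------------------------------------------------------


@dataclass
class NetMap:
    """Planar unwrapping of a cage.

    ``nodes`` are 2D copies of capsomers (boundary capsomers may appear more
    than once); every dimer edge appears exactly once, referencing node
    copies.  ``pentamer_labels`` number the 12 pentamers I–XII.
    """

    nodes: list[dict]
    edges: list[dict]
    pentamer_labels: dict[int, str]
    markers: list[dict] = field(default_factory=list)

    def reconstruct_adjacency(self) -> set[tuple[int, int]]:
        node_site = {n["id"]: n["site"] for n in self.nodes}
        return {
            tuple(sorted((node_site[e["node_a"]], node_site[e["node_b"]])))
            for e in self.edges
        }

    def to_json_dict(self) -> dict:
        return {
            "nodes": self.nodes,
            "edges": self.edges,
            "pentamer_labels": {str(k): v for k, v in self.pentamer_labels.items()},
            "markers": self.markers,
        }


def unwrap_net(cage: LatticeCage, markers=None, anchor_pentamer: int | None = None) -> NetMap:
    """Unfold the facet triangulation into the plane.

    A spanning tree of the facet-adjacency graph is unfolded isometrically;
    facets joined across a tree edge share welded capsomer copies, and each
    dimer edge is drawn exactly once (cut edges on one of their two sides).
    Pentamers are numbered I–XII, anchored at ``anchor_pentamer`` (default:
    the pentamer with the greatest z) and ordered by descending z then
    azimuth.
    """
    pos = {s.id: s.position for s in cage.sites}
    facets = cage.facets
    edge_by_pair = {tuple(sorted((e.site_a, e.site_b))): e for e in cage.edges}

    # facet adjacency via shared edges
    by_edge = {}
    for fi, f in enumerate(facets):
        for pair in ((f[0], f[1]), (f[0], f[2]), (f[1], f[2])):
            by_edge.setdefault(tuple(sorted(pair)), []).append(fi)

    # BFS unfold
    placed2d = {}  # (facet, site) -> xy
    visited = set()
    import collections

    queue = collections.deque()
    f0 = 0
    a, b, c = facets[f0]
    la = np.linalg.norm(pos[b] - pos[a])
    placed2d[(f0, a)] = np.array([0.0, 0.0])
    placed2d[(f0, b)] = np.array([la, 0.0])
    placed2d[(f0, c)] = _third_point(
        placed2d[(f0, a)], placed2d[(f0, b)],
        np.linalg.norm(pos[c] - pos[a]), np.linalg.norm(pos[c] - pos[b]), +1.0
    )
    visited.add(f0)
    queue.append(f0)
    tree_welds = []  # ((f_parent, site), (f_child, site)) pairs welded
    while queue:
        fi = queue.popleft()
        for pair in ((facets[fi][0], facets[fi][1]), (facets[fi][0], facets[fi][2]), (facets[fi][1], facets[fi][2])):
            key = tuple(sorted(pair))
            for fj in by_edge[key]:
                if fj in visited:
                    continue
                u, v = key
                w = [x for x in facets[fj] if x not in key][0]
                p_u, p_v = placed2d[(fi, u)], placed2d[(fi, v)]
                # place w on the opposite side of uv from fi's third point
                other = [x for x in facets[fi] if x not in key][0]
                side = _side(p_u, p_v, placed2d[(fi, other)])
                p_w = _third_point(
                    p_u, p_v,
                    np.linalg.norm(pos[w] - pos[u]), np.linalg.norm(pos[w] - pos[v]),
                    -side,
                )
                placed2d[(fj, u)] = p_u
                placed2d[(fj, v)] = p_v
                placed2d[(fj, w)] = p_w
                tree_welds.append(((fi, u), (fj, u)))
                tree_welds.append(((fi, v), (fj, v)))
                visited.add(fj)
                queue.append(fj)

    # union-find over (facet, site) instances
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for x, y in tree_welds:
        union(x, y)

    node_of_root = {}
    nodes = []
    for (fi, site), xy in placed2d.items():
        r = find((fi, site))
        if r not in node_of_root:
            node_of_root[r] = len(nodes)
            rxy = placed2d[r] if r in placed2d else xy
            nodes.append({"id": len(nodes), "site": site, "xy": [float(rxy[0]), float(rxy[1])]})

    def node_id(fi, site):
        return node_of_root[find((fi, site))]

    # each cage edge drawn once: pick the lowest-index facet containing it
    net_edges = []
    for key, e in sorted(edge_by_pair.items(), key=lambda kv: kv[1].id):
        fi = min(by_edge[key])
        na, nb = node_id(fi, key[0]), node_id(fi, key[1])
        net_edges.append(
            {"edge": e.id, "node_a": na, "node_b": nb, "dimer_class": e.dimer_class}
        )

    # pentamer numbering I–XII
    pents = [s for s in cage.sites if s.kind == "pentamer"]
    if anchor_pentamer is not None:
        valid = {s.id for s in pents}
        if anchor_pentamer not in valid:
            raise ValueError(f"anchor pentamer {anchor_pentamer} is not a pentamer site")
        anchor = next(s for s in pents if s.id == anchor_pentamer)
    else:
        anchor = max(pents, key=lambda s: s.position[2])
    rest = sorted(
        (s for s in pents if s.id != anchor.id),
        key=lambda s: (-round(s.position[2], 6), math.atan2(s.position[1], s.position[0])),
    )
    labels = {anchor.id: ROMAN[0]}
    for i, s in enumerate(rest, start=1):
        labels[s.id] = ROMAN[i]

    net = NetMap(nodes, net_edges, labels)

    if markers:
        known = {e["edge"] for e in net_edges}
        bad = [d for d, _ in markers if d not in known]
        if bad:
            raise ValueError(f"markers reference unknown dimer ids: {sorted(bad)}")
        xy_of = {n["id"]: np.array(n["xy"]) for n in nodes}
        edge_lookup = {e["edge"]: e for e in net_edges}
        order = sorted(range(len(markers)), key=lambda i: markers[i][1])
        rank = {markers[i][1]: r for r, i in enumerate(sorted(order, key=lambda i: markers[i][1]))}
        for dimer_id, genome_index in markers:
            e = edge_lookup[dimer_id]
            mid = 0.5 * (xy_of[e["node_a"]] + xy_of[e["node_b"]])
            net.markers.append(
                {
                    "edge": dimer_id,
                    "genome_index": genome_index,
                    "xy": [float(mid[0]), float(mid[1])],
                    "color_index": rank[genome_index],
                }
            )
    return net


def _third_point(p, q, d_p, d_q, sign):
    """2D point at distances d_p from p and d_q from q, on the given side."""
    v = q - p
    L = np.linalg.norm(v)
    x = (d_p * d_p - d_q * d_q + L * L) / (2 * L)
    h2 = d_p * d_p - x * x
    h = sqrt(max(h2, 0.0))
    u = v / L
    n = np.array([-u[1], u[0]])
    return p + x * u + sign * h * n


def _side(p, q, r):
    v = q - p
    return 1.0 if (v[0] * (r - p)[1] - v[1] * (r - p)[0]) >= 0 else -1.0


def build(architecture: CapsidArchitecture, radius: float | None = None) -> LatticeCage:
    """Dispatch on the symmetry class of an architecture descriptor."""
    a = architecture
    if a.symmetry_class == "icosahedral":
        return build_icosahedral(a.T, radius=radius)
    if a.symmetry_class == "elongated_5fold":
        return build_elongated_5fold(a.T, a.Q, radius=radius)
    return build_elongated_3fold(a.T, a.Q1, a.Q2, radius=radius)
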