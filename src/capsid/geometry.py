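"""Hexamer curvature analysis.

A coat-protein hexamer is described by its six subunit centroids, labeled
a–f cyclically around the ring.  Curvature is measured by three arch angles
across the opposite subunit pairs (a,d), (b,e), (c,f): each angle is taken at
the hexamer centroid m (the mean of the six subunit centroids) between the
vectors to the two opposite centroids.  A flat hexamer gives 180°; doming
decreases the angle.  θ is the angle across the pair singled out by the
hexamer's local dyad — operationally, the assignment of (θ, ϕ, Ψ) that
minimizes |ϕ − Ψ|, since ϕ and Ψ are symmetry-equal in all observed forms.

Hexamers fall into four curvature classes by θ, anchored at the observed
values ≈130° (over-arched), ≈155° (normal), ≈170° (less arched) and ≈180°
(straight); class boundaries sit at the midpoints 142.5°, 162.5° and 175°.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .lattice import LatticeCage

logger = logging.getLogger("capsid.geometry")

SUBUNIT_LABELS = ["a", "b", "c", "d", "e", "f"]

#: class boundaries on θ (degrees): midpoints between the ~130/~155/~170/~180
#: anchors of the four observed hexamer types
OVER_ARCHED_MAX = 142.5
NORMAL_ARCHED_MAX = 162.5
LESS_ARCHED_MAX = 175.0

#: atom names treated as backbone when computing subunit centroids
BACKBONE_ATOMS = {"N", "CA", "C", "O", "P", "O5'", "C5'", "C4'", "C3'", "O3'"}


@dataclass
class HexamerGeometry:
    """Six ordered subunits of one hexamer with its arch angles."""

    site: int | None
    centroids: np.ndarray  # (6, 3), cyclic order a..f
    centroid_m: np.ndarray = field(default=None)
    theta: float = float("nan")
    phi: float = float("nan")
    psi: float = float("nan")
    curvature_class: str = ""
    zone: str = ""
    form: str = ""
    chains: dict = field(default_factory=dict)  # label -> chain name


@dataclass
class LoopDisplacement:
    loop_name: str
    residue_range: tuple[int, int]
    displacement: float
    direction: str  # "toward" | "away"


def pair_angles(centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Angles (degrees) across the three opposite pairs, at the mean point."""
    c = np.asarray(centroids, dtype=float)
    if c.shape != (6, 3):
        raise ValueError("a hexamer needs exactly six subunit centroids")
    m = c.mean(axis=0)
    angles = np.empty(3)
    for i in range(3):
        u, v = c[i] - m, c[i + 3] - m
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-9 or nv < 1e-9:
            raise ValueError("degenerate hexamer: a subunit centroid coincides with m")
        cosang = float(np.dot(u, v) / (nu * nv))
        angles[i] = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return angles, m


def arch_angles(hexamer) -> tuple[float, float, float]:
    """(θ, ϕ, Ψ) for a HexamerGeometry or a (6,3) centroid array.

    θ is assigned to the pair that makes the remaining two angles most
    similar (|ϕ−Ψ| minimal); on ties, to the pair angle most deviant from
    the mean of the three.
    """
    c = hexamer.centroids if isinstance(hexamer, HexamerGeometry) else np.asarray(hexamer)
    angles, m = pair_angles(c)
    best, best_key = 0, None
    mean = angles.mean()
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        key = (round(abs(angles[j] - angles[k]), 9), -round(abs(angles[i] - mean), 9))
        if best_key is None or key < best_key:
            best, best_key = i, key
    theta = float(angles[best])
    phi = float(angles[(best + 1) % 3])
    psi = float(angles[(best + 2) % 3])
    if isinstance(hexamer, HexamerGeometry):
        hexamer.centroid_m = m
        hexamer.theta, hexamer.phi, hexamer.psi = theta, phi, psi
        hexamer.curvature_class = classify_curvature(theta)
    return theta, phi, psi


def classify_curvature(theta: float) -> str:
    """Four-way curvature class from θ in degrees."""
    if not (0.0 < theta <= 180.0):
        raise ValueError(f"arch angle θ={theta} out of range (0, 180]")
    if theta < OVER_ARCHED_MAX:
        return "over_arched"
    if theta < NORMAL_ARCHED_MAX:
        return "normal_arched"
    if theta < LESS_ARCHED_MAX:
        return "less_arched"
    return "straight"


# ---------------------------------------------------------------------------
# extraction from structures / cages
# ---------------------------------------------------------------------------


def _order_ring(centroids, center=None):
    """Cyclic a..f order by angular sweep about the ring normal."""
    c = np.asarray(centroids, dtype=float)
    m = c.mean(axis=0)
    x = c - m
    _, _, vt = np.linalg.svd(x)
    normal = vt[2]
    if center is not None and np.dot(normal, m - center) < 0:
        normal = -normal
    e1 = vt[0]
    e2 = np.cross(normal, e1)
    ang = np.arctan2(x @ e2, x @ e1)
    return np.argsort(ang)


def hexamer_geometries_from_cage(cage: LatticeCage) -> list[HexamerGeometry]:
    """Ideal hexamer geometries straight from a cage's subunit placements."""
    center = np.mean([s.position for s in cage.sites], axis=0)
    out = []
    for s in cage.sites:
        if s.kind != "hexamer":
            continue
        subs = cage.hexamer_subunits(s.id)
        cents = np.array([p.origin for p in subs])
        order = _order_ring(cents, center)
        geom = HexamerGeometry(
            site=s.id,
            centroids=cents[order],
            zone=s.zone,
            form=cage.architecture.label(),
        )
        arch_angles(geom)
        out.append(geom)
    return out


def extract_hexamers(structure, cage: LatticeCage | None = None, chain_map=None) -> list[HexamerGeometry]:
    """Group coat-protein chains into hexamers and measure their geometry.

    ``chain_map`` maps chain name -> capsomer site id; if absent and a cage
    is given, chains are assigned to the nearest cage site by centroid (the
    structure and cage must share a frame, as synthetic fixtures do).
    Without a cage, chains are clustered by centroid proximity into rings of
    five or six.  Hexamers with a number of resolved chains other than six
    are skipped with a warning.
    """
    cents = {}
    for ch in structure.chains:
        xyz = ch.atom_coords(backbone_only=True)
        if len(xyz):
            cents[ch.name] = xyz.mean(axis=0)
    if chain_map is None:
        if cage is not None:
            sites = np.array([s.position for s in cage.sites])
            ids = [s.id for s in cage.sites]
            chain_map = {}
            for name, c in cents.items():
                chain_map[name] = ids[int(np.argmin(np.linalg.norm(sites - c, axis=1)))]
        else:
            chain_map = _cluster_chains(cents)

    groups = {}
    for name, site in chain_map.items():
        if name in cents:
            groups.setdefault(site, []).append(name)

    zone_of, form = {}, ""
    if cage is not None:
        zone_of = {s.id: (s.zone, s.kind) for s in cage.sites}
        form = cage.architecture.label()

    center = np.mean(list(cents.values()), axis=0)
    out = []
    for site, names in sorted(groups.items()):
        if cage is not None and zone_of.get(site, ("", ""))[1] != "hexamer":
            continue
        if cage is None and len(names) == 5:
            continue  # pentamer cluster
        if len(names) != 6:
            logger.warning(
                "hexamer %s skipped: %d resolved chains (need 6)", site, len(names)
            )
            continue
        c6 = np.array([cents[n] for n in names])
        order = _order_ring(c6, center)
        geom = HexamerGeometry(
            site=site,
            centroids=c6[order],
            zone=zone_of.get(site, ("", ""))[0],
            form=form,
            chains={SUBUNIT_LABELS[i]: names[order[i]] for i in range(6)},
        )
        arch_angles(geom)
        out.append(geom)
    return out


def _cluster_chains(cents: dict) -> dict:
    """Cluster chain centroids into capsomers by proximity (single-linkage
    at 1.5× the smallest inter-centroid spacing)."""
    names = list(cents)
    xyz = np.array([cents[n] for n in names])
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(xyz))
    np.fill_diagonal(d, np.inf)
    cut = 1.5 * d.min()
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if d[i, j] < cut:
                g.add_edge(i, j)
    chain_map = {}
    for k, comp in enumerate(nx.connected_components(g)):
        for i in comp:
            chain_map[names[i]] = k
    return chain_map


# ---------------------------------------------------------------------------
# loop displacement between hexamer conformations
# ---------------------------------------------------------------------------


def _chain_atoms(chain, resrange=None, backbone_only=False):
    out = {}
    for res in chain.residues:
        if resrange and not (resrange[0] <= res.seqid <= resrange[1]):
            continue
        for at in res.atoms:
            if backbone_only and at.name not in BACKBONE_ATOMS:
                continue
            out[(res.seqid, at.name)] = at.pos
    return out


def loop_displacement(
    hex_a: dict,
    hex_b: dict,
    loop_ranges: dict,
    anchor: str = "a",
    opposite: str = "f",
    c_terminus: int | None = None,
) -> list[LoopDisplacement]:
    """Loop motion of the ``opposite`` subunit between two hexamer
    conformations after superposing the ``anchor`` subunit backbone.

    ``hex_a``/``hex_b`` map subunit labels to chains sharing residue
    numbering; ``loop_ranges`` maps loop names (e.g. CD, DE) to inclusive
    residue ranges.  Direction is relative to the anchor's C-terminal
    residue: "toward" if the loop ends up closer to it in conformation B.
    """
    if anchor not in hex_a or anchor not in hex_b:
        raise ValueError(f"anchor subunit {anchor!r} missing from a hexamer")
    a_anchor = _chain_atoms(hex_a[anchor], backbone_only=True)
    b_anchor = _chain_atoms(hex_b[anchor], backbone_only=True)
    common = sorted(set(a_anchor) & set(b_anchor))
    if len(common) < 3:
        raise ValueError("anchor subunits share fewer than 3 backbone atoms")
    ref = np.array([a_anchor[k] for k in common])
    mov = np.array([b_anchor[k] for k in common])
    sup = SVDSuperimposer()
    sup.set(ref, mov)
    sup.run()
    rot, tran = sup.get_rotran()

    cterm_id = c_terminus if c_terminus is not None else max(r.seqid for r in hex_a[anchor].residues)
    cterm_atoms = _chain_atoms(hex_a[anchor], resrange=(cterm_id, cterm_id))
    cterm = np.mean(list(cterm_atoms.values()), axis=0)

    out = []
    for name, rng in loop_ranges.items():
        la = _chain_atoms(hex_a[opposite], resrange=tuple(rng))
        lb = _chain_atoms(hex_b[opposite], resrange=tuple(rng))
        if not la or not lb:
            raise ValueError(f"loop {name} residues {rng[0]}-{rng[1]} missing from a hexamer")
        ca = np.mean(list(la.values()), axis=0)
        cb = np.mean(list(lb.values()), axis=0) @ rot + tran
        disp = float(np.linalg.norm(cb - ca))
        direction = "toward" if np.linalg.norm(cb - cterm) < np.linalg.norm(ca - cterm) else "away"
        out.append(LoopDisplacement(name, tuple(rng), disp, direction))
    return out


def default_loop_ranges() -> dict:
    """Shipped approximate loop annotation of the Qβ coat-protein fold
    (CD/DE/FG loops and the C-terminal residue); override per structure."""
    import json
    from pathlib import Path

    path = Path(__file__).parent / "data" / "qbeta_cp_loops.json"
    return json.loads(path.read_text())


def hexamer_table(geoms: list[HexamerGeometry]):
    """Per-hexamer summary (form, zone, θ, ϕ, Ψ, class) as a DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "form": g.form,
                "site": g.site,
                "zone": g.zone,
                "theta": round(g.theta, 3),
                "phi": round(g.phi, 3),
                "psi": round(g.psi, 3),
                "curvature_class": g.curvature_class,
            }
            for g in geoms
        ]
    )
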