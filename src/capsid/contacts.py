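"""RNA stem-loop inventory and coat-protein contact census.

Stem-loops are maximal helices (>= min_helix stacked pairs, small bulges
allowed) read off a secondary structure; each helix of a multibranch
junction is reported as its own stem element.  The census measures, per
stem-loop, the minimum heavy-atom distance to the protein components of the
virion (the CP shell organized as dimers, the maturation protein, and the
internal CP dimer); stem-loops strictly closer than the cutoff (5 Å for the
Qβ virion) are in contact, and their binding mode is classified:

* operator-like — the backbone follows the canonical operator trace
  relative to its CP dimer (RMSD in the dimer frame below a threshold,
  either monomer orientation);
* CP-sandwiched — the apical loop points at the dimer center (apex within
  ``axis_tol`` of the dyad axis) with both monomers contacted;
* CP-anchored — gripping exactly one monomer of the dimer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import EntityConfig, StructureModel

logger = logging.getLogger("capsid.contacts")

#: approximate gene map of the 4217-nt Qβ genome (1-based, inclusive),
#: used only to annotate stem-loops with their genetic context
QBETA_GENE_MAP = [
    ("5'UTR", 1, 60),
    ("mat", 61, 1323),
    ("cp", 1344, 1743),
    ("A1", 1744, 2333),
    ("rep", 2352, 4118),
    ("3'UTR", 4119, 4217),
]
QBETA_GENOME_LENGTH = 4217


@dataclass
class StemLoop:
    """One helix element: nt_range spans the outermost pair; apical_loop is
    the enclosed terminal loop when the helix closes a hairpin."""

    id: int
    nt_range: tuple[int, int]
    helix_pairs: list[tuple[int, int]]
    apical_loop: tuple[int, int] | None = None
    name: str = ""
    gene_context: str = ""
    pseudoknotted: bool = False


@dataclass
class ContactRecord:
    stemloop_id: int
    partner: str | None  # dimer id, "Mat", "internal", or None
    min_distance: float
    monomers_contacted: tuple[str, ...] = ()
    mode: str = "none"  # operator_like | cp_sandwiched | cp_anchored | none
    dimer_class: str = ""
    unresolved: bool = False


def detect_stem_loops(
    pairs,
    sequence: str,
    min_helix: int = 3,
    max_bulge: int = 2,
    gene_map=None,
) -> list[StemLoop]:
    """Group base pairs into maximal helices and number them in genome order.

    Consecutive pairs belong to one helix when the total bulged nucleotides
    between them is at most ``max_bulge``.  Helices shorter than
    ``min_helix`` are dropped.  Crossing (pseudoknotted) helices are kept
    and flagged.
    """
    n = len(sequence)
    partner = [0] * (n + 1)
    for i, j in pairs:
        if not (1 <= i < j <= n):
            raise ValueError(f"pair ({i},{j}) outside sequence or not i<j")
        if partner[i] or partner[j]:
            raise ValueError(f"conflicting base pairs at position {i if partner[i] else j}")
        partner[i], partner[j] = j, i

    sorted_pairs = sorted(pairs)
    helices = []
    used = set()
    for p in sorted_pairs:
        if p in used:
            continue
        helix = [p]
        used.add(p)
        while True:
            i, j = helix[-1]
            nxt = None
            for di in range(1, max_bulge + 2):
                ii = i + di
                if ii >= j or ii > n:
                    break
                jj = partner[ii]
                if jj and ii < jj < j and (di - 1) + (j - jj - 1) <= max_bulge:
                    nxt = (ii, jj)
                    break
            if nxt is None or nxt in used:
                break
            helix.append(nxt)
            used.add(nxt)
        helices.append(helix)

    helices = [h for h in helices if len(h) >= min_helix]
    helices.sort(key=lambda h: h[0][0])

    def crosses(h1, h2):
        (a, b), (c, d) = h1[0], h2[0]
        return a < c < b < d or c < a < d < b

    stems = []
    for idx, h in enumerate(helices, start=1):
        i_out, j_out = h[0]
        i_in, j_in = h[-1]
        apical = None
        if all(partner[k] == 0 for k in range(i_in + 1, j_in)):
            if j_in - i_in > 1:
                apical = (i_in + 1, j_in - 1)
        pk = any(crosses(h, other) for other in helices if other is not h)
        ctx = ""
        gm = QBETA_GENE_MAP if gene_map is None and n == QBETA_GENOME_LENGTH else gene_map
        if gm:
            for gname, lo, hi in gm:
                if lo <= i_out <= hi:
                    ctx = gname
                    break
        stems.append(
            StemLoop(idx, (i_out, j_out), list(h), apical, gene_context=ctx, pseudoknotted=pk)
        )
    return stems


# ---------------------------------------------------------------------------
# contact census
# ---------------------------------------------------------------------------


def _entity_atoms(structure: StructureModel, config: EntityConfig):
    """(partner, monomer, coordinates) per protein atom."""
    rows = []
    for did, chains in config.cp_dimers.items():
        for mon, chname in zip(("1", "2"), chains):
            ch = structure.chain(chname)
            for r in ch.residues:
                for a in r.heavy_atoms():
                    rows.append((str(did), mon, a.pos))
    if config.mat_chain:
        ch = structure.chain(config.mat_chain)
        for r in ch.residues:
            for a in r.heavy_atoms():
                rows.append(("Mat", "", a.pos))
    return rows


def contact_census(
    stemloops,
    structure: StructureModel,
    config: EntityConfig,
    cutoff: float | None = None,
) -> list[ContactRecord]:
    """Minimum heavy-atom distance from each stem-loop to any protein
    component; contacts are strictly below the cutoff."""
    cutoff = config.cutoff if cutoff is None else cutoff
    rows = _entity_atoms(structure, config)
    if not rows:
        raise ValueError("entity config names no protein chains")
    coords = np.array([r[2] for r in rows])
    tree = cKDTree(coords)

    res_index = {}
    for chname in config.rna_chains:
        ch = structure.chain(chname)
        for r in ch.residues:
            res_index[r.seqid + config.genome_offset] = r

    records = []
    for sl in stemloops:
        lo, hi = sl.nt_range
        atoms = []
        for nt in range(lo, hi + 1):
            r = res_index.get(nt)
            if r is not None:
                atoms.extend(a.pos for a in r.heavy_atoms())
        if not atoms:
            records.append(
                ContactRecord(sl.id, None, float("inf"), unresolved=True)
            )
            continue
        d, idx = tree.query(np.array(atoms))
        best = int(np.argmin(d))
        min_d = float(d[best])
        if min_d >= cutoff:
            records.append(ContactRecord(sl.id, None, min_d))
            continue
        partner = rows[idx[best]][0]
        monomers = set()
        if partner != "Mat":
            near = tree.query_ball_point(np.array(atoms), cutoff)
            for hits in near:
                for h in hits:
                    if rows[h][0] == partner:
                        monomers.add(rows[h][1])
        records.append(
            ContactRecord(
                sl.id,
                partner,
                min_d,
                tuple(sorted(monomers)),
                dimer_class=config.dimer_class.get(partner, ""),
            )
        )
    return records


# ---------------------------------------------------------------------------
# binding-mode classification
# ---------------------------------------------------------------------------


def _protein_center(structure: StructureModel, exclude=()):
    """Centroid of the coat-protein shell (chains with CA atoms), used as
    the capsid center when orienting dimer frames."""
    coords = []
    for ch in structure.chains:
        if ch.name in exclude:
            continue
        xyz = ch.atom_coords(backbone_only=True)
        if len(xyz) and any(a.name == "CA" for r in ch.residues for a in r.atoms):
            coords.append(xyz.mean(axis=0))
    if not coords:
        return np.zeros(3)
    return np.mean(coords, axis=0)


def dimer_frame(structure: StructureModel, chains, outward=None):
    """(origin, axes) of a CP dimer: origin at the dimer centroid, x along
    the dyad axis from least-squares monomer superposition, z outward.

    ``outward`` is the outward capsid normal at the dimer (defaults to the
    origin direction from the structure centroid)."""
    ch1 = structure.chain(chains[0]).atom_coords(backbone_only=True)
    ch2 = structure.chain(chains[1]).atom_coords(backbone_only=True)
    origin = np.vstack([ch1, ch2]).mean(axis=0)
    if outward is None:
        outward = origin - _protein_center(structure, chains)
        if np.linalg.norm(outward) < 1e-3:
            # isolated dimer: no shell to point away from; +z by convention
            outward = np.array([0.0, 0.0, 1.0])
    outward = np.asarray(outward, float)
    outward = outward / np.linalg.norm(outward)

    # rotation mapping monomer 1 onto monomer 2 (matched by rank); its axis
    # approximates the dimer dyad
    m = min(len(ch1), len(ch2))
    a = ch1[:m] - ch1[:m].mean(axis=0)
    b = ch2[:m] - ch2[:m].mean(axis=0)
    H = a.T @ b
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    w, v = np.linalg.eig(R)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis = axis / np.linalg.norm(axis)
    if np.dot(axis, outward) < 0:
        axis = -axis
    # frame: z = dyad (outward-aligned), x = monomer separation, y = z × x
    z = axis
    sep = ch2.mean(axis=0) - ch1.mean(axis=0)
    x = sep - np.dot(sep, z) * z
    if np.linalg.norm(x) < 1e-9:
        x = np.array([1.0, 0.0, 0.0]) - z[0] * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return origin, np.array([x, y, z])


def _resample(points: np.ndarray, n: int) -> np.ndarray:
    """Arclength-uniform resampling of a backbone trace to n points."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] == 0:
        return np.repeat(pts[:1], n, axis=0)
    ti = np.linspace(0, t[-1], n)
    return np.column_stack([np.interp(ti, t, pts[:, k]) for k in range(3)])


def classify_mode(
    record: ContactRecord,
    backbone: np.ndarray,
    frame,
    reference_trace: np.ndarray,
    apical_centroid: np.ndarray | None = None,
    trace_rmsd_max: float = 8.0,
    axis_tol: float = 6.0,
) -> str:
    """Binding mode of an in-contact stem-loop against its CP dimer.

    ``backbone`` is the stem-loop phosphate/backbone trace (world frame);
    ``frame`` the (origin, axes) of the partner dimer; ``reference_trace``
    the canonical operator backbone in the dimer frame."""
    if record.partner is None or record.partner == "Mat":
        return "none"
    if reference_trace is None:
        raise ValueError(
            "no reference operator trace: generate one with "
            "capsid.synthetic_data.canonical_operator_trace()"
        )
    origin, axes = frame
    local = (np.asarray(backbone, float) - origin) @ axes.T
    ref = np.asarray(reference_trace, float)
    trace = _resample(local, len(ref))
    # dyad flip: rotate 180 deg about z (x -> -x, y -> -y)
    flip = trace * np.array([-1.0, -1.0, 1.0])
    rmsd = min(
        float(np.sqrt(np.mean(np.sum((t - ref) ** 2, axis=1))))
        for t in (trace, trace[::-1], flip, flip[::-1])
    )
    both = set(record.monomers_contacted) >= {"1", "2"}
    if rmsd <= trace_rmsd_max and both:
        return "operator_like"
    if apical_centroid is not None and both:
        ap = (np.asarray(apical_centroid, float) - origin) @ axes.T
        if float(np.hypot(ap[0], ap[1])) <= axis_tol:
            return "cp_sandwiched"
    if len(record.monomers_contacted) == 1:
        return "cp_anchored"
    return "none"


def classify_records(
    records,
    stemloops,
    structure: StructureModel,
    config: EntityConfig,
    reference_trace: np.ndarray,
) -> list[ContactRecord]:
    """Run classify_mode over a census, filling record.mode in place."""
    sl_by_id = {sl.id: sl for sl in stemloops}
    res_index = {}
    for chname in config.rna_chains:
        for r in structure.chain(chname).residues:
            res_index[r.seqid + config.genome_offset] = r
    frames = {}
    for rec in records:
        if rec.partner in (None, "Mat") or rec.unresolved:
            continue
        sl = sl_by_id[rec.stemloop_id]
        if rec.partner not in frames:
            frames[rec.partner] = dimer_frame(structure, config.cp_dimers[rec.partner])
        bb, apex = [], []
        for nt in range(sl.nt_range[0], sl.nt_range[1] + 1):
            r = res_index.get(nt)
            if r is None:
                continue
            coords = [a.pos for a in r.heavy_atoms() if a.name in ("P", "C4'", "CA")]
            if not coords:
                coords = [a.pos for a in r.heavy_atoms()]
            bb.append(np.mean(coords, axis=0))
            if sl.apical_loop and sl.apical_loop[0] <= nt <= sl.apical_loop[1]:
                apex.append(np.mean(coords, axis=0))
        rec.mode = classify_mode(
            rec,
            np.array(bb),
            frames[rec.partner],
            reference_trace,
            np.mean(apex, axis=0) if apex else None,
            config.trace_rmsd_max,
            config.axis_tol,
        )
    return records


def census_summary(records, stemloops=None, pentamer_membership=None):
    """Counts by mode × dimer class, plus optional per-pentamer operator
    tallies (``pentamer_membership``: dimer id -> pentamer labels)."""
    import pandas as pd

    rows = []
    for r in records:
        if r.unresolved:
            continue
        rows.append(
            {
                "stemloop_id": r.stemloop_id,
                "partner": r.partner if r.partner is not None else "none",
                "dimer_class": r.dimer_class or ("Mat" if r.partner == "Mat" else ""),
                "mode": r.mode,
                "min_distance": round(r.min_distance, 3) if np.isfinite(r.min_distance) else None,
            }
        )
    df = pd.DataFrame(rows)
    in_contact = df[df["partner"] != "none"] if len(df) else df
    by_mode = (
        in_contact.groupby(["mode", "dimer_class"]).size().rename("count").reset_index()
        if len(in_contact)
        else pd.DataFrame(columns=["mode", "dimer_class", "count"])
    )
    out = {"records": df, "by_mode": by_mode, "n_total": len(df), "n_in_contact": len(in_contact)}
    if pentamer_membership is not None:
        tally = {}
        for r in records:
            if r.mode == "operator_like" and r.partner in pentamer_membership:
                for p in pentamer_membership[r.partner]:
                    tally[p] = tally.get(p, 0) + 1
        out["per_pentamer_operator"] = tally
    return out
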