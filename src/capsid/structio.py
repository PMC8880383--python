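"""Structure, sequence and secondary-structure I/O plus reporting.

PDB/mmCIF files are read and written through gemmi into a light
chain/residue/atom hierarchy (``StructureModel``).  Secondary structure is
accepted as dot-bracket (with pseudoknot bracket layers) or CT; both are
plain text and parsed here.  All coordinates in reports are 1-based
inclusive; the single conversion between model residue numbering and genome
coordinates is the ``genome_offset`` of the entity configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import __version__ as _VERSION

logger = logging.getLogger("capsid.structio")

_OPEN = "([{<" + "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_CLOSE = ")]}>" + "abcdefghijklmnopqrstuvwxyz"


# ---------------------------------------------------------------------------
# structure hierarchy
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray


@dataclass
class Residue:
    name: str
    seqid: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def heavy_atoms(self):
        return [a for a in self.atoms if a.element.upper() != "H"]


@dataclass
class Chain:
    name: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, seqid: int) -> Residue | None:
        for r in self.residues:
            if r.seqid == seqid:
                return r
        return None

    def atom_coords(self, backbone_only: bool = False, heavy_only: bool = True) -> np.ndarray:
        from .geometry import BACKBONE_ATOMS

        coords = []
        for r in self.residues:
            for a in r.atoms:
                if heavy_only and a.element.upper() == "H":
                    continue
                if backbone_only and a.name not in BACKBONE_ATOMS:
                    continue
                coords.append(a.pos)
        if backbone_only and not coords:
            return self.atom_coords(backbone_only=False, heavy_only=heavy_only)
        return np.array(coords) if coords else np.zeros((0, 3))


@dataclass
class StructureModel:
    """Chain/residue/atom hierarchy with entity role annotations."""

    chains: list[Chain] = field(default_factory=list)
    roles: dict = field(default_factory=dict)  # role name -> chain name(s)
    name: str = ""

    def chain(self, name: str) -> Chain:
        for c in self.chains:
            if c.name == name:
                return c
        raise KeyError(f"no chain {name!r} in structure")

    def validate(self):
        seen = set()
        for c in self.chains:
            if c.name in seen:
                raise ValueError(f"duplicate chain id {c.name!r}")
            seen.add(c.name)
            for r in c.residues:
                for a in r.atoms:
                    if not np.all(np.isfinite(a.pos)):
                        raise ValueError(f"non-finite coordinates in {c.name}/{r.seqid}")
        for role, chains in self.roles.items():
            names = chains if isinstance(chains, (list, tuple)) else [chains]
            for n in names:
                if n not in seen:
                    raise ValueError(f"role {role!r} references unknown chain {n!r}")
        return self


def read_structure(path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file (auto-detected by extension unless ``fmt``
    is given); alternative conformations keep the highest-occupancy atom."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"structure file {path} is missing or empty")
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("cif", "mmcif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError with context
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    model = st[0]
    out = StructureModel(name=st.name or path.stem)
    for ch in model:
        chain = Chain(ch.name)
        for res in ch:
            r = Residue(res.name, res.seqid.num, res.seqid.icode.strip())
            best = {}
            for at in res:
                key = at.name
                if key not in best or at.occ > best[key].occ:
                    best[key] = at
            for at in best.values():
                r.atoms.append(
                    Atom(at.name, at.element.name, np.array([at.pos.x, at.pos.y, at.pos.z]))
                )
            chain.residues.append(r)
        out.chains.append(chain)
    return out.validate()


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.name or "model"
    md = gemmi.Model("1")
    for ch in model.chains:
        gc = gemmi.Chain(ch.name)
        for r in ch.residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.seqid, r.icode or " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*[float(x) for x in a.pos])
                ga.occ = 1.0
                gr.add_atom(ga)
            gc.add_residue(gr)
        md.add_chain(gc)
    st.add_model(md)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path, fmt: str | None = None) -> None:
    """Write PDB (chain ids must be short) or mmCIF (any chain ids)."""
    path = Path(path)
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "cif"
    st = to_gemmi(model)
    if fmt == "pdb":
        if any(len(c.name) > 2 for c in model.chains):
            raise ValueError("PDB output needs chain ids of at most 2 characters; use mmCIF")
        st.write_pdb(str(path))
    else:
        doc = st.make_mmcif_document()
        doc.write_file(str(path))


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------


def parse_dotbracket(text: str) -> tuple[list[tuple[int, int]], str]:
    """Dot-bracket (with pseudoknot layers) -> 1-based pair list + sequence.

    Accepts plain structure text or FASTA-like blocks (``>header``,
    sequence line, structure line)."""
    seq, struct = "", ""
    for line in text.strip().splitlines():
        line = line.strip()
        if not line or line.startswith(">") or line.startswith("#"):
            continue
        if set(line) <= set(".()[]{}<>" + _OPEN + _CLOSE + "-_,"):
            if any(ch in line for ch in ".()[]{}<>") or not line.isalpha():
                struct += line
                continue
        seq += line
    if not struct and seq and set(seq) <= set(".()[]{}<>"):
        seq, struct = "", seq
    stacks = {}
    pairs = []
    for i, ch in enumerate(struct, start=1):
        if ch in "._-,:":
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN.index(ch), []).append(i)
        elif ch in _CLOSE:
            layer = _CLOSE.index(ch)
            if not stacks.get(layer):
                raise ValueError(f"unbalanced bracket {ch!r} at position {i}")
            pairs.append((stacks[layer].pop(), i))
        else:
            raise ValueError(f"unexpected character {ch!r} at position {i}")
    for layer, st in stacks.items():
        if st:
            raise ValueError(f"unbalanced bracket {_OPEN[layer]!r} at position {st[-1]}")
    pairs.sort()
    if seq and len(seq) != len(struct):
        raise ValueError(
            f"sequence length {len(seq)} != structure length {len(struct)}"
        )
    return pairs, seq


def parse_ct(text: str) -> tuple[list[tuple[int, int]], str]:
    """Standard 6-column CT format -> 1-based pair list + sequence."""
    lines = [l for l in text.strip().splitlines() if l.strip()]
    if not lines:
        raise ValueError("empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError("CT header must begin with the sequence length") from exc
    seq = []
    pairs = []
    for ln in lines[1 : n + 1]:
        cols = ln.split()
        if len(cols) < 6:
            raise ValueError(f"CT line has {len(cols)} columns (need 6): {ln!r}")
        idx, base, pair = int(cols[0]), cols[1], int(cols[4])
        seq.append(base)
        if pair > idx:
            pairs.append((idx, pair))
    if len(seq) != n:
        raise ValueError(f"CT file lists {len(seq)} residues, header says {n}")
    return sorted(pairs), "".join(seq)


def read_secondary_structure(path, fmt: str | None = None) -> tuple[list[tuple[int, int]], str]:
    path = Path(path)
    text = path.read_text()
    if fmt is None:
        fmt = "ct" if path.suffix.lower() == ".ct" else "dotbracket"
    return parse_ct(text) if fmt == "ct" else parse_dotbracket(text)


def pairs_to_dotbracket(pairs, length: int) -> str:
    """Pair list -> dot-bracket string, assigning bracket layers greedily to
    crossing pairs."""
    layers: list[list[tuple[int, int]]] = []
    out = ["."] * length
    for i, j in sorted(pairs):
        for li, layer in enumerate(layers):
            if all(not (a < i < b < j or i < a < j < b) for a, b in layer):
                layer.append((i, j))
                out[i - 1], out[j - 1] = _OPEN[li], _CLOSE[li]
                break
        else:
            layers.append([(i, j)])
            out[i - 1], out[j - 1] = _OPEN[len(layers) - 1], _CLOSE[len(layers) - 1]
    return "".join(out)


def read_fasta(path) -> str:
    seq = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith(">"):
            seq.append(line)
    return "".join(seq).upper().replace("T", "U")


def write_fasta(seq: str, path, header: str = "sequence") -> None:
    with open(path, "w") as fh:
        fh.write(f">{header}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# entity configuration
# ---------------------------------------------------------------------------


@dataclass
class EntityConfig:
    """Names the molecular entities of a virion model and the analysis
    thresholds.

    genome_offset converts model residue numbers to 1-based genome
    coordinates (genome = model + genome_offset).
    """

    rna_chains: list[str] = field(default_factory=list)
    cp_dimers: dict = field(default_factory=dict)  # dimer id -> [chain, chain]
    dimer_class: dict = field(default_factory=dict)  # dimer id -> A/B | C/C | internal
    mat_chain: str | None = None
    genome_offset: int = 0
    genome_length: int | None = None
    cutoff: float = 5.0
    min_helix: int = 3
    max_bulge: int = 2
    trace_rmsd_max: float = 8.0
    axis_tol: float = 6.0

    @classmethod
    def from_file(cls, path) -> "EntityConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def to_file(self, path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

REPORT_SCHEMA = {
    "required": ["capsid_version", "kind", "records"],
    "types": {"capsid_version": str, "kind": str, "records": list},
}


def validate_report(d: dict) -> None:
    for key in REPORT_SCHEMA["required"]:
        if key not in d:
            raise ValueError(f"report missing required key {key!r}")
        want = REPORT_SCHEMA["types"][key]
        if not isinstance(d[key], want):
            raise ValueError(f"report key {key!r} must be {want.__name__}")


def write_report(records: list[dict], path, fmt: str = "tsv", kind: str = "records",
                 columns: list[str] | None = None) -> None:
    """Stable-column TSV or version-stamped JSON; empty inputs produce a
    header-only TSV / empty record list."""
    import pandas as pd

    path = Path(path)
    if fmt == "tsv":
        if columns is None:
            columns = list(records[0]) if records else []
        df = pd.DataFrame(records, columns=columns)
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        doc = {"capsid_version": _VERSION, "kind": kind, "records": records}
        validate_report(doc)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


# ---------------------------------------------------------------------------
# SVG rendering of net maps
# ---------------------------------------------------------------------------


def net_to_svg(net, scale: float = 40.0, margin: float = 30.0) -> str:
    """Serialize a NetMap as SVG: one <line> per dimer edge, one <circle>
    per capsomer copy and per stem-loop marker."""
    xs = [n["xy"][0] for n in net.nodes]
    ys = [n["xy"][1] for n in net.nodes]
    x0, y0 = min(xs), min(ys)
    w = (max(xs) - x0) * scale + 2 * margin
    h = (max(ys) - y0) * scale + 2 * margin

    def tx(p):
        return (p[0] - x0) * scale + margin, (p[1] - y0) * scale + margin

    xy = {n["id"]: tx(n["xy"]) for n in net.nodes}
    site_of = {n["id"]: n["site"] for n in net.nodes}
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" height="{h:.0f}" '
        f'viewBox="0 0 {w:.0f} {h:.0f}">'
    ]
    for e in net.edges:
        (xa, ya), (xb, yb) = xy[e["node_a"]], xy[e["node_b"]]
        color = "#333333" if e.get("dimer_class") == "A/B" else "#888888"
        parts.append(
            f'<line class="dimer" x1="{xa:.1f}" y1="{ya:.1f}" x2="{xb:.1f}" y2="{yb:.1f}" '
            f'stroke="{color}" stroke-width="3"/>'
        )
    for n in net.nodes:
        x, y = xy[n["id"]]
        lab = net.pentamer_labels.get(n["site"])
        fill = "#777777" if lab else "#ffffff"
        parts.append(
            f'<circle class="capsomer" cx="{x:.1f}" cy="{y:.1f}" r="5" fill="{fill}" '
            f'stroke="#000000"/>'
        )
        if lab:
            parts.append(
                f'<text x="{x + 6:.1f}" y="{y - 6:.1f}" font-size="10">{lab}</text>'
            )
    nm = max((m["color_index"] for m in net.markers), default=0) + 1
    for m in net.markers:
        x, y = tx(m["xy"])
        hue = int(240 * (1 - m["color_index"] / max(nm - 1, 1)))
        parts.append(
            f'<circle class="marker" cx="{x:.1f}" cy="{y:.1f}" r="4" '
            f'fill="hsl({hue},90%,50%)" stroke="#000000"/>'
        )
    parts.append("</svg>")
    return "\n".join(parts)


def cage_to_pseudo_pdb(cage, path, scale: float = 20.0) -> None:
    """One CA-style record per subunit origin, one chain per capsomer, for
    quick visualization of a cage."""
    pool = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
    if len(cage.sites) > len(pool):
        raise ValueError("too many capsomers for single-character PDB chain ids")
    model = StructureModel(name="cage")
    for s in cage.sites:
        ch = Chain(pool[s.id])
        for i, p in enumerate(cage.hexamer_subunits(s.id), start=1):
            r = Residue("GLY", i)
            r.atoms.append(Atom("CA", "C", p.origin * scale))
            ch.residues.append(r)
        model.chains.append(ch)
    write_structure(model, path, fmt="pdb")
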