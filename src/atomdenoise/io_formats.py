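"""Reading and writing the molecular formats the tool touches.

Small molecules come in as SDF/MOL V2000 (parsed here field-by-field so the
bond orders and ``M  CHG`` formal charges are under our control); protein and
complex structures come in as PDB via :mod:`gemmi`. Conformational ensembles
go out as multi-MODEL PDB files with per-atom confidence (sigma, Å) stored in
the B-factor column.

Polymer chemistry is expanded from an embedded residue-template dictionary
covering the 20 standard amino acids (atom names, elements, intra-residue
bonds and the inter-residue C→N link), so no external component dictionary is
needed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# elements we are prepared to see in inputs (hydrogens retained at parse time,
# stripped later when the chemical graph is built)
KNOWN_ELEMENTS = {
    "H", "B", "C", "N", "O", "F", "Na", "Mg", "Si", "P", "S", "Cl", "K", "Ca",
    "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Se", "Br", "I",
}

AROMATIC = "ar"

# legacy V2000 atom-block charge codes
_V2000_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


class ParseError(ValueError):
    """Raised when a molecular file cannot be interpreted."""


@dataclass
class MolRecord:
    """A molecule as read from file: atoms, bonds, optional 3-D coordinates."""

    name: str
    atoms: list  # (element, formal charge)
    bonds: list  # (i, j, order) with order in {1, 2, 3, "ar"}; each pair once
    coords: Optional[np.ndarray] = None  # (n, 3) Å
    atom_names: Optional[list] = None  # PDB atom names when applicable

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ParseError(f"bond ({i},{j}) references missing atom in {self.name!r}")
            if i == j:
                raise ParseError(f"self-bond on atom {i} in {self.name!r}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ParseError(f"duplicate bond {key} in {self.name!r}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, (el, _) in enumerate(self.atoms) if el != "H"], dtype=int)


@dataclass
class ResidueTemplate:
    name: str
    atom_names: list
    elements: list
    bonds: list  # (name_a, name_b, order)
    backbone: tuple = ("N", "CA", "C", "O")
    link: tuple = ("C", "N")  # inter-residue peptide bond


@dataclass
class Residue:
    name: str
    seqid: int
    icode: str
    atom_names: list
    elements: list
    coords: np.ndarray
    missing_backbone: list = field(default_factory=list)


@dataclass
class PolymerChain:
    chain_id: str
    residues: list


@dataclass
class PdbContents:
    chains: list  # PolymerChain
    hetero: list  # MolRecord (bonds empty; assigned later)
    n_models_skipped: int = 0


# ---------------------------------------------------------------------------
# residue templates
# ---------------------------------------------------------------------------

_TEMPLATES: Optional[dict] = None


def residue_templates() -> dict:
    """The embedded amino-acid template dictionary, keyed by 3-letter code."""
    global _TEMPLATES
    if _TEMPLATES is None:
        raw = json.loads(
            resources.files("atomdenoise.data").joinpath("residue_templates.json").read_text()
        )
        link = tuple(raw["link"])
        _TEMPLATES = {
            name: ResidueTemplate(
                name=name,
                atom_names=[a for a, _ in entry["atoms"]],
                elements=[e for _, e in entry["atoms"]],
                bonds=[(a, b, o) for a, b, o in entry["bonds"]],
                backbone=tuple(entry["backbone"]),
                link=link,
            )
            for name, entry in raw["residues"].items()
        }
    return _TEMPLATES


# ---------------------------------------------------------------------------
# SDF / MOL V2000
# ---------------------------------------------------------------------------

def read_sdf(path) -> list:
    """Read an SDF (or single MOL) file; returns one :class:`MolRecord` per record.

    Hydrogens are retained at this stage. Formal charges come from ``M  CHG``
    lines when present (which supersede the legacy atom-block column), else
    from the atom-block charge code.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    records = []
    pos = 0
    while pos < len(lines):
        # skip blank padding between records
        while pos < len(lines) and not lines[pos].strip() and not records:
            pos += 1
        if pos >= len(lines):
            break
        rest = [ln.strip() for ln in lines[pos:]]
        if all(not ln for ln in rest):
            break
        rec, pos = _parse_mol_block(lines, pos, path)
        records.append(rec)
        # advance past data items to the record terminator
        while pos < len(lines) and lines[pos].strip() != "$$$$":
            pos += 1
        pos += 1
    return records


def _parse_mol_block(lines, start, path):
    if start + 3 >= len(lines):
        raise ParseError(f"{path}: truncated MOL block at line {start + 1}")
    name = lines[start].strip()
    counts_line_no = start + 4  # 1-based line number of the counts line
    counts = lines[start + 3]
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: malformed counts line at line {counts_line_no}: {counts!r}")
    if n_atoms <= 0:
        raise ParseError(f"{path}: non-positive atom count at line {counts_line_no}")

    atoms, coords = [], []
    base = start + 4
    for k in range(n_atoms):
        ln = lines[base + k]
        try:
            x, y, z = float(ln[0:10]), float(ln[10:20]), float(ln[20:30])
            el = ln[31:34].strip()
            code = int(ln[36:39]) if ln[36:39].strip() else 0
        except (ValueError, IndexError):
            raise ParseError(f"{path}: malformed atom line at line {base + k + 1}")
        if el not in KNOWN_ELEMENTS:
            raise ParseError(f"{path}: unknown element {el!r} at line {base + k + 1}")
        atoms.append((el, _V2000_CHARGE.get(code, 0)))
        coords.append((x, y, z))

    bonds = []
    bbase = base + n_atoms
    for k in range(n_bonds):
        ln = lines[bbase + k]
        try:
            i, j, order = int(ln[0:3]) - 1, int(ln[3:6]) - 1, int(ln[6:9])
        except (ValueError, IndexError):
            raise ParseError(f"{path}: malformed bond line at line {bbase + k + 1}")
        bonds.append((i, j, AROMATIC if order == 4 else order))

    # properties block: M CHG supersedes all atom-block charges
    pos = bbase + n_bonds
    chg: Optional[dict] = None
    while pos < len(lines):
        ln = lines[pos]
        stripped = ln.strip()
        if stripped == "M  END" or stripped == "M END":
            pos += 1
            break
        if stripped == "$$$$":
            break
        if ln.startswith("M  CHG"):
            if chg is None:
                chg = {}
            fields = ln.split()
            count = int(fields[2])
            for c in range(count):
                idx = int(fields[3 + 2 * c]) - 1
                chg[idx] = int(fields[4 + 2 * c])
        pos += 1
    if chg is not None:
        atoms = [(el, chg.get(i, 0)) for i, (el, _) in enumerate(atoms)]

    arr = np.asarray(coords, dtype=float)
    has_coords = np.abs(arr).max() > 0 or n_atoms == 1
    rec = MolRecord(name=name or Path(str(path)).stem, atoms=atoms, bonds=bonds,
                    coords=arr if has_coords else None)
    return rec, pos


def write_sdf(records: Sequence[MolRecord], path) -> None:
    """Write records as an SDF file (V2000, one ``$$$$``-terminated block each)."""
    out = []
    for rec in records:
        coords = rec.coords if rec.coords is not None else np.zeros((rec.n_atoms, 3))
        out.append(rec.name)
        out.append("  atomdenoise")
        out.append("")
        out.append(f"{rec.n_atoms:3d}{len(rec.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
        for (el, _), (x, y, z) in zip(rec.atoms, coords):
            out.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {el:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
        for i, j, order in rec.bonds:
            o = 4 if order == AROMATIC else int(order)
            out.append(f"{i + 1:3d}{j + 1:3d}{o:3d}  0  0  0  0")
        charged = [(i, c) for i, (_, c) in enumerate(rec.atoms) if c != 0]
        for k in range(0, len(charged), 8):
            chunk = charged[k:k + 8]
            ln = f"M  CHG{len(chunk):3d}"
            for i, c in chunk:
                ln += f"{i + 1:4d}{c:4d}"
            out.append(ln)
        out.append("M  END")
        out.append("$$$$")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_WATERS = {"HOH", "WAT", "DOD"}


def read_pdb(path) -> PdbContents:
    """Read a PDB file into polymer chains and hetero groups.

    Only the first MODEL is read (the number skipped is logged). Alternate
    locations are resolved to the highest-occupancy copy, ties broken by file
    order. HETATM groups come back as :class:`MolRecord` without bonds —
    ligand bonds are assigned later from a companion SDF or a residue
    template; waters are dropped. A polymer residue missing any backbone atom
    is flagged on the residue, not dropped.
    """
    import gemmi

    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    n_skipped = max(0, len(st) - 1)
    if n_skipped:
        logger.info("read_pdb(%s): %d additional models skipped", path, n_skipped)
    model = st[0]
    templates = residue_templates()

    chains, hetero = [], []
    for chain in model:
        residues = []
        for res in chain:
            picked = _resolve_altlocs(res)
            names = [a.name for a in picked]
            els = [a.element.name for a in picked]
            xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in picked], dtype=float)
            seqid = res.seqid.num
            icode = (res.seqid.icode or " ").strip()
            if res.name in templates:
                tmpl = templates[res.name]
                missing = [b for b in tmpl.backbone if b not in names]
                if missing:
                    logger.warning(
                        "read_pdb(%s): residue %s %s%d missing backbone atoms %s",
                        path, res.name, chain.name, seqid, missing,
                    )
                residues.append(Residue(res.name, seqid, icode, names, els, xyz, missing))
            elif res.name in _WATERS:
                continue
            else:
                for el in els:
                    if el not in KNOWN_ELEMENTS:
                        raise ParseError(f"{path}: unknown element {el!r} in {res.name}")
                hetero.append(
                    MolRecord(
                        name=f"{res.name}_{chain.name}{seqid}{icode}".rstrip("_ "),
                        atoms=[(el, 0) for el in els],
                        bonds=[],
                        coords=xyz,
                        atom_names=names,
                    )
                )
        if residues:
            chains.append(PolymerChain(chain.name, residues))
    return PdbContents(chains=chains, hetero=hetero, n_models_skipped=n_skipped)


def _resolve_altlocs(res):
    """Highest-occupancy altloc per atom name; ties broken by file order."""
    best = {}
    order = []
    for atom in res:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[n] for n in order]


def write_pdb_ensemble(models, graph, path, bfactors=None) -> None:
    """Write an ensemble as a multi-MODEL PDB.

    `models` are :class:`~atomdenoise.chemgraph.Conformation` objects sharing
    the graph's atom count; `bfactors` (optional, one per-atom array per
    model) fills the B-factor column — by convention the per-atom predicted
    deviation sigma_i in Å.
    """
    if len(models) == 0:
        raise ValueError("cannot write an ensemble of 0 models")
    n = len(graph.atoms)
    for m, conf in enumerate(models):
        if conf.coords.shape[0] != n:
            raise ValueError(
                f"model {m} has {conf.coords.shape[0]} atoms, system has {n}"
            )
    lines = []
    for m, conf in enumerate(models):
        lines.append(f"MODEL     {m + 1:4d}")
        bf = None if bfactors is None else np.asarray(bfactors[m], dtype=float)
        serial = 0
        for i, atom in enumerate(graph.atoms):
            serial += 1
            x, y, z = conf.coords[i]
            record = "HETATM" if atom.role == "ligand" else "ATOM  "
            name = atom.name if atom.name else f"{atom.element}{i + 1}"
            # PDB name alignment: element right-justified into columns 13-14
            pdb_name = name if len(name) == 4 else f" {name:<3s}"
            b = 0.0 if bf is None else float(bf[i])
            icode = atom.icode or ""
            lines.append(
                f"{record}{serial:5d} {pdb_name:<4s}"
                f" {atom.resname:<3s} {atom.chain:1s}{atom.resnum:4d}{icode:1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b:6.2f}"
                f"          {atom.element:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
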