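"""Atom-level chemical graphs.

Everything downstream — corruption, losses, the denoising network — sees a
molecular system only through this one representation: nodes are individual
heavy atoms, edges are chemical bonds. Polymers are expanded from residue
templates (with peptide C→N links between consecutive residues), ligands
bring their own bonds, hydrogens are stripped on construction.

Each pair of atoms carries a *bond separation*: the number of covalent bonds
on the shortest path in the graph, with a sentinel for atoms in different
covalent components. Chiral centers are stored as (O, A, B, C) index tuples
with a target handedness sign read off the reference geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .io_formats import AROMATIC, MolRecord, PolymerChain, residue_templates

logger = logging.getLogger(__name__)

#: sentinel bond separation for atoms in different covalent components
UNCONNECTED = 2**30

#: ideal magnitude of the chirality pseudoscalar for tetrahedral geometry
V_IDEAL_MAGNITUDE = 4.0 / (3.0 * np.sqrt(3.0))

_CHIRAL_ELEMENTS = {"C", "N", "P", "S"}


@dataclass
class Atom:
    element: str
    charge: int = 0
    role: str = "ligand"  # backbone | sidechain | ligand
    chain: str = "A"
    resnum: int = 1
    icode: str = ""
    resname: str = "LIG"
    name: str = ""
    group: int = 0  # residue / ligand-record index, used by crop & corruption


@dataclass
class ChiralCenter:
    """(O, A, B, C) with O the central pyramidal/tetrahedral atom.

    ``sign`` is the handedness observed in the reference structure; the ideal
    pseudoscalar value is ``sign * 4/(3*sqrt(3))``.
    """

    center: int
    a: int
    b: int
    c: int
    sign: int

    @property
    def v_ideal(self) -> float:
        return self.sign * V_IDEAL_MAGNITUDE

    @property
    def indices(self):
        return (self.center, self.a, self.b, self.c)


@dataclass
class Conformation:
    """Per-atom coordinates (Å) with a resolved/placed mask."""

    coords: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.mask is None:
            self.mask = np.ones(len(self.coords), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool).reshape(-1)
        if self.mask.any() and not np.isfinite(self.coords[self.mask]).all():
            raise ValueError("non-finite coordinates on resolved atoms")

    def copy(self) -> "Conformation":
        return Conformation(self.coords.copy(), self.mask.copy())


@dataclass
class ChemGraph:
    atoms: list  # Atom
    bonds: list  # (i, j, order), each pair once, i < j
    chiral_centers: list = field(default_factory=list)
    group_kinds: dict = field(default_factory=dict)  # group id -> "residue" | "ligand"

    def __post_init__(self):
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j})")

    @property
    def bond_separation(self) -> np.ndarray:
        """Covalent-bond counts on shortest paths; UNCONNECTED sentinel for
        atoms in different components. Computed lazily (dense n × n)."""
        if not hasattr(self, "_sep"):
            self._sep, self._comp = _bond_separation(self.n_atoms, self.bonds)
        return self._sep

    @property
    def components(self) -> np.ndarray:
        if not hasattr(self, "_comp"):
            self.bond_separation
        return self._comp

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list:
        return self._adjacency()[i]

    def _adjacency(self):
        if not hasattr(self, "_adj"):
            adj = [[] for _ in range(self.n_atoms)]
            for i, j, _ in self.bonds:
                adj[i].append(j)
                adj[j].append(i)
            self._adj = [sorted(a) for a in adj]
        return self._adj

    def bond_order_matrix(self) -> np.ndarray:
        """Dense order matrix; aromatic encoded as 1.5, no bond as 0."""
        m = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, order in self.bonds:
            o = 1.5 if order == AROMATIC else float(order)
            m[i, j] = m[j, i] = o
        return m

    def roles(self) -> np.ndarray:
        return np.array([a.role for a in self.atoms])

    def groups(self) -> np.ndarray:
        return np.array([a.group for a in self.atoms], dtype=int)


def _bond_separation(n, bonds):
    if n == 0:
        return np.zeros((0, 0), dtype=np.int64), np.zeros(0, dtype=int)
    rows = [i for i, j, _ in bonds] + [j for i, j, _ in bonds]
    cols = [j for i, j, _ in bonds] + [i for i, j, _ in bonds]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="BF", unweighted=True, directed=False)
    _, labels = connected_components(adj, directed=False)
    sep = np.where(np.isinf(dist), UNCONNECTED, dist).astype(np.int64)
    return sep, labels


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_chemgraph(
    chains: Sequence[PolymerChain] = (),
    ligands: Sequence[MolRecord] = (),
) -> tuple:
    """Build the heavy-atom graph for polymer chains plus ligand records.

    Returns ``(graph, reference)`` where the reference
    :class:`Conformation` is masked False for template atoms without input
    coordinates. Hydrogens are removed; peptide C→N bonds are added between
    consecutive residues of each chain.
    """
    templates = residue_templates()
    atoms: list = []
    bonds: list = []
    coords: list = []
    mask: list = []
    group_kinds: dict = {}
    group = 0

    for chain in chains:
        prev_c: Optional[int] = None
        for res in chain.residues:
            if res.name not in templates:
                raise ValueError(f"no template for residue {res.name!r} "
                                 f"({chain.chain_id}{res.seqid})")
            tmpl = templates[res.name]
            index_of = {}
            present = dict(zip(res.atom_names, range(len(res.atom_names))))
            extra = [n for n in res.atom_names
                     if n not in tmpl.atom_names and not n.startswith("H")]
            if extra:
                logger.info("residue %s %s%d: ignoring non-template atoms %s",
                            res.name, chain.chain_id, res.seqid, extra)
            for name, el in zip(tmpl.atom_names, tmpl.elements):
                idx = len(atoms)
                index_of[name] = idx
                role = "backbone" if name in tmpl.backbone else "sidechain"
                atoms.append(Atom(element=el, role=role, chain=chain.chain_id,
                                  resnum=res.seqid, icode=res.icode,
                                  resname=res.name, name=name, group=group))
                if name in present:
                    coords.append(res.coords[present[name]])
                    mask.append(True)
                else:
                    coords.append(np.zeros(3))
                    mask.append(False)
            for a, b, order in tmpl.bonds:
                i, j = index_of[a], index_of[b]
                bonds.append((min(i, j), max(i, j), order))
            if prev_c is not None:
                i, j = prev_c, index_of[tmpl.link[1]]
                # guard against chain breaks: only link when the peptide
                # bond geometry is plausible (or coordinates are missing)
                ok = True
                if mask[i] and mask[j]:
                    ok = np.linalg.norm(np.asarray(coords[i])
                                        - np.asarray(coords[j])) < 2.5
                if ok:
                    bonds.append((min(i, j), max(i, j), 1))
                else:
                    logger.info("chain %s: no peptide bond %d-%d (distance)",
                                chain.chain_id, i, j)
            prev_c = index_of[tmpl.link[0]]
            group_kinds[group] = "residue"
            group += 1

    for lig in ligands:
        if not lig.bonds and lig.n_atoms > 1:
            raise ValueError(
                f"ligand {lig.name!r} carries no bonds; supply a companion SDF "
                "or a residue template (distance-based bond perception is not done)"
            )
        heavy = lig.heavy_indices()
        remap = {int(old): k for k, old in enumerate(heavy)}
        offset = len(atoms)
        for k, old in enumerate(heavy):
            el, chg = lig.atoms[old]
            name = (lig.atom_names[old] if lig.atom_names else f"{el}{k + 1}")
            atoms.append(Atom(element=el, charge=chg, role="ligand", chain="X",
                              resnum=group + 1, resname=lig.name[:3].upper() or "LIG",
                              name=name, group=group))
            if lig.coords is not None:
                coords.append(lig.coords[old])
                mask.append(True)
            else:
                coords.append(np.zeros(3))
                mask.append(False)
        for i, j, order in lig.bonds:
            if i in remap and j in remap:
                a, b = offset + remap[i], offset + remap[j]
                bonds.append((min(a, b), max(a, b), order))
        group_kinds[group] = "ligand"
        group += 1

    graph = ChemGraph(atoms=atoms, bonds=sorted(set((i, j, o) for i, j, o in bonds)),
                      group_kinds=group_kinds)
    ref = Conformation(np.array(coords).reshape(-1, 3), np.array(mask, dtype=bool))
    return graph, ref


# ---------------------------------------------------------------------------
# chirality perception
# ---------------------------------------------------------------------------

def _branch_signature(graph: ChemGraph, start: int, exclude: int, depth: int = 4):
    """BFS-level signature of the substituent branch rooted at `start`,
    walking away from `exclude`; used for the substituent-distinctness test."""
    adj = graph._adjacency()
    level = {start}
    visited = {exclude, start}
    sig = [(graph.atoms[start].element, graph.atoms[start].charge)]
    for _ in range(depth):
        nxt = set()
        for u in level:
            for v in adj[u]:
                if v not in visited:
                    nxt.add(v)
                    visited.add(v)
        if not nxt:
            break
        sig.append(tuple(sorted((graph.atoms[v].element, graph.atoms[v].charge)
                                for v in nxt)))
        level = nxt
    return tuple(sig)


def perceive_chirality(
    graph: ChemGraph,
    reference: Conformation,
    planarity_tol: float = 0.1,
) -> list:
    """Detect stereogenic centers and read their handedness off the reference.

    Candidates are C/N/P/S atoms with >= 3 heavy neighbors whose substituent
    branches are pairwise distinct (subgraph distinctness to depth 4).
    (A, B, C) are the three lowest-index neighbors in ascending order; the
    target sign is the sign of the triple product V in the reference
    structure. Near-planar candidates (|V| < `planarity_tol`) are excluded.
    """
    from .geometry import triple_product_V

    centers = []
    for o, atom in enumerate(graph.atoms):
        if atom.element not in _CHIRAL_ELEMENTS:
            continue
        nbrs = graph.neighbors(o)
        if len(nbrs) < 3 or len(nbrs) > 4:
            continue
        sigs = [_branch_signature(graph, x, o) for x in nbrs]
        if len(set(sigs)) != len(sigs):
            continue
        if not (reference.mask[o] and all(reference.mask[x] for x in nbrs)):
            continue
        a, b, c = sorted(nbrs)[:3]
        v = triple_product_V(reference.coords[o], reference.coords[a],
                             reference.coords[b], reference.coords[c])
        if abs(v) < planarity_tol:
            logger.info("atom %d (%s): near-planar center excluded (|V|=%.3f)",
                        o, atom.element, abs(v))
            continue
        centers.append(ChiralCenter(center=o, a=a, b=b, c=c, sign=int(np.sign(v))))
    return centers


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def crop(
    graph: ChemGraph,
    conformation: Conformation,
    center_atom: int,
    max_atoms: int,
) -> tuple:
    """Spatial crop around `center_atom`, keeping residues/ligands whole.

    Groups (residues or ligand components) are considered in order of their
    nearest atom to the center; a group is included whole if it fits within
    the cap, otherwise skipped. Returns ``(subgraph, index_map)`` where
    ``index_map[new] = old``.
    """
    if max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")
    if not conformation.mask[center_atom]:
        raise ValueError(f"center atom {center_atom} unresolved in conformation")
    d = np.linalg.norm(conformation.coords - conformation.coords[center_atom], axis=1)
    d = np.where(conformation.mask, d, np.inf)
    groups = graph.groups()
    group_size = {g: int((groups == g).sum()) for g in np.unique(groups)}
    chosen: list = []
    decided: set = set()
    budget = max_atoms
    for idx in np.argsort(d, kind="stable"):
        g = int(groups[idx])
        if g in decided:
            continue
        decided.add(g)
        if group_size[g] <= budget:
            chosen.append(g)
            budget -= group_size[g]
        if budget == 0:
            break
    keep = np.where(np.isin(groups, chosen))[0]
    return _subgraph(graph, keep), keep


def _subgraph(graph: ChemGraph, keep: np.ndarray) -> ChemGraph:
    remap = {int(old): new for new, old in enumerate(keep)}
    atoms = [replace(graph.atoms[int(old)]) for old in keep]
    bonds = [(remap[i], remap[j], o) for i, j, o in graph.bonds
             if i in remap and j in remap]
    centers = [
        ChiralCenter(remap[cc.center], remap[cc.a], remap[cc.b], remap[cc.c], cc.sign)
        for cc in graph.chiral_centers
        if all(x in remap for x in cc.indices)
    ]
    kinds = {graph.atoms[int(old)].group: graph.group_kinds.get(graph.atoms[int(old)].group)
             for old in keep}
    return ChemGraph(atoms=atoms, bonds=bonds, chiral_centers=centers, group_kinds=kinds)
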