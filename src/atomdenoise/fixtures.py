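"""Synthetic molecules, peptides and toy binding pockets with exact ground truth.

Desk-scale stand-ins for curated crystal-structure training data: idealized
geometry (default bond length 1.5 Å, tetrahedral angle 109.47°) rather than
force-field minima, so that oracle tests have exact expected coordinates and
the micro-network has a self-consistent target to learn.

Every fixture is a pure function of its :class:`FixtureSpec` (including the
seed). Toy pockets use pseudo-residues with real backbone atom names (N, CA,
C, O) so cropping, corruption and selection code paths run unmodified.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .chemgraph import ChemGraph, Conformation, build_chemgraph, perceive_chirality
from .io_formats import MolRecord, PolymerChain, Residue

TETRAHEDRAL_ANGLE = 109.47122063449069  # degrees

# unit vectors to the vertices of a regular tetrahedron
_TET = np.array([
    [1.0, 1.0, 1.0],
    [1.0, -1.0, -1.0],
    [-1.0, 1.0, -1.0],
    [-1.0, -1.0, 1.0],
]) / np.sqrt(3.0)


@dataclass
class FixtureSpec:
    kind: str  # chain | ring | branched | chiral | macrocycle | dipeptide | toy-pocket
    size: int = 6
    bond_length: float = 1.5  # Å
    bond_angle: float = TETRAHEDRAL_ANGLE  # degrees
    seed: int = 0
    sign: int = +1  # requested handedness for chiral fixtures
    elements: Optional[list] = None
    n_residues: int = 24  # toy pockets
    ligand_size: int = 6  # toy pockets

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def nerf_place(a, b, c, r, theta_deg, phi_deg) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D.

    D is bonded to `c` with length `r`, angle b–c–D = `theta_deg`, torsion
    a–b–c–D = `phi_deg`.
    """
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -r * np.cos(theta),
        r * np.sin(theta) * np.cos(phi),
        r * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _cycle_elements(n, elements, default=("C", "C", "N", "C", "O")):
    pat = elements if elements else list(default)
    return [pat[i % len(pat)] for i in range(n)]


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------

def _chain_coords(n, length, angle_deg):
    half = np.radians(angle_deg) / 2.0
    d_even = np.array([np.sin(half), np.cos(half), 0.0]) * length
    d_odd = np.array([np.sin(half), -np.cos(half), 0.0]) * length
    coords = [np.zeros(3)]
    for i in range(1, n):
        coords.append(coords[-1] + (d_even if i % 2 else d_odd))
    return np.array(coords)


def _ring_coords(n, length):
    # regular n-gon with side `length`, in the z=0 plane
    radius = length / (2.0 * np.sin(np.pi / n))
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])


def make_molecule(spec: FixtureSpec):
    """Build a fixture molecule; returns ``(ChemGraph, Conformation)``.

    Chiral fixtures carry the requested handedness sign; rings and loops
    close exactly (closure error < 1e-6 Å by construction).
    """
    kind = spec.kind
    L = spec.bond_length
    if kind == "chain":
        if spec.size < 2:
            raise ValueError("chain needs >= 2 atoms")
        els = _cycle_elements(spec.size, spec.elements)
        coords = _chain_coords(spec.size, L, spec.bond_angle)
        bonds = [(i, i + 1, 1) for i in range(spec.size - 1)]
    elif kind in ("ring", "macrocycle"):
        if spec.size < 3:
            raise ValueError(f"{kind} of {spec.size} atoms is infeasible")
        els = _cycle_elements(spec.size, spec.elements)
        coords = _ring_coords(spec.size, L)
        bonds = [(i, (i + 1) % spec.size, 1) for i in range(spec.size)]
        bonds = [(min(i, j), max(i, j), o) for i, j, o in bonds]
    elif kind == "branched":
        k = min(max(spec.size - 1, 2), 4)
        els = ["C"] + _cycle_elements(k, spec.elements, default=("C", "N", "O", "S"))
        coords = np.vstack([np.zeros(3), _TET[:k] * L])
        bonds = [(0, i + 1, 1) for i in range(k)]
    elif kind == "chiral":
        # central carbon with four distinct single-atom substituents
        els = ["C", "N", "O", "S", "F"]
        coords = np.vstack([np.zeros(3), _TET * L])
        bonds = [(0, i + 1, 1) for i in range(4)]
        if spec.sign not in (-1, 1):
            raise ValueError("chiral sign must be +1 or -1")
    elif kind == "dipeptide":
        return _make_dipeptide()
    elif kind == "toy-pocket":
        pocket = make_toy_pocket(spec)
        return pocket.graph, pocket.reference
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    rec = MolRecord(name=f"{kind}{spec.size}", atoms=[(e, 0) for e in els],
                    bonds=bonds, coords=np.asarray(coords, dtype=float))
    graph, ref = build_chemgraph(ligands=[rec])
    graph.chiral_centers = perceive_chirality(graph, ref)
    if kind == "chiral":
        assert len(graph.chiral_centers) == 1
        if graph.chiral_centers[0].sign != spec.sign:
            ref.coords[:, 0] *= -1.0  # mirror to the requested handedness
            graph.chiral_centers = perceive_chirality(graph, ref)
        assert graph.chiral_centers[0].sign == spec.sign
    return graph, ref


# ideal peptide internal coordinates (Å, degrees)
_PEP = dict(n_ca=1.458, ca_c=1.525, c_o=1.231, c_n=1.329, ca_cb=1.521,
            ang_n_ca_c=111.0, ang_ca_c_o=120.8, ang_ca_c_n=116.6,
            ang_c_n_ca=121.7, ang_n_ca_cb=110.4)


def _make_dipeptide():
    """Ala–Ala with idealized geometry and L-configured alpha carbons."""
    p = _PEP
    phi, psi, omega = -140.0, 135.0, 180.0
    n1 = np.zeros(3)
    ca1 = np.array([p["n_ca"], 0.0, 0.0])
    c1 = nerf_place(np.array([0.0, -1.0, 0.0]), n1, ca1,
                    p["ca_c"], p["ang_n_ca_c"], 120.0)
    o1 = nerf_place(n1, ca1, c1, p["c_o"], p["ang_ca_c_o"], psi + 180.0)
    cb1 = nerf_place(c1, n1, ca1, p["ca_cb"], p["ang_n_ca_cb"], -122.0)
    n2 = nerf_place(n1, ca1, c1, p["c_n"], p["ang_ca_c_n"], psi)
    ca2 = nerf_place(ca1, c1, n2, p["n_ca"], p["ang_c_n_ca"], omega)
    c2 = nerf_place(c1, n2, ca2, p["ca_c"], p["ang_n_ca_c"], phi)
    o2 = nerf_place(n2, ca2, c2, p["c_o"], p["ang_ca_c_o"], psi + 180.0)
    cb2 = nerf_place(c2, n2, ca2, p["ca_cb"], p["ang_n_ca_cb"], -122.0)

    def res(seq, n, ca, c, o, cb):
        return Residue("ALA", seq, "", ["N", "CA", "C", "O", "CB"],
                       ["N", "C", "C", "O", "C"], np.vstack([n, ca, c, o, cb]))

    chain = PolymerChain("A", [res(1, n1, ca1, c1, o1, cb1),
                               res(2, n2, ca2, c2, o2, cb2)])
    graph, ref = build_chemgraph(chains=[chain])
    graph.chiral_centers = perceive_chirality(graph, ref)
    return graph, ref


# ---------------------------------------------------------------------------
# toy pockets
# ---------------------------------------------------------------------------

@dataclass
class ToyPocket:
    graph: ChemGraph
    reference: Conformation
    ligand_group: int
    spec: FixtureSpec = field(default=None)

    def ligand_atoms(self) -> np.ndarray:
        return np.where(self.graph.groups() == self.ligand_group)[0]


_POCKET_RESNAMES = ("ALA", "SER", "CYS", "VAL")


def make_toy_pocket(spec: FixtureSpec) -> ToyPocket:
    """A rigid pseudo-residue cage enclosing a cavity with a small ligand.

    Pseudo-residues (backbone N, CA, C, O plus 1–3 side-chain atoms, real
    atom names) sit on a sphere with side chains pointing inward; the ligand
    (ring) is placed at the cavity center in a seeded random orientation.
    Regenerated (fresh sub-seed) up to 10 times if any pocket–ligand contact
    falls below 2 Å; requires >= 3 pocket atoms within 4 Å of the ligand.
    """
    if not (4 <= spec.ligand_size <= 12):
        raise ValueError("ligand_size must be in [4, 12]")
    if not (8 <= spec.n_residues <= 60):
        raise ValueError("n_residues must be in [8, 60]")
    rng = np.random.default_rng(spec.seed)
    last_err = None
    for _attempt in range(10):
        try:
            return _build_pocket(spec, rng)
        except ValueError as err:  # clash; retry with fresh sub-seed
            last_err = err
    raise ValueError(f"could not build clash-free pocket: {last_err}")


def _build_pocket(spec: FixtureSpec, rng) -> ToyPocket:
    from .io_formats import residue_templates

    templates = residue_templates()
    n_res = spec.n_residues
    # Fibonacci sphere for even coverage, deformed to an ellipsoid with
    # per-residue radius jitter: real pockets are asymmetric, and the
    # asymmetry is what lets contact patterns distinguish ligand poses
    idx = np.arange(n_res) + 0.5
    phi = np.arccos(1.0 - 2.0 * idx / n_res)
    theta = np.pi * (1.0 + 5**0.5) * idx
    radii = 7.0 + rng.uniform(-0.8, 0.8, size=n_res)
    axes = np.array([1.0, 0.88, 1.15])
    centers = radii[:, None] * axes * np.column_stack([
        np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)])

    chains = []
    for r_i, ca in enumerate(centers):
        resname = _POCKET_RESNAMES[r_i % len(_POCKET_RESNAMES)]
        tmpl = templates[resname]
        inward = -ca / np.linalg.norm(ca)
        # local frame: x inward, y/z arbitrary orthogonal (seeded jitter)
        ref_vec = rng.normal(size=3)
        y = np.cross(inward, ref_vec)
        y /= np.linalg.norm(y)
        z = np.cross(inward, y)
        n = ca + 1.458 * y
        c = ca + 1.525 * (np.cos(np.radians(111.0)) * y
                          + np.sin(np.radians(111.0)) * z)
        o = nerf_place(n, ca, c, 1.231, 120.8, 0.0)
        coords = {"N": n, "CA": ca, "C": c, "O": o}
        if "CB" in tmpl.atom_names:
            coords["CB"] = ca + 1.521 * inward
        for name in tmpl.atom_names:
            if name in coords:
                continue
            # walk remaining side-chain atoms further inward with jitter
            parent = next(a for a, b, _ in tmpl.bonds if b == name)
            jitter = rng.normal(scale=0.25, size=3)
            step = 1.5 * inward + jitter
            coords[name] = coords[parent] + step / np.linalg.norm(step) * 1.5
        names = list(tmpl.atom_names)
        alphabet = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                    "abcdefghijklmnopqrstuvwxyz0123456789")
        chains.append(PolymerChain(alphabet[r_i % len(alphabet)], [Residue(
            resname, r_i + 1, "", names,
            [tmpl.elements[tmpl.atom_names.index(nm)] for nm in names],
            np.vstack([coords[nm] for nm in names]))]))
    lig_coords = _ring_coords(spec.ligand_size, spec.bond_length)
    rot = _random_rotation(rng)
    lig_coords = lig_coords @ rot.T
    lig = MolRecord(
        name="LIG",
        atoms=[(e, 0) for e in _cycle_elements(spec.ligand_size, spec.elements,
                                               default=("C", "C", "N", "C", "C", "O"))],
        bonds=[(min(i, (i + 1) % spec.ligand_size), max(i, (i + 1) % spec.ligand_size), 1)
               for i in range(spec.ligand_size)],
        coords=lig_coords,
    )
    graph, ref = build_chemgraph(chains=chains, ligands=[lig])
    graph.chiral_centers = perceive_chirality(graph, ref)
    lig_group = int(graph.groups().max())
    lig_atoms = np.where(graph.groups() == lig_group)[0]
    pocket_atoms = np.where(graph.groups() != lig_group)[0]
    d = np.linalg.norm(ref.coords[pocket_atoms][:, None, :]
                       - ref.coords[lig_atoms][None, :, :], axis=-1)
    if d.min() < 2.0:
        raise ValueError(f"pocket-ligand clash at {d.min():.2f} Å")
    if (d.min(axis=1) < 4.0).sum() < 3:
        raise ValueError("fewer than 3 pocket contacts within 4 Å")
    return ToyPocket(graph=graph, reference=ref, ligand_group=lig_group, spec=spec)


def _random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


# ---------------------------------------------------------------------------
# training sets
# ---------------------------------------------------------------------------

def make_training_set(n: int, seed: int = 0) -> list:
    """A mixed fixture dataset: ``[(spec, graph, reference), ...]``.

    Cycles through chains, rings, branched centers and an enantiomer pair
    (always present once n >= 6); deterministic in (n, seed).
    """
    if n > 50:
        raise ValueError("desk-scale training sets are capped at 50 systems")
    recipe = [
        FixtureSpec("chain", size=5, seed=seed),
        FixtureSpec("ring", size=6, seed=seed),
        FixtureSpec("branched", size=5, seed=seed),
        FixtureSpec("chiral", sign=+1, seed=seed),
        FixtureSpec("chiral", sign=-1, seed=seed),
        FixtureSpec("chain", size=7, elements=["C", "O", "C", "N"], seed=seed),
        FixtureSpec("ring", size=5, elements=["C", "C", "O"], seed=seed),
        FixtureSpec("macrocycle", size=10, seed=seed),
        FixtureSpec("dipeptide", seed=seed),
        FixtureSpec("chain", size=4, elements=["N", "C", "C", "O"], seed=seed),
    ]
    out = []
    for i in range(n):
        spec = recipe[i % len(recipe)]
        if i >= len(recipe):  # vary sizes on later laps, reproducibly
            spec = FixtureSpec("chain", size=4 + (i * 3 + seed) % 6,
                               elements=["C", "N"], seed=seed + i)
        graph, ref = make_molecule(spec)
        out.append((spec, graph, ref))
    return out


def train_val_split(items) -> list:
    """'val' for specs whose hash lands in the 1-in-5 bucket, else 'train'."""
    return ["val" if int(spec.hash(), 16) % 5 == 0 else "train"
            for spec, _, _ in items]
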