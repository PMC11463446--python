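"""Stochastic input corruption: the denoising task definition.

Training corruption collapses every connected component onto an anchor —
side chains onto the backbone atom they hang from, ligands onto one randomly
chosen atom — and then adds i.i.d. Gaussian noise (default σ = 1.5 Å per
coordinate) to all atoms. Docking-style corruption rebuilds the ligand from
a single noised anchor point so that neither its internal structure nor its
orientation is recoverable from the input, randomizes protein side chains
around their Cα, and leaves the backbone untouched.

Every mode is a pure function of (input, seed): one random stream per call,
consumed in documented order (group order, then atom order), so results
reproduce across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chemgraph import ChemGraph, Conformation

MODES = ("training", "docking", "sidechain")


@dataclass
class CorruptionConfig:
    noise_sigma: float = 1.5  # Å, per coordinate
    mode: str = "training"
    seed: int = 0
    crop_max_atoms: int = 600

    def __post_init__(self):
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


def _check_resolved(graph: ChemGraph, reference: Conformation, atoms=None):
    idx = np.arange(graph.n_atoms) if atoms is None else np.asarray(atoms)
    if not reference.mask[idx].all():
        bad = idx[~reference.mask[idx]]
        raise ValueError(f"unresolved reference atoms {bad.tolist()[:5]} in corruption input")


def backbone_anchor_map(graph: ChemGraph) -> dict:
    """For each side-chain atom, the backbone atom it transitively hangs from.

    BFS within the atom's residue from the backbone set through side-chain
    atoms; for standard amino acids every side-chain atom maps to CA.
    """
    roles = graph.roles()
    groups = graph.groups()
    anchors: dict = {}
    for g in np.unique(groups):
        if graph.group_kinds.get(int(g)) != "residue":
            continue
        members = np.where(groups == g)[0]
        bb = [int(i) for i in members if roles[i] == "backbone"]
        frontier = list(bb)
        root = {i: i for i in bb}
        member_set = set(int(i) for i in members)
        while frontier:
            nxt = []
            for u in frontier:
                for v in graph.neighbors(u):
                    if v in member_set and v not in root:
                        root[v] = root[u] if roles[u] != "backbone" else u
                        nxt.append(v)
            frontier = nxt
        for i in members:
            if roles[i] == "sidechain" and int(i) in root:
                anchors[int(i)] = root[int(i)]
    return anchors


def corrupt(graph: ChemGraph, reference: Conformation, config: CorruptionConfig,
            ligand_group: Optional[int] = None, anchor: Optional[np.ndarray] = None,
            seed: Optional[int] = None) -> Conformation:
    """Dispatch on ``config.mode``; `seed` overrides ``config.seed`` when given."""
    s = config.seed if seed is None else seed
    if config.mode == "training":
        return corrupt_training(graph, reference, config, seed=s)
    if config.mode == "docking":
        if ligand_group is None:
            lig = [g for g, k in graph.group_kinds.items() if k == "ligand"]
            if len(lig) != 1:
                raise ValueError("docking mode needs a unique ligand component "
                                 "(pass ligand_group)")
            ligand_group = lig[0]
        return corrupt_docking(graph, reference, ligand_group, config,
                               anchor=anchor, seed=s)
    return corrupt_sidechain(graph, reference, config, seed=s)


def corrupt_training(graph: ChemGraph, reference: Conformation,
                     config: CorruptionConfig, seed: Optional[int] = None,
                     return_collapsed: bool = False):
    """Collapse-to-anchor plus Gaussian noise on *all* atoms (backbone included).

    Residues: each side-chain atom moves to the backbone atom it hangs from.
    Ligand components: all atoms move to one uniformly selected atom.
    Then i.i.d. N(0, σ²) noise per coordinate on every atom.

    With ``return_collapsed=True`` also returns the collapsed pre-noise
    coordinates, so the added displacement can be measured directly.
    """
    _check_resolved(graph, reference)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    coords = reference.coords.copy()
    groups = graph.groups()
    anchors = backbone_anchor_map(graph)
    for g in sorted(np.unique(groups)):
        members = np.where(groups == g)[0]
        if graph.group_kinds.get(int(g)) == "ligand":
            pick = members[rng.integers(len(members))]
            coords[members] = reference.coords[pick]
        else:
            for i in members:
                if int(i) in anchors:
                    coords[i] = reference.coords[anchors[int(i)]]
    collapsed = coords.copy()
    coords = coords + rng.normal(0.0, config.noise_sigma, size=coords.shape)
    out = Conformation(coords, np.ones(graph.n_atoms, dtype=bool))
    if return_collapsed:
        return out, collapsed
    return out


def corrupt_docking(graph: ChemGraph, reference: Conformation, ligand_group: int,
                    config: CorruptionConfig, anchor: Optional[np.ndarray] = None,
                    seed: Optional[int] = None) -> Conformation:
    """Docking-time initialization.

    Ligand: one anchor position (a randomly chosen reference ligand atom, or
    the user-supplied point when no reference pose exists) is noised with
    N(0, σ²); all ligand atoms are collapsed onto it; uncorrelated N(0, σ²)
    noise is then added to every ligand atom. Protein side chains are
    randomized around their residue's Cα; the backbone is kept exactly.
    """
    groups = graph.groups()
    lig = np.where(groups == ligand_group)[0]
    if len(lig) == 0:
        raise ValueError(f"ligand component {ligand_group} not found")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sigma = config.noise_sigma
    roles = graph.roles()
    protein = np.where(groups != ligand_group)[0]
    _check_resolved(graph, reference, protein)

    coords = reference.coords.copy()
    # step 1: anchor point
    if anchor is not None:
        anchor_pos = np.asarray(anchor, dtype=float)
    elif reference.mask[lig].all():
        anchor_pos = reference.coords[lig[rng.integers(len(lig))]]
    else:
        raise ValueError("no reference ligand pose: supply an anchor point "
                         "for the binding site")
    anchor_pos = anchor_pos + rng.normal(0.0, sigma, size=3)
    # steps 2-3: collapse, then uncorrelated noise
    coords[lig] = anchor_pos + rng.normal(0.0, sigma, size=(len(lig), 3))

    names = np.array([a.name for a in graph.atoms])
    for g in sorted(np.unique(groups[protein])):
        members = np.where(groups == g)[0]
        kind = graph.group_kinds.get(int(g))
        if kind == "residue":
            ca = members[names[members] == "CA"]
            anchor_ca = reference.coords[ca[0]] if len(ca) else \
                reference.coords[members[0]]
            side = members[roles[members] == "sidechain"]
            coords[side] = anchor_ca + rng.normal(0.0, sigma, size=(len(side), 3))
        elif kind == "ligand":  # a second, non-docked ligand: training-style
            pick = members[rng.integers(len(members))]
            coords[members] = reference.coords[pick] + \
                rng.normal(0.0, sigma, size=(len(members), 3))
    mask = np.ones(graph.n_atoms, dtype=bool)
    return Conformation(coords, mask)


def corrupt_sidechain(graph: ChemGraph, reference: Conformation,
                      config: CorruptionConfig, seed: Optional[int] = None) -> Conformation:
    """Side-chain repacking initialization: backbone fixed, side chains
    randomized around Cα, ligand components collapsed training-style."""
    _check_resolved(graph, reference)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sigma = config.noise_sigma
    coords = reference.coords.copy()
    groups = graph.groups()
    roles = graph.roles()
    names = np.array([a.name for a in graph.atoms])
    for g in sorted(np.unique(groups)):
        members = np.where(groups == g)[0]
        kind = graph.group_kinds.get(int(g))
        if kind == "residue":
            ca = members[names[members] == "CA"]
            anchor_ca = reference.coords[ca[0]] if len(ca) else reference.coords[members[0]]
            side = members[roles[members] == "sidechain"]
            coords[side] = anchor_ca + rng.normal(0.0, sigma, size=(len(side), 3))
        else:
            pick = members[rng.integers(len(members))]
            coords[members] = reference.coords[pick] + \
                rng.normal(0.0, sigma, size=(len(members), 3))
    return Conformation(coords, np.ones(graph.n_atoms, dtype=bool))
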