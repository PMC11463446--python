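"""Stochastic ensembles, pRMSD ranking and preorganization scoring.

Because the denoiser starts from randomized coordinates, running it
repeatedly with different corruption seeds yields a structurally diverse
ensemble. Per-sample pRMSD over the ligand atoms ranks the pool (lower =
more confident); the mean over the ensemble of the per-sample side-chain
pRMSD — backbone N, Cα, C, O excluded — is the active-site preorganization
score used to compare designs.

Ligand RMSD is pose RMSD in the pocket frame (no re-superposition),
minimized over chemical-graph automorphisms so that symmetric ligands are
not penalized for equivalent atom labelings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

from .chemgraph import ChemGraph, Conformation
from .confidence import prmsd
from .corruption import CorruptionConfig, corrupt
from .network import ModelConfig, forward

logger = logging.getLogger(__name__)

BACKBONE_NAMES = ("N", "CA", "C", "O")
MAX_AUTOMORPHISMS = 10_000


@dataclass
class SampleResult:
    index: int
    prmsd: float
    ligand_rmsd: Optional[float] = None
    failed: bool = False


@dataclass
class EnsembleSummary:
    samples: list  # SampleResult, in sampling order
    ranking: list  # sample indices by ascending pRMSD (failed excluded)
    models: list  # Conformation per successful sample
    sigmas: list  # per-atom sigma array per successful sample
    n_failed: int = 0
    selection: np.ndarray = field(default=None)

    def best(self) -> SampleResult:
        return self.samples[self.ranking[0]]


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def select_atoms(graph: ChemGraph, expr: str) -> np.ndarray:
    """Tiny selection language: clauses joined by ``and``.

    Clauses: ``chain A``, ``resi 83`` (or ``resi 2-5``), ``name CB+OG``,
    each optionally prefixed with ``not``. Returns atom indices.
    """
    keep = np.ones(graph.n_atoms, dtype=bool)
    tokens = expr.replace("(", " ").replace(")", " ").split()
    i = 0
    while i < len(tokens):
        tok = tokens[i].lower()
        if tok == "and":
            i += 1
            continue
        negate = False
        if tok == "not":
            negate = True
            i += 1
            tok = tokens[i].lower()
        if tok in ("chain", "resi", "name"):
            value = tokens[i + 1]
            i += 2
        else:
            raise ValueError(f"cannot parse selection token {tokens[i]!r}")
        if tok == "chain":
            m = np.array([a.chain == value for a in graph.atoms])
        elif tok == "resi":
            if "-" in value:
                lo, hi = (int(v) for v in value.split("-"))
            else:
                lo = hi = int(value)
            m = np.array([lo <= a.resnum <= hi for a in graph.atoms])
        else:
            names = set(value.upper().split("+"))
            m = np.array([a.name.upper() in names for a in graph.atoms])
        keep &= ~m if negate else m
    return np.where(keep)[0]


def sidechain_selection(graph: ChemGraph, atoms: np.ndarray) -> np.ndarray:
    """Drop backbone N, CA, C, O from an atom selection (by atom name)."""
    names = np.array([graph.atoms[i].name for i in atoms])
    return atoms[~np.isin(names, BACKBONE_NAMES)]


# ---------------------------------------------------------------------------
# ligand RMSD
# ---------------------------------------------------------------------------

def _ligand_nx(graph: ChemGraph, atoms: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    aset = set(int(a) for a in atoms)
    for i in atoms:
        a = graph.atoms[int(i)]
        g.add_node(int(i), element=a.element, charge=a.charge)
    for i, j, order in graph.bonds:
        if i in aset and j in aset:
            g.add_edge(i, j, order=order)
    return g


def ligand_automorphisms(graph: ChemGraph, atoms: np.ndarray,
                         limit: int = MAX_AUTOMORPHISMS) -> list:
    """Element- and bond-order-preserving automorphisms of the ligand graph.

    Returns mappings as dicts; falls back to the identity alone (with a
    warning) if the count exceeds `limit`.
    """
    g = _ligand_nx(graph, atoms)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g, g,
        node_match=lambda a, b: a["element"] == b["element"] and a["charge"] == b["charge"],
        edge_match=lambda a, b: a["order"] == b["order"],
    )
    autos = []
    for mapping in matcher.isomorphisms_iter():
        autos.append(mapping)
        if len(autos) > limit:
            logger.warning("more than %d automorphisms; falling back to identity", limit)
            return [{int(i): int(i) for i in atoms}]
    return autos


def ligand_rmsd(model, reference, graph: ChemGraph, atoms: Optional[np.ndarray] = None,
                symmetry: bool = True) -> float:
    """Pose RMSD of the ligand in the pocket frame (no re-superposition).

    With ``symmetry=True`` (default) the RMSD is minimized over chemical
    automorphisms of the ligand graph; ``symmetry=False`` gives the plain
    identity-mapping metric for comparison.
    """
    mc = model.coords if isinstance(model, Conformation) else np.asarray(model)
    rc = reference.coords if isinstance(reference, Conformation) else np.asarray(reference)
    if atoms is None:
        atoms = np.where(graph.roles() == "ligand")[0]
    atoms = np.asarray(atoms, dtype=int)
    if len(atoms) == 0:
        raise ValueError("empty ligand selection")
    if not symmetry:
        return float(np.sqrt(np.mean(np.sum((mc[atoms] - rc[atoms]) ** 2, axis=1))))
    best = np.inf
    for mapping in ligand_automorphisms(graph, atoms):
        perm = np.array([mapping[int(i)] for i in atoms])
        rmsd = np.sqrt(np.mean(np.sum((mc[atoms] - rc[perm]) ** 2, axis=1)))
        best = min(best, float(rmsd))
    return best


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_ensemble(graph: ChemGraph, reference: Conformation, params: dict,
                    model_cfg: ModelConfig, corruption: CorruptionConfig,
                    n_samples: int = 50, base_seed: int = 0,
                    selection: Optional[np.ndarray] = None,
                    ligand_group: Optional[int] = None,
                    anchor: Optional[np.ndarray] = None) -> EnsembleSummary:
    """Generate `n_samples` denoised models; sample i uses corruption seed
    ``base_seed + i``. Ranked by per-sample pRMSD over `selection` (default:
    the ligand atoms). Failed forwards are excluded from the ranking but
    counted."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if selection is None:
        selection = np.where(graph.roles() == "ligand")[0]
    if len(selection) == 0:
        raise ValueError("selection resolves to zero atoms")
    samples, models, sigmas = [], [], []
    for i in range(n_samples):
        try:
            corrupted = corrupt(graph, reference, corruption,
                                ligand_group=ligand_group, anchor=anchor,
                                seed=(base_seed + i) % (2**31))
            final, confs, _ = forward(graph, corrupted, params, model_cfg)
            sigma = np.asarray(confs[-1].sigma.value)
            score = prmsd(sigma[selection])
            rmsd = None
            lig_atoms = np.where(graph.roles() == "ligand")[0]
            if len(lig_atoms) and reference.mask[lig_atoms].all():
                rmsd = ligand_rmsd(final, reference, graph, atoms=lig_atoms)
            samples.append(SampleResult(i, score, rmsd))
            models.append(final)
            sigmas.append(sigma)
        except (FloatingPointError, ValueError) as err:
            logger.warning("sample %d failed: %s", i, err)
            samples.append(SampleResult(i, np.nan, failed=True))
            models.append(None)
            sigmas.append(None)
    ok = [s.index for s in samples if not s.failed]
    ranking = sorted(ok, key=lambda i: samples[i].prmsd)
    return EnsembleSummary(samples=samples, ranking=ranking,
                           models=[m for m in models if m is not None],
                           sigmas=[s for s in sigmas if s is not None],
                           n_failed=len(samples) - len(ok),
                           selection=np.asarray(selection))


def success_rate(best_rmsds, thresholds=(1.0, 2.0)) -> dict:
    """Fraction of targets whose best-ranked model has RMSD strictly below
    each threshold."""
    arr = np.asarray(list(best_rmsds), dtype=float)
    if arr.size == 0:
        raise ValueError("success_rate of an empty input")
    return {float(t): float((arr < t).mean()) for t in thresholds}


def preorganization_score(summary: EnsembleSummary, graph: ChemGraph,
                          selection: np.ndarray) -> float:
    """Mean over samples of the per-sample pRMSD over side-chain atoms of
    the selection (backbone N, Cα, C, O excluded). Lower = more preorganized."""
    sel = sidechain_selection(graph, np.asarray(selection, dtype=int))
    if len(sel) == 0:
        raise ValueError("selection resolves to zero side-chain atoms")
    scores = [prmsd(sig[sel]) for sig in summary.sigmas]
    if not scores:
        raise ValueError("no successful samples to score")
    return float(np.mean(scores))
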