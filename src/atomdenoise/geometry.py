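"""Structural losses and metrics on chemical graphs.

The central quantity is all-atom frame-aligned point error (FAPE): local
coordinate frames are erected on every bonded atom triple a–b–c, every atom
of the model and the reference is expressed in the corresponding frame of
its own structure, and the per-atom deviations (clamped, default 10 Å) are
averaged over atoms × frames. Because frames ride along with the structure,
the loss is invariant under global rotation + translation but still sees all
internal geometry.

Alongside FAPE: bonded-geometry errors (bond lengths, bonded angles, planar
and chiral improper dihedrals), the chirality pseudoscalar V with its
analytic biasing vectors, and superposition-free per-atom lDDT.

All loss functions run on :class:`~atomdenoise.autodiff.Tensor` coordinates
(returning a Tensor for use as a training loss) or plain arrays (returning
floats).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chemgraph import ChemGraph, Conformation
from .io_formats import AROMATIC

logger = logging.getLogger(__name__)

DEFAULT_FAPE_CLAMP = 10.0  # Å
_COLLINEAR_TOL_DEG = 2.0
_EPS = 1e-12


def _coords_of(x):
    """Coordinates as (n, 3) Tensor or ndarray plus the resolved mask."""
    if isinstance(x, Conformation):
        return x.coords, x.mask
    if isinstance(x, Tensor):
        return x, None
    arr = np.asarray(x, dtype=float).reshape(-1, 3)
    return arr, None


# ---------------------------------------------------------------------------
# frames & FAPE
# ---------------------------------------------------------------------------

def enumerate_frames(graph: ChemGraph, reference=None,
                     collinear_tol_deg: float = _COLLINEAR_TOL_DEG) -> list:
    """All bonded-triple frames a–b–c (each geometric triple once, a < c).

    When a reference structure is given, triples that are collinear in it
    (angle within `collinear_tol_deg` of 180°) are excluded and logged.
    """
    frames = []
    for b in range(graph.n_atoms):
        nbrs = graph.neighbors(b)
        for ii in range(len(nbrs)):
            for jj in range(ii + 1, len(nbrs)):
                a, c = nbrs[ii], nbrs[jj]
                frames.append((min(a, c), b, max(a, c)))
    if reference is not None:
        coords, mask = _coords_of(reference)
        kept = []
        for (a, b, c) in frames:
            if mask is not None and not (mask[a] and mask[b] and mask[c]):
                continue
            u = coords[a] - coords[b]
            v = coords[c] - coords[b]
            cosang = np.dot(u, v) / max(np.linalg.norm(u) * np.linalg.norm(v), _EPS)
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang > 180.0 - collinear_tol_deg:
                logger.info("frame (%d,%d,%d) collinear (%.2f deg); excluded", a, b, c, ang)
                continue
            kept.append((a, b, c))
        frames = kept
    return frames


def _local_coords(coords, a_idx, b_idx, c_idx):
    """Express all atoms in each frame's local basis; works on Tensor or ndarray.

    Basis: origin at b, x along b->c, y = Gram-Schmidt of b->a against x,
    z = x cross y (right-handed).
    """
    t = ad.as_tensor(coords)
    A, B, C = t[a_idx], t[b_idx], t[c_idx]  # (F, 3)
    x = C - B
    x = x / ad.norm(x, eps=_EPS).reshape(-1, 1)
    ab = A - B
    y = ab - (ab * x).sum(axis=-1, keepdims=True) * x
    y = y / ad.norm(y, eps=_EPS).reshape(-1, 1)
    z = ad.cross(x, y)
    F = len(a_idx)
    n = t.shape[0]
    diff = t.reshape(1, n, 3) - B.reshape(F, 1, 3)  # (F, N, 3)
    lx = (diff * x.reshape(F, 1, 3)).sum(axis=-1)
    ly = (diff * y.reshape(F, 1, 3)).sum(axis=-1)
    lz = (diff * z.reshape(F, 1, 3)).sum(axis=-1)
    return ad.stack([lx, ly, lz], axis=-1)  # (F, N, 3)


def fape_allatom(model, reference, graph: ChemGraph,
                 clamp: float = DEFAULT_FAPE_CLAMP):
    """All-atom FAPE between model and reference (mean over atoms × frames, Å).

    Deviations are clamped at `clamp` (default 10 Å). Returns a float, or a
    Tensor when `model` carries gradients.
    """
    if clamp <= 0:
        raise ValueError("clamp must be positive")
    mcoords, mmask = _coords_of(model)
    rcoords, rmask = _coords_of(reference)
    frames = enumerate_frames(graph, reference)
    if len(frames) < 1:
        raise ValueError("FAPE undefined: no usable frames in the graph")
    a_idx, b_idx, c_idx = (np.array(x) for x in zip(*frames))
    atom_mask = np.ones(graph.n_atoms, dtype=bool)
    if mmask is not None:
        atom_mask &= mmask
    if rmask is not None:
        atom_mask &= rmask
    atoms = np.where(atom_mask)[0]
    rvals = rcoords.value if isinstance(rcoords, Tensor) else np.asarray(rcoords)
    local_r = _local_coords(rvals, a_idx, b_idx, c_idx).value[:, atoms, :]
    if isinstance(mcoords, Tensor):
        local_m = _local_coords(mcoords, a_idx, b_idx, c_idx)[:, atoms, :]
        dev = ad.norm(local_m - local_r, eps=_EPS)
        return dev.clip_max(clamp).mean()
    local_m = _local_coords(np.asarray(mcoords), a_idx, b_idx, c_idx).value[:, atoms, :]
    dev = np.linalg.norm(local_m - local_r, axis=-1)
    return float(np.minimum(dev, clamp).mean())


# ---------------------------------------------------------------------------
# chirality pseudoscalar
# ---------------------------------------------------------------------------

def triple_product_V(o, a, b, c) -> float:
    """V = ê_A · (ê_B × ê_C) for unit vectors from the central atom O.

    A pseudoscalar: its sign distinguishes the two handednesses of a
    tetrahedral center; ideal magnitude 4/(3√3) ≈ 0.7698.
    """
    o, a, b, c = (np.asarray(x, dtype=float) for x in (o, a, b, c))
    es = []
    for x in (a, b, c):
        r = x - o
        nr = np.linalg.norm(r)
        if nr < 1e-6:
            raise ValueError("degenerate chiral center: substituent coincides with O")
        es.append(r / nr)
    return float(np.dot(es[0], np.cross(es[1], es[2])))


def chirality_bias_vectors(center, coords) -> np.ndarray:
    """Analytic gradient of (V − V_ideal)² w.r.t. the four atoms O, A, B, C.

    Returns a (4, 3) array of biasing vectors (rows: O, A, B, C) pointing in
    the directions the atoms should move to restore the target handedness.
    """
    coords = np.asarray(coords, dtype=float)
    o, a, b, c = (coords[i] for i in center.indices)
    rs = [np.asarray(x) - o for x in (a, b, c)]
    ls = [np.linalg.norm(r) for r in rs]
    if min(ls) < 1e-6:
        raise ValueError("degenerate chiral center: substituent coincides with O")
    e = [r / l for r, l in zip(rs, ls)]
    v = float(np.dot(e[0], np.cross(e[1], e[2])))
    # dV/dê_A = ê_B × ê_C (and cyclic); chain through unit-vector projection
    dV_de = [np.cross(e[1], e[2]), np.cross(e[2], e[0]), np.cross(e[0], e[1])]
    grads = np.zeros((4, 3))
    for k in range(3):
        proj = (np.eye(3) - np.outer(e[k], e[k])) / ls[k]
        gk = proj @ dV_de[k]
        grads[k + 1] = gk
        grads[0] -= gk
    return 2.0 * (v - center.v_ideal) * grads


def chirality_loss(coords, centers):
    """Sum of (V − V_ideal)² over chiral centers; Tensor in, Tensor out."""
    t = ad.as_tensor(coords)
    if not centers:
        return Tensor(0.0)
    total = Tensor(0.0)
    for cc in centers:
        o = t[cc.center]
        es = []
        for idx in (cc.a, cc.b, cc.c):
            r = t[idx] - o
            es.append(r / ad.norm(r, eps=_EPS))
        v = (es[0] * ad.cross(es[1], es[2])).sum()
        total = total + (v - cc.v_ideal) ** 2
    return total / float(len(centers))


# ---------------------------------------------------------------------------
# bonded geometry
# ---------------------------------------------------------------------------

@dataclass
class GeometryErrorReport:
    """Mean absolute errors of local geometry, model vs reference."""

    bond_length_mae: float  # Å
    bond_angle_mae: float  # deg
    planar_angle_mae: float  # deg
    chiral_angle_mae: float  # deg
    n_bonds: int = 0
    n_angles: int = 0
    n_planar: int = 0
    n_chiral: int = 0

    def as_dict(self) -> dict:
        return {
            "bond_length_mae_A": self.bond_length_mae,
            "bond_angle_mae_deg": self.bond_angle_mae,
            "planar_angle_mae_deg": self.planar_angle_mae,
            "chiral_angle_mae_deg": self.chiral_angle_mae,
        }


def _planar_centers(graph: ChemGraph) -> list:
    """3-coordinate centers flagged planar (sp², from bond orders)."""
    order = graph.bond_order_matrix()
    out = []
    for b in range(graph.n_atoms):
        nbrs = graph.neighbors(b)
        if len(nbrs) != 3:
            continue
        if any(order[b, x] > 1.0 for x in nbrs):
            out.append((b, tuple(sorted(nbrs))))
    return out


def _dihedral(t: Tensor, p, q, r, s):
    """Torsion angle (radians) of the atom sequence p–q–r–s, autodiff-safe."""
    b1 = t[q] - t[p]
    b2 = t[r] - t[q]
    b3 = t[s] - t[r]
    n1 = ad.cross(b1, b2)
    n2 = ad.cross(b2, b3)
    m1 = ad.cross(n1, b2 / ad.norm(b2, eps=_EPS).reshape(-1, 1))
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    return ad.arctan2(y, x)


def _geometry_terms(coords, graph: ChemGraph):
    """Bond lengths (Å) and bonded/planar/chiral angles (radians) as Tensors."""
    t = ad.as_tensor(coords)
    terms = {}
    if graph.bonds:
        i = np.array([b[0] for b in graph.bonds])
        j = np.array([b[1] for b in graph.bonds])
        terms["bonds"] = ad.norm(t[i] - t[j], eps=_EPS)
    angles = enumerate_frames(graph)
    if angles:
        a, b, c = (np.array(x) for x in zip(*angles))
        u = t[a] - t[b]
        v = t[c] - t[b]
        cosang = (u * v).sum(axis=-1) / (ad.norm(u, eps=_EPS) * ad.norm(v, eps=_EPS))
        terms["angles"] = cosang.clip_min(-1.0 + 1e-9).clip_max(1.0 - 1e-9).arccos()
    planar = _planar_centers(graph)
    if planar:
        p = np.array([nbrs[0] for _, nbrs in planar])
        q = np.array([nbrs[1] for _, nbrs in planar])
        ctr = np.array([b for b, _ in planar])
        s = np.array([nbrs[2] for _, nbrs in planar])
        terms["planar"] = _dihedral(t, p, q, ctr, s)
    if graph.chiral_centers:
        a = np.array([cc.a for cc in graph.chiral_centers])
        b = np.array([cc.b for cc in graph.chiral_centers])
        o = np.array([cc.center for cc in graph.chiral_centers])
        c = np.array([cc.c for cc in graph.chiral_centers])
        terms["chiral"] = _dihedral(t, a, b, o, c)
    return terms


def _wrapped_abs_diff(m, r):
    """|angle difference| wrapped to [0, pi]; Tensor-safe."""
    d = m - ad.as_tensor(r)
    return ad.arctan2(d.sin(), d.cos()).abs()


def bonded_geometry_errors(model, reference, graph: ChemGraph) -> GeometryErrorReport:
    """Mean absolute local-geometry errors of `model` against `reference`."""
    mcoords, _ = _coords_of(model)
    rcoords, _ = _coords_of(reference)
    tm = _geometry_terms(np.asarray(mcoords if not isinstance(mcoords, Tensor)
                                    else mcoords.value), graph)
    tr = _geometry_terms(np.asarray(rcoords if not isinstance(rcoords, Tensor)
                                    else rcoords.value), graph)

    def mae(key, angular):
        if key not in tm:
            return 0.0, 0
        m, r = tm[key].value, tr[key].value
        if angular:
            d = np.abs(np.arctan2(np.sin(m - r), np.cos(m - r)))
            return float(np.degrees(d).mean()), len(m)
        return float(np.abs(m - r).mean()), len(m)

    bl, nb = mae("bonds", False)
    ba, na = mae("angles", True)
    pa, npl = mae("planar", True)
    ca, nc = mae("chiral", True)
    return GeometryErrorReport(bl, ba, pa, ca, nb, na, npl, nc)


def bonded_geometry_loss(model: Tensor, reference, graph: ChemGraph,
                         w_bond: float = 1.0, w_angle: float = 0.02):
    """Differentiable bonded-geometry training loss (MAE terms, weighted).

    Weights: `w_bond` in Å⁻¹ on bond lengths, `w_angle` in deg⁻¹ on all
    angle categories.
    """
    rcoords, _ = _coords_of(reference)
    rterms = _geometry_terms(np.asarray(rcoords), graph)
    mterms = _geometry_terms(model, graph)
    loss = Tensor(0.0)
    if "bonds" in mterms:
        loss = loss + w_bond * (mterms["bonds"] - rterms["bonds"].value).abs().mean()
    for key in ("angles", "planar", "chiral"):
        if key in mterms:
            deg = _wrapped_abs_diff(mterms[key], rterms[key].value) * (180.0 / np.pi)
            loss = loss + w_angle * deg.mean()
    return loss


# ---------------------------------------------------------------------------
# lDDT
# ---------------------------------------------------------------------------

def lddt_per_atom(model, reference, graph: ChemGraph,
                  inclusion_radius: float = 15.0,
                  thresholds=(0.5, 1.0, 2.0, 4.0)) -> tuple:
    """Per-atom all-atom lDDT in [0, 1].

    Pairs qualify when the reference distance is below `inclusion_radius`
    and the partners are either in different covalent components or at bond
    separation >= 4 — so the score measures packing, not bonded geometry.
    Returns ``(values, defined)``; atoms with no qualifying partner are
    masked out in `defined`.
    """
    mcoords, mmask = _coords_of(model)
    rcoords, rmask = _coords_of(reference)
    mcoords = np.asarray(mcoords.value if isinstance(mcoords, Tensor) else mcoords)
    rcoords = np.asarray(rcoords.value if isinstance(rcoords, Tensor) else rcoords)
    n = graph.n_atoms
    sep = graph.bond_separation
    dr = np.linalg.norm(rcoords[:, None, :] - rcoords[None, :, :], axis=-1)
    dm = np.linalg.norm(mcoords[:, None, :] - mcoords[None, :, :], axis=-1)
    qualify = (dr < inclusion_radius) & (sep >= 4)
    np.fill_diagonal(qualify, False)
    for mask in (mmask, rmask):
        if mask is not None:
            qualify &= mask[:, None] & mask[None, :]
    delta = np.abs(dm - dr)
    frac = np.zeros((n, n))
    for thr in thresholds:
        frac += (delta < thr).astype(float)
    frac /= len(thresholds)
    counts = qualify.sum(axis=1)
    defined = counts > 0
    values = np.zeros(n)
    values[defined] = (frac * qualify).sum(axis=1)[defined] / counts[defined]
    return values, defined
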