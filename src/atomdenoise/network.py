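"""A miniature three-track iterative denoising network.

The architecture follows the reference design at desk scale: 1D per-atom
embeddings, a dense 2D pair track, and 3D coordinates are updated jointly by
shared-weight iteration blocks. Inside each block the atom neighbor graph is
rebuilt (half the K slots filled by spatial proximity, half by bond
separation), pair features are adapted into edge embeddings, an
SE(3)-equivariant scalar+vector message-passing layer updates coordinates
and 1D features, the pair track takes a structure-biased update, and
confidence heads (per-atom σ and lDDT, per-pair signed-distance-error
logits) branch off the 1D/2D tracks.

Equivariance is structural: coordinates move only along relative directions
and learned vector features, scalars see only invariants (distances, dot
products, graph features), so forward(R·x + t) = R·forward(x) + t exactly,
for any weights. Chirality enters through type-1 (vector) features: the
analytic biasing vectors of each chiral center, recomputed from the current
coordinates at every block, are the one parity-odd input and let the network
distinguish enantiomers.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chemgraph import ChemGraph, Conformation, UNCONNECTED
from .confidence import SIGMA_MAX, SIGMA_MIN, ConfidenceOutput
from .geometry import chirality_bias_vectors

#: supported heavy elements (organic set + common metals); hydrogens are
#: never featurized — they are stripped when the graph is built
ELEMENTS = ["B", "C", "N", "O", "F", "Na", "Mg", "Si", "P", "S", "Cl", "K",
            "Ca", "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Se", "Br", "I"]
_ELEMENT_INDEX = {el: i for i, el in enumerate(ELEMENTS)}
_ROLES = ["backbone", "sidechain", "ligand"]
_BOND_ORDERS = [1, 2, 3, "ar"]

SEPARATION_CLAMP = 32  # featurization-side clamp on bond separation


@dataclass
class ModelConfig:
    """Network hyper-parameters. One parameter set is shared by all blocks,
    so `n_blocks` adds compute, never parameters."""

    n_blocks: int = 2
    d1: int = 64  # 1D track width
    d2: int = 32  # 2D track width
    d_edge: int = 32
    d_hidden: int = 128
    dv: int = 8  # equivariant vector channels
    n_rbf: int = 16
    K: int = 16  # neighbor-list size (even)
    rounds: int = 4  # message-passing rounds inside a block
    n_pair_bins: int = 9
    seed: int = 0
    max_atoms: int = 600  # dense 2D track: larger systems are rejected
    ablate_bond_separation: bool = False  # keep only the binary bonded flag

    def __post_init__(self):
        if self.K % 2 != 0 or self.K < 2:
            raise ValueError("K must be even and >= 2")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        for name in ("d1", "d2", "d_edge", "d_hidden", "dv", "n_rbf"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def micro(cls, seed: int = 0) -> "ModelConfig":
        """Desk-scale default: 2 blocks, K=16, for fixtures under ~40 atoms."""
        return cls(seed=seed)

    @classmethod
    def reference_scale(cls, seed: int = 0) -> "ModelConfig":
        """The full-scale preset: eight shared-weight blocks, 32 neighbors."""
        return cls(n_blocks=8, K=32, d1=128, d2=64, d_hidden=192, seed=seed)


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def featurize_1d(graph: ChemGraph) -> np.ndarray:
    """Per-atom invariant features: element one-hot, formal charge, role."""
    n = graph.n_atoms
    out = np.zeros((n, len(ELEMENTS) + 1 + len(_ROLES)))
    for i, atom in enumerate(graph.atoms):
        if atom.element not in _ELEMENT_INDEX:
            raise ValueError(f"unsupported element {atom.element!r} at atom {i}")
        out[i, _ELEMENT_INDEX[atom.element]] = 1.0
        out[i, len(ELEMENTS)] = np.clip(atom.charge, -2, 2) / 2.0
        out[i, len(ELEMENTS) + 1 + _ROLES.index(atom.role)] = 1.0
    return out


def featurize_2d(graph: ChemGraph) -> np.ndarray:
    """Dense pair features: bonded flag, bond-order one-hot, clamped
    bond-separation one-hot with an 'unconnected' token, same-component flag.

    No feature depends on coordinates, so nothing leaks the reference
    structure.
    """
    n = graph.n_atoms
    n_sep = SEPARATION_CLAMP + 1
    dim = 1 + len(_BOND_ORDERS) + n_sep + 1 + 1
    out = np.zeros((n, n, dim))
    order_base = 1
    sep_base = order_base + len(_BOND_ORDERS)
    unconn = sep_base + n_sep
    samec = unconn + 1
    for i, j, order in graph.bonds:
        out[i, j, 0] = out[j, i, 0] = 1.0
        k = order_base + _BOND_ORDERS.index(order)
        out[i, j, k] = out[j, i, k] = 1.0
    sep = graph.bond_separation
    connected = sep < UNCONNECTED
    clamped = np.minimum(sep, SEPARATION_CLAMP)
    ii, jj = np.where(connected)
    out[ii, jj, sep_base + clamped[ii, jj]] = 1.0
    out[:, :, unconn] = (~connected).astype(float)
    comp = graph.components
    out[:, :, samec] = (comp[:, None] == comp[None, :]).astype(float)
    return out


def chirality_field(graph: ChemGraph, coords: np.ndarray) -> np.ndarray:
    """Per-atom chirality biasing vectors (n, 3), summed over centers.

    The analytic gradient of (V − V_ideal)² scattered onto O, A, B, C —
    the type-1 input that communicates handedness to the network.
    """
    field_ = np.zeros((graph.n_atoms, 3))
    for cc in graph.chiral_centers:
        try:
            vecs = chirality_bias_vectors(cc, coords)
        except ValueError:
            continue  # degenerate geometry this iteration; no bias
        for row, idx in zip(vecs, cc.indices):
            field_[idx] += row
    return field_


# ---------------------------------------------------------------------------
# neighbor graph
# ---------------------------------------------------------------------------

def build_neighbor_graph(graph: ChemGraph, coords: np.ndarray, K: int):
    """Per-atom neighbor lists of length exactly K.

    K/2 slots are filled by spatial proximity (ties by atom index), K/2 by
    bond separation (ties by separation then index, skipping atoms already
    in the spatial half), then backfilled with further spatial candidates
    and padded with a sentinel (= n_atoms) when the system is small.
    Returns ``(indices (n, K), valid mask (n, K))``.
    """
    if K % 2 != 0 or K < 2:
        raise ValueError("K must be even and >= 2")
    n = graph.n_atoms
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    sep = graph.bond_separation.astype(float).copy()
    np.fill_diagonal(sep, np.inf)
    sep[sep >= UNCONNECTED] = np.inf
    half = K // 2
    idx_arr = np.arange(n)
    indices = np.full((n, K), n, dtype=int)
    valid = np.zeros((n, K), dtype=bool)
    for i in range(n):
        spatial_order = np.lexsort((idx_arr, d[i]))
        spatial_order = spatial_order[np.isfinite(d[i][spatial_order])]
        chosen = list(spatial_order[:half])
        chosen_set = set(chosen)
        chem_order = np.lexsort((idx_arr, sep[i]))
        chem_order = chem_order[np.isfinite(sep[i][chem_order])]
        for j in chem_order:
            if len(chosen) >= K:
                break
            if j not in chosen_set:
                chosen.append(int(j))
                chosen_set.add(int(j))
        for j in spatial_order[half:]:
            if len(chosen) >= K:
                break
            if j not in chosen_set:
                chosen.append(int(j))
                chosen_set.add(int(j))
        indices[i, :len(chosen)] = chosen
        valid[i, :len(chosen)] = True
    return indices, valid


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _msg_input_dim(cfg: ModelConfig) -> int:
    return 2 * cfg.d1 + cfg.d_edge + cfg.n_rbf + 3 * cfg.dv


def init_params(cfg: ModelConfig) -> dict:
    """Seeded initialization; coordinate-update head weights start at zero,
    so an untrained block is the identity on coordinates."""
    rng = np.random.default_rng(cfg.seed)

    def w(name, shape, scale=None, zero=False):
        if zero:
            arr = np.zeros(shape)
        else:
            fan_in = shape[0] if len(shape) > 1 else 1
            arr = rng.normal(0.0, (scale or 1.0) / np.sqrt(fan_in), size=shape)
        params[name] = Tensor(arr, requires_grad=True)

    f1 = len(ELEMENTS) + 1 + len(_ROLES)
    f2 = 1 + len(_BOND_ORDERS) + (SEPARATION_CLAMP + 1) + 1 + 1
    params: dict = {}
    w("emb1_w", (f1, cfg.d1)); w("emb1_b", (cfg.d1,), zero=True)
    w("emb2_w", (f2, cfg.d2)); w("emb2_b", (cfg.d2,), zero=True)
    w("adapt_w", (cfg.d2, cfg.d_edge)); w("adapt_b", (cfg.d_edge,), zero=True)
    din, dh = _msg_input_dim(cfg), cfg.d_hidden
    for r in range(cfg.rounds):
        w(f"m{r}_w1", (din, dh)); w(f"m{r}_b1", (dh,), zero=True)
        w(f"m{r}_w2", (dh, dh)); w(f"m{r}_b2", (dh,), zero=True)
        w(f"m{r}_hs", (dh, cfg.d1))
        w(f"m{r}_ha", (dh, 1), zero=True)  # coordinate head: direct term
        w(f"m{r}_hgv", (dh, cfg.dv))
        w(f"m{r}_hgd", (dh, cfg.dv))
        w(f"m{r}_eta", (cfg.d1, cfg.dv), zero=True)  # coordinate head: vector term
    w("pair_sproj", (cfg.d1, cfg.d2))
    w("pair_w1", (3 * cfg.d2 + cfg.n_rbf, cfg.d2)); w("pair_b1", (cfg.d2,), zero=True)
    w("pair_w2", (cfg.d2, cfg.d2)); w("pair_b2", (cfg.d2,), zero=True)
    w("s_from_p", (cfg.d2, cfg.d1))
    w("conf_w1", (cfg.d1 + cfg.n_rbf + 2, 32)); w("conf_b1", (32,), zero=True)
    w("conf_w2", (32, 2)); w("conf_b2", (2,), zero=True)
    w("conf_skip", (cfg.n_rbf + 2, 2), zero=True)
    w("pairconf_w", (cfg.d2, cfg.n_pair_bins)); w("pairconf_b", (cfg.n_pair_bins,), zero=True)
    return params


def count_parameters(params: dict) -> int:
    return int(sum(p.value.size for p in params.values()))


def save_weights(path, params: dict, cfg: ModelConfig) -> None:
    """Checkpoint container: JSON with the config embedded."""
    payload = {
        "format": "atomdenoise-weights-v1",
        "config": asdict(cfg),
        "params": {k: v.value.tolist() for k, v in params.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_weights(path):
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "atomdenoise-weights-v1":
        raise ValueError(f"{path}: not an atomdenoise checkpoint")
    cfg = ModelConfig(**payload["config"])
    params = {k: Tensor(np.array(v), requires_grad=True)
              for k, v in payload["params"].items()}
    return params, cfg


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

@dataclass
class TrackState:
    s: Tensor  # (n, d1)
    p: Tensor  # (n, n, d2)
    x: Tensor  # (n, 3) current coordinates
    graph: ChemGraph
    feat2d: np.ndarray = field(default=None, repr=False)


def embed_inputs(graph: ChemGraph, corrupted: Conformation,
                 params: dict, cfg: ModelConfig) -> TrackState:
    """Initial embedding of the 1D and 2D features plus the corrupted 3D state."""
    if graph.n_atoms > cfg.max_atoms:
        raise ValueError(
            f"system has {graph.n_atoms} atoms; the dense pair track is "
            f"capped at {cfg.max_atoms} — crop the input first")
    f1 = featurize_1d(graph)
    f2 = featurize_2d(graph)
    if cfg.ablate_bond_separation:
        # ablation: drop separation one-hots + unconnected token, keeping
        # only the binary bonded flag (and bond orders / component flag)
        sep_base = 1 + len(_BOND_ORDERS)
        f2 = f2.copy()
        f2[:, :, sep_base:sep_base + SEPARATION_CLAMP + 2] = 0.0
    s = Tensor(f1) @ params["emb1_w"] + params["emb1_b"]
    p = Tensor(f2.reshape(-1, f2.shape[-1])) @ params["emb2_w"]
    p = (p + params["emb2_b"]).reshape(graph.n_atoms, graph.n_atoms, cfg.d2)
    return TrackState(s=s, p=p, x=Tensor(corrupted.coords.copy()), graph=graph,
                      feat2d=f2)


def _pair_bin_centers(n_bins: int) -> np.ndarray:
    """Representative signed-error value per bin (midpoints, ±5 Å tails)."""
    from .confidence import DEFAULT_PAIR_BIN_EDGES as E
    mids = [(E[i] + E[i + 1]) / 2 for i in range(len(E) - 1)]
    return np.array([-5.0] + mids + [5.0])[:n_bins]


def _rbf(d: Tensor, n_rbf: int, r_max: float = 8.0) -> Tensor:
    centers = np.linspace(0.0, r_max, n_rbf)
    width = r_max / n_rbf
    diff = d.reshape(*d.shape, 1) - centers
    return (-(diff * diff) / (2.0 * width * width)).exp()


def iteration_block(state: TrackState, params: dict, cfg: ModelConfig,
                    block_index: int = 0):
    """One shared-weight iteration: neighbor graph, equivariant update of
    coordinates + 1D track, structure-biased pair update, confidence heads.

    Returns ``(new_state, ConfidenceOutput)``.
    """
    graph = state.graph
    n = graph.n_atoms
    xv = state.x.value
    if not np.isfinite(xv).all():
        raise FloatingPointError(f"non-finite coordinates entering block {block_index}")
    nbr, nbr_mask = build_neighbor_graph(graph, xv, cfg.K)
    Kk = nbr.shape[1]
    safe = np.minimum(nbr, n - 1)  # sentinel-safe gather; masked out below
    mask = nbr_mask.astype(float)[..., None]  # (n, K, 1)

    # chirality type-1 input, recomputed from the current coordinates
    vinit = np.zeros((n, cfg.dv, 3))
    vinit[:, 0, :] = chirality_field(graph, xv)
    v = Tensor(vinit)

    # 2D -> edge embeddings through the adapter layer
    pair_flat = state.p.reshape(n * n, cfg.d2)
    edge_all = (pair_flat @ params["adapt_w"] + params["adapt_b"]).reshape(n, n, cfg.d_edge)
    e_ij = edge_all[np.arange(n)[:, None], safe]  # (n, K, d_edge)

    s, x = state.s, state.x
    for r in range(cfg.rounds):
        xi = x.reshape(n, 1, 3)
        xj = x[safe]
        diff = xj - xi
        dij = ad.norm(diff, eps=1e-10)  # (n, K)
        u = diff / (dij.reshape(n, Kk, 1) + 1.0)
        rbf = _rbf(dij, cfg.n_rbf)
        vi = v.reshape(n, 1, cfg.dv, 3)
        vj = v[safe]  # (n, K, dv, 3)
        dots_vv = (vi * vj).sum(axis=-1)
        dots_vu = (vi * u.reshape(n, Kk, 1, 3)).sum(axis=-1)
        dots_ju = (vj * u.reshape(n, Kk, 1, 3)).sum(axis=-1)
        si = s.reshape(n, 1, cfg.d1) * Tensor(np.ones((1, Kk, 1)))
        sj = s[safe]
        m_in = ad.concatenate([si, sj, e_ij, rbf, dots_vv, dots_vu, dots_ju], axis=-1)
        h = (m_in @ params[f"m{r}_w1"] + params[f"m{r}_b1"]).tanh()
        h = (h @ params[f"m{r}_w2"] + params[f"m{r}_b2"]).tanh()
        agg = lambda t: (t * mask).sum(axis=1) / np.maximum(
            nbr_mask.sum(axis=1), 1)[:, None]
        s = s + agg(h @ params[f"m{r}_hs"])
        gv = (h @ params[f"m{r}_hgv"]).reshape(n, Kk, cfg.dv, 1)
        gd = (h @ params[f"m{r}_hgd"]).reshape(n, Kk, cfg.dv, 1)
        vmsg = gv * vj + gd * u.reshape(n, Kk, 1, 3)
        v = v + (vmsg * mask.reshape(n, Kk, 1, 1)).sum(axis=1) / np.maximum(
            nbr_mask.sum(axis=1), 1)[:, None, None]
        # coordinate update: neighbor-direction term + vector-channel term
        alpha = h @ params[f"m{r}_ha"]  # (n, K, 1)
        dx_dir = (alpha * u * mask).sum(axis=1) / np.maximum(
            nbr_mask.sum(axis=1), 1)[:, None]
        eta = (s @ params[f"m{r}_eta"]).reshape(n, cfg.dv, 1)
        dx_vec = (eta * v).sum(axis=1)
        x = x + dx_dir + dx_vec

    # pair-to-pair update with bias from structure (current distances)
    xv_now = x
    dmat = ad.norm(xv_now.reshape(n, 1, 3) - xv_now.reshape(1, n, 3), eps=1e-10)
    rbf_p = _rbf(dmat, cfg.n_rbf)
    sp = s @ params["pair_sproj"]  # (n, d2)
    sp_i = sp.reshape(n, 1, cfg.d2) * Tensor(np.ones((1, n, 1)))
    sp_j = sp.reshape(1, n, cfg.d2) * Tensor(np.ones((n, 1, 1)))
    p_in = ad.concatenate([state.p, sp_i, sp_j, rbf_p], axis=-1)
    ph = (p_in.reshape(n * n, -1) @ params["pair_w1"] + params["pair_b1"]).tanh()
    ph = ph @ params["pair_w2"] + params["pair_b2"]
    p = state.p + ph.reshape(n, n, cfg.d2)
    # symmetrize so pair features stay order-independent
    p = (p + p.transpose(1, 0, 2)) * 0.5
    s = s + agg(p[np.arange(n)[:, None], safe] @ params["s_from_p"])

    # pair confidence head: signed distance-error bin logits per neighbor pair
    plog_nk = (p[np.arange(n)[:, None], safe].reshape(n * Kk, cfg.d2)
               @ params["pairconf_w"] + params["pairconf_b"]).reshape(n, Kk, -1)
    pair_pairs = np.stack([np.repeat(np.arange(n), Kk), nbr.reshape(-1)], axis=1)
    keep = nbr_mask.reshape(-1)
    plog = plog_nk.reshape(n * Kk, -1)[keep]

    # atom confidence head: 1D track plus direct geometric cues — the atom's
    # neighbor-distance histogram, how far this block moved it, and the pair
    # head's expected |distance error| — with a linear skip path so small
    # geometric signals are not squashed by the tanh MLP
    dij_now = ad.norm(xv_now[safe] - xv_now.reshape(n, 1, 3), eps=1e-10)
    geo = agg(_rbf(dij_now, cfg.n_rbf))
    moved = ad.norm(x - Tensor(state.x.value), eps=1e-10).reshape(n, 1)
    abs_centers = np.abs(_pair_bin_centers(cfg.n_pair_bins))
    exp_err = (ad.softmax(plog_nk, axis=-1) * abs_centers).sum(axis=-1)
    pair_err_feat = agg(exp_err.reshape(n, Kk, 1))
    geo_in = ad.concatenate([geo, moved, pair_err_feat], axis=-1)
    hin = ad.concatenate([s, geo_in], axis=-1)
    hc = (hin @ params["conf_w1"] + params["conf_b1"]).tanh() @ params["conf_w2"] \
        + geo_in @ params["conf_skip"] + params["conf_b2"]
    log_sigma = hc[:, 0].clip_min(np.log(SIGMA_MIN)).clip_max(np.log(SIGMA_MAX))
    sigma = log_sigma.exp()
    plddt = hc[:, 1].sigmoid()
    conf = ConfidenceOutput(sigma=sigma, plddt=plddt, pair_logits=plog,
                            pairs=pair_pairs[keep])
    if not np.isfinite(x.value).all():
        raise FloatingPointError(f"non-finite update in block {block_index}")
    return TrackState(s=s, p=p, x=x, graph=graph, feat2d=state.feat2d), conf


def forward(graph: ChemGraph, corrupted: Conformation, params: dict,
            cfg: ModelConfig, n_blocks=None):
    """Run `n_blocks` shared-weight iterations (default from config).

    Returns ``(final Conformation, confidences per block, coords per block)``
    where coordinates are Tensors so losses applied after every iteration
    can differentiate back to the parameters. The network itself is
    deterministic; all stochasticity lives in the corruption.
    """
    nb = cfg.n_blocks if n_blocks is None else n_blocks
    state = embed_inputs(graph, corrupted, params, cfg)
    confidences, coords_per_block = [], []
    for b in range(nb):
        state, conf = iteration_block(state, params, cfg, block_index=b)
        confidences.append(conf)
        coords_per_block.append(state.x)
    final = Conformation(state.x.value.copy(), corrupted.mask.copy())
    return final, confidences, coords_per_block
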