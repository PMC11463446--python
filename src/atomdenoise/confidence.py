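"""Confidence targets, likelihoods and pRMSD aggregation.

The network predicts, per atom, a positional deviation σᵢ (Å) trained by
maximizing the Gaussian likelihood of the actual deviations dᵢ of the model
from the reference, a per-atom lDDT, and per-neighbor-pair logits over
signed distance-error bins. σ values aggregate over any atom selection into
the predicted RMSD, pRMSD = sqrt(mean σᵢ²), used downstream to rank sampled
models and to score active-site preorganization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .autodiff import Tensor
from .chemgraph import ChemGraph, Conformation
from .geometry import _coords_of, _local_coords, enumerate_frames

SIGMA_MIN = 0.05  # Å, training floor
SIGMA_MAX = 20.0  # Å, cap keeping the NLL bounded on corrupted inputs

#: signed distance-error bin edges (Å); open tails on both sides
DEFAULT_PAIR_BIN_EDGES = (-4.0, -2.0, -1.0, -0.5, 0.5, 1.0, 2.0, 4.0)


@dataclass
class ConfidenceOutput:
    sigma: np.ndarray  # per-atom σᵢ, Å, strictly positive
    plddt: np.ndarray  # per-atom predicted lDDT in [0, 1]
    pair_logits: Optional[np.ndarray] = None  # (n_pairs, n_bins)
    pairs: Optional[np.ndarray] = None  # (n_pairs, 2) atom indices

    def __post_init__(self):
        sig = np.asarray(self.sigma.value if isinstance(self.sigma, Tensor)
                         else self.sigma)
        pl = np.asarray(self.plddt.value if isinstance(self.plddt, Tensor)
                        else self.plddt)
        if (sig <= 0).any():
            raise ValueError("sigma must be strictly positive")
        if ((pl < 0) | (pl > 1)).any():
            raise ValueError("plddt must lie in [0, 1]")


def superpose(model_coords: np.ndarray, reference_coords: np.ndarray,
              mask: Optional[np.ndarray] = None):
    """Optimal rigid superposition of model onto reference (Kabsch).

    Returns the transformed model coordinates for *all* atoms, with the fit
    computed over the masked subset.
    """
    m = np.asarray(model_coords, dtype=float)
    r = np.asarray(reference_coords, dtype=float)
    sel = np.ones(len(m), dtype=bool) if mask is None else np.asarray(mask, bool)
    if sel.sum() < 3:
        raise ValueError("superposition needs at least 3 resolved atoms")
    mc, rc = m[sel].mean(axis=0), r[sel].mean(axis=0)
    rot, _ = Rotation.align_vectors(r[sel] - rc, m[sel] - mc)
    return rot.apply(m - mc) + rc


def deviation_targets(model, reference, policy: str = "global-superposition",
                      graph: Optional[ChemGraph] = None) -> np.ndarray:
    """Per-atom deviations dᵢ (Å) of the model from the reference.

    ``global-superposition`` (default): distances after optimal rigid
    superposition over all resolved atoms. ``frame-median``: median of the
    frame-local deviations over the FAPE frames (needs `graph`).
    """
    mcoords, mmask = _coords_of(model)
    rcoords, rmask = _coords_of(reference)
    mcoords = np.asarray(mcoords.value if isinstance(mcoords, Tensor) else mcoords)
    rcoords = np.asarray(rcoords.value if isinstance(rcoords, Tensor) else rcoords)
    mask = np.ones(len(mcoords), dtype=bool)
    if mmask is not None:
        mask &= mmask
    if rmask is not None:
        mask &= rmask
    if policy == "global-superposition":
        fitted = superpose(mcoords, rcoords, mask)
        return np.linalg.norm(fitted - rcoords, axis=1)
    if policy == "frame-median":
        if graph is None:
            raise ValueError("frame-median policy needs the chemical graph")
        frames = enumerate_frames(graph, reference)
        if not frames:
            raise ValueError("no frames available for frame-median deviations")
        a, b, c = (np.array(x) for x in zip(*frames))
        lm = _local_coords(mcoords, a, b, c).value
        lr = _local_coords(rcoords, a, b, c).value
        return np.median(np.linalg.norm(lm - lr, axis=-1), axis=0)
    raise ValueError(f"unknown policy {policy!r}")


def gaussian_nll(d, sigma):
    """Per-atom negative log likelihood of deviation d under N(0, σ²).

    Reduced to the sufficient statistic: ln σ + d² / (2σ²) (up to an
    additive constant); works on arrays or Tensors and is differentiable
    in σ. The argmin over σ for fixed d is σ = d.
    """
    if isinstance(sigma, Tensor):
        if (sigma.value <= 0).any():
            raise ValueError("sigma must be positive")
        dd = d.detach() if isinstance(d, Tensor) else Tensor(np.asarray(d, float))
        return sigma.log() + dd * dd / (2.0 * sigma * sigma)
    sigma = np.asarray(sigma, dtype=float)
    if (sigma <= 0).any():
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    return np.log(sigma) + d**2 / (2.0 * sigma**2)


def prmsd(sigmas) -> float:
    """Predicted RMSD over a selection: sqrt(mean of σᵢ²)."""
    sigmas = np.asarray(sigmas, dtype=float)
    if sigmas.size == 0:
        raise ValueError("pRMSD of an empty selection is undefined")
    return float(np.sqrt(np.mean(sigmas**2)))


def pair_error_targets(model, reference, pairs,
                       bin_edges=DEFAULT_PAIR_BIN_EDGES) -> np.ndarray:
    """Per-pair signed distance-error bin index.

    Signed error = d_model − d_reference; edges are open-tailed, so with the
    default 8 edges there are 9 bins and bin 4 is the central (−0.5, 0.5) Å
    band.
    """
    mcoords, _ = _coords_of(model)
    rcoords, _ = _coords_of(reference)
    mcoords = np.asarray(mcoords.value if isinstance(mcoords, Tensor) else mcoords)
    rcoords = np.asarray(rcoords.value if isinstance(rcoords, Tensor) else rcoords)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    dm = np.linalg.norm(mcoords[pairs[:, 0]] - mcoords[pairs[:, 1]], axis=1)
    dr = np.linalg.norm(rcoords[pairs[:, 0]] - rcoords[pairs[:, 1]], axis=1)
    return np.digitize(dm - dr, bin_edges)
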