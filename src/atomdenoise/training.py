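"""Desk-scale training for the micro denoiser.

Two-stage schedule: stage 1 runs a reduced block count with all-atom FAPE as
the only loss; stage 2 raises the block count and adds the bonded-geometry,
chirality and confidence losses. All losses are applied to the output of
every iteration block. One adaptive optimizer (Adam), global-norm gradient
clipping at 1.0, fixed seeds everywhere — a given (dataset, config,
schedule, seed) reproduces the loss trace to floating-point determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chemgraph import Conformation
from .confidence import gaussian_nll, pair_error_targets, deviation_targets
from .corruption import CorruptionConfig, corrupt
from .geometry import (bonded_geometry_loss, chirality_loss, fape_allatom,
                       lddt_per_atom)
from .network import ModelConfig, forward, init_params


@dataclass
class TrainSchedule:
    stage1_steps: int = 350
    stage2_steps: int = 450
    stage1_blocks: int = 1
    stage2_blocks: Optional[int] = None  # default: the config's n_blocks
    lr: float = 3e-3
    lr_floor_frac: float = 0.15  # cosine decay down to this fraction of lr
    grad_clip: float = 1.0
    batch_max: int = 8  # systems averaged per step
    w_fape: float = 1.0
    w_bond: float = 1.0  # Å⁻¹
    w_angle: float = 0.02  # deg⁻¹
    w_chiral: float = 1.0
    w_conf: float = 0.05
    fape_clamp: float = 10.0
    corruption: CorruptionConfig = field(
        default_factory=lambda: CorruptionConfig(mode="training"))


class Adam:
    def __init__(self, params: dict, lr: float, clip: float = 1.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.clip = lr, clip
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        grads = {k: p.grad for k, p in self.params.items() if p.grad is not None}
        gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
        scale = min(1.0, self.clip / (gnorm + 1e-12))
        for k, g in grads.items():
            g = g * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k].value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def _step_loss(graph, ref, coords_blocks, confidences, stage2: bool,
               sched: TrainSchedule):
    """Loss summed over iteration blocks (every-iteration supervision)."""
    total = Tensor(0.0)
    fape_last = None
    for x, conf in zip(coords_blocks, confidences):
        fape = fape_allatom(x, ref, graph, clamp=sched.fape_clamp)
        fape_last = float(fape.value)
        term = sched.w_fape * fape
        if stage2:
            term = term + bonded_geometry_loss(x, ref, graph,
                                               w_bond=sched.w_bond,
                                               w_angle=sched.w_angle)
            if graph.chiral_centers:
                term = term + sched.w_chiral * chirality_loss(x, graph.chiral_centers)
            d = deviation_targets(Conformation(x.value, ref.mask), ref)
            nll_all = gaussian_nll(d, conf.sigma)
            # balance over roles so abundant easy backbone atoms do not
            # drown out the ligand / side-chain deviation signal
            roles = graph.roles()
            role_means = [nll_all[np.where(roles == r)[0]].mean()
                          for r in ("backbone", "sidechain", "ligand")
                          if (roles == r).any()]
            nll = role_means[0]
            for rm in role_means[1:]:
                nll = nll + rm
            nll = nll / float(len(role_means))
            lddt_true, defined = lddt_per_atom(x.value, ref, graph)
            conf_loss = nll
            if defined.any():
                pl_err = (conf.plddt[np.where(defined)[0]]
                          - lddt_true[defined]) ** 2
                conf_loss = conf_loss + pl_err.mean()
            if conf.pairs is not None and len(conf.pairs):
                bins = pair_error_targets(x.value, ref, conf.pairs)
                logp = ad.log_softmax(conf.pair_logits, axis=-1)
                conf_loss = conf_loss - logp[np.arange(len(bins)), bins].mean()
            term = term + sched.w_conf * conf_loss
        total = total + term
    return total / float(len(coords_blocks)), fape_last


def train_micro(dataset, cfg: Optional[ModelConfig] = None,
                sched: Optional[TrainSchedule] = None,
                params: Optional[dict] = None, verbose: bool = False):
    """Train the micro model on <= 50 fixture systems.

    `dataset` is a list of ``(graph, reference)`` pairs (a fixture tuple
    ``(spec, graph, reference)`` is also accepted). Returns
    ``(params, trace)`` where `trace` records per-step stage, loss and FAPE.

    Raises ``FloatingPointError`` (with the trace attached) on divergence.
    """
    cfg = cfg or ModelConfig.micro()
    sched = sched or TrainSchedule()
    items = [(it[-2], it[-1]) for it in dataset]
    if len(items) > 50:
        raise ValueError("desk-scale training is capped at 50 systems")
    if params is None:
        params = init_params(cfg)
    opt = Adam(params, lr=sched.lr, clip=sched.grad_clip)
    trace = []
    stage2_blocks = sched.stage2_blocks or cfg.n_blocks
    total_steps = sched.stage1_steps + sched.stage2_steps
    base_seed = (sched.corruption.seed * 1000003 + 17) % (2**31)
    batch_rng = np.random.default_rng(base_seed + 1)
    for step in range(total_steps):
        stage2 = step >= sched.stage1_steps
        n_blocks = stage2_blocks if stage2 else sched.stage1_blocks
        # cosine decay to lr * lr_floor_frac
        frac = sched.lr_floor_frac + (1 - sched.lr_floor_frac) * 0.5 * (
            1 + np.cos(np.pi * step / total_steps))
        opt.lr = sched.lr * frac
        if len(items) <= sched.batch_max:
            batch = list(range(len(items)))
        else:
            batch = list(batch_rng.choice(len(items), sched.batch_max,
                                          replace=False))
        loss = Tensor(0.0)
        fapes = []
        for k in batch:
            graph, ref = items[k]
            cseed = (base_seed + step * 1009 + k * 7919) % (2**31)
            corrupted = corrupt(graph, ref, sched.corruption, seed=cseed)
            _, confs, coords_blocks = forward(graph, corrupted, params, cfg,
                                              n_blocks=n_blocks)
            item_loss, fape_last = _step_loss(graph, ref, coords_blocks,
                                              confs, stage2, sched)
            loss = loss + item_loss
            fapes.append(fape_last)
        loss = loss / float(len(batch))
        if not np.isfinite(loss.value):
            err = FloatingPointError(f"training diverged at step {step}")
            err.trace = trace
            raise err
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append({"step": step, "stage": 2 if stage2 else 1,
                      "n_blocks": n_blocks, "loss": float(loss.value),
                      "fape": float(np.mean(fapes))})
        if verbose and step % 50 == 0:
            print(f"step {step:5d} stage {2 if stage2 else 1} "
                  f"loss {float(loss.value):8.4f} fape {np.mean(fapes):7.4f}")
    return params, trace


def calibrate_confidence(items, params, cfg: ModelConfig,
                         corruption: CorruptionConfig, steps: int = 200,
                         lr: float = 5e-3, seed: int = 999331):
    """Post-hoc confidence calibration: freeze the structure weights and fit
    only the confidence heads by the role-balanced Gaussian NLL (plus the
    pair-bin cross entropy) on fresh corruptions of the training systems.

    With the features frozen this is a plain regression of realized
    deviations onto them, which sharpens the conditional spread of σ —
    exactly what pRMSD ranking relies on.
    """
    items = [(it[-2], it[-1]) for it in items]
    head = {k: p for k, p in params.items()
            if k.startswith("conf_") or k.startswith("pairconf_")}
    opt = Adam(head, lr=lr, clip=1.0)
    trace = []
    for step in range(steps):
        graph, ref = items[step % len(items)]
        cseed = (seed + step * 613) % (2**31)
        corrupted = corrupt(graph, ref, corruption, seed=cseed)
        _, confs, coords_blocks = forward(graph, corrupted, params, cfg)
        x, conf = coords_blocks[-1], confs[-1]
        d = deviation_targets(Conformation(x.value, ref.mask), ref)
        nll_all = gaussian_nll(d, conf.sigma)
        roles = graph.roles()
        role_means = [nll_all[np.where(roles == r)[0]].mean()
                      for r in ("backbone", "sidechain", "ligand")
                      if (roles == r).any()]
        loss = role_means[0]
        for rm_ in role_means[1:]:
            loss = loss + rm_
        loss = loss / float(len(role_means))
        if conf.pairs is not None and len(conf.pairs):
            bins = pair_error_targets(x.value, ref, conf.pairs)
            logp = ad.log_softmax(conf.pair_logits, axis=-1)
            loss = loss - 0.2 * logp[np.arange(len(bins)), bins].mean()
        opt.zero_grad()
        for p in params.values():
            p.grad = None
        loss.backward()
        opt.step()
        trace.append(float(loss.value))
    return trace


def evaluate_denoising(items, params, cfg, corruption: CorruptionConfig,
                       n_runs: int = 20, seed: int = 10**6):
    """Denoise each system from `n_runs` fresh corruptions; report FAPE and
    all-atom RMSD (after optimal superposition) per run."""
    from .confidence import deviation_targets as _dev

    results = []
    for k, item in enumerate(items):
        graph, ref = item[-2], item[-1]
        for r in range(n_runs):
            corrupted = corrupt(graph, ref, corruption,
                                seed=(seed + 7919 * k + r) % (2**31))
            final, confs, _ = forward(graph, corrupted, params, cfg)
            fape = fape_allatom(final, ref, graph)
            d = _dev(final, ref)
            rmsd = float(np.sqrt(np.mean(d**2)))
            results.append({"system": k, "run": r, "fape": fape, "rmsd": rmsd})
    return results
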