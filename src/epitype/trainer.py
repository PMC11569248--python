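"""Two-stage training with frozen-backbone latent caching.

Stage 1 (pre-training) fits the two branches separately, each with its
own Adam optimiser: the DNA heads against the cross-cell average
(Poisson negative log-likelihood) and distribution (cross-entropy
against the soft target simplex), and the celltyping branch against the
cell-minus-average delta (mean squared error).  Stage 2 trains the
combined model end to end with Poisson NLL on the arcsinh-scale
cell-specific signal, early-stopping on validation loss and returning
the best-validation checkpoint.

Because the backbone is frozen, its latent for each unique
(region, strand, shift) input is computed once and cached on disk; the
cache is invalidated when the backbone's weight hash changes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, StaleCacheError, TrainingDivergedError
from .features import build_celltype_features
from .model import CelltypeFeatures, EpitypeModel, ModelConfig
from .nn import Adam, Tensor
from .nn import autograd as ag
from .regions import RegionSpec, TargetBundle, TrainItem, build_targets
from .seq import one_hot, rc_one_hot
from .tracks import BinnedTrack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# losses


def poisson_nll(pred, target):
    """Mean over elements of (pred − target·ln pred); the ln(target!)
    term is constant in the prediction and omitted."""
    if isinstance(pred, Tensor):
        if np.any(pred.data <= 0):
            raise ConfigError("Poisson NLL requires strictly positive predictions")
        return (pred - Tensor(np.asarray(target, float)) * ag.log(pred)).mean()
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if np.any(pred <= 0):
        raise ConfigError("Poisson NLL requires strictly positive predictions")
    if np.any(target < 0):
        raise ConfigError("Poisson NLL requires non-negative targets")
    return float(np.mean(pred - target * np.log(pred)))


def soft_cross_entropy(dist_pred: Tensor, target: np.ndarray) -> Tensor:
    """−mean Σ_k t_k log p_k against the soft target simplex."""
    return -(Tensor(target) * ag.log(dist_pred + 1e-12)).sum(axis=-1).mean()


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    d = pred - Tensor(np.asarray(target, float))
    return (d * d).mean()


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TrainProfile:
    steps_pretrain: int
    steps_full: int
    batch_size: int

    @classmethod
    def toy(cls) -> "TrainProfile":
        return cls(steps_pretrain=200, steps_full=500, batch_size=8)

    @classmethod
    def paper(cls) -> "TrainProfile":
        return cls(steps_pretrain=1000, steps_full=6940, batch_size=128)


@dataclass
class TrainState:
    stage: str = "pretrain"
    step: int = 0
    lr_pretrain: float = 0.0002
    lr_full: float = 0.005
    batch_size: int = 8
    seed: int = 0
    patience: int = 3
    eval_every: int = 50
    best_val: float = float("inf")

    def __post_init__(self) -> None:
        if self.lr_pretrain <= 0 or self.lr_full <= 0:
            raise ConfigError("learning rates must be positive")


# ---------------------------------------------------------------------------
# data materialisation


class RegionDataset:
    """Turns (region, cell, strand, shift) items into model arrays.

    Holds the genome sequences, arcsinh histone tracks per mark and
    cell, arcsinh accessibility per cell plus the training average, and
    the marker-gene table.  Average/distribution targets pool the
    training cells only, so held-out cells never leak into them.
    """

    def __init__(
        self,
        sequences: Mapping[str, str],
        histone: Mapping[str, Mapping[str, BinnedTrack]],
        atac: Mapping[str, BinnedTrack],
        atac_avg: BinnedTrack,
        markers: pd.DataFrame,
        mcfg: ModelConfig,
        avg_cells: Sequence[str],
    ):
        self.sequences = sequences
        self.histone = histone
        self.atac = atac
        self.atac_avg = atac_avg
        self.markers = markers
        self.mcfg = mcfg
        self.avg_cells = list(avg_cells)
        self.marks = sorted(histone)
        if len(self.marks) != mcfg.n_marks:
            raise ConfigError("histone mark count disagrees with model config")
        self._global_cache: dict[str, np.ndarray] = {}

    def latent_key(self, item: TrainItem) -> str:
        r = item.region
        return f"{r.chrom}:{r.window_start}:{item.strand}:{item.shift}"

    def onehot(self, item: TrainItem) -> np.ndarray:
        """(4, input_len) one-hot for the item's augmented window."""
        r, cfg = item.region, self.mcfg.data
        start = r.input_start + item.shift
        seq = self.sequences[r.chrom][start : start + cfg.input_len]
        oh = one_hot(seq)
        if item.strand == "-":
            oh = rc_one_hot(oh)
        return oh.T

    def features(self, item: TrainItem) -> CelltypeFeatures:
        feats = build_celltype_features(
            item.region,
            self.atac[item.cell],
            self.atac_avg,
            self.markers,
            self.mcfg,
            window_start=item.region.window_start + item.shift,
        )
        if item.strand == "-":
            feats = CelltypeFeatures(
                feats.local_delta[::-1].copy(), feats.global_vec
            )
        return feats

    def targets(self, item: TrainItem) -> TargetBundle:
        bundle = build_targets(
            item.region,
            self.histone,
            item.cell,
            self.mcfg.data,
            window_start=item.region.window_start + item.shift,
            cell_pool=self.avg_cells,
        )
        if item.strand == "-":
            bundle = TargetBundle(
                bundle.avg[::-1].copy(),
                bundle.dist[::-1].copy(),
                bundle.delta[::-1].copy(),
                bundle.cell_signal[::-1].copy(),
            )
        return bundle


# ---------------------------------------------------------------------------
# latent cache


class LatentCache:
    """Disk-backed map (region, strand, shift) -> frozen-backbone latent."""

    def __init__(self, path: str | Path, backbone_hash: str):
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)
        meta = self.path / "meta.json"
        if meta.exists():
            stored = json.loads(meta.read_text())["backbone_hash"]
            if stored != backbone_hash:
                raise StaleCacheError(
                    f"cache built for backbone {stored[:12]}, "
                    f"current is {backbone_hash[:12]}"
                )
        else:
            meta.write_text(json.dumps({"backbone_hash": backbone_hash}))
        self.backbone_hash = backbone_hash

    def _file(self, key: str) -> Path:
        safe = key.replace(":", "_").replace("-", "m").replace("+", "p")
        return self.path / f"{safe}.npy"

    def get(self, key: str) -> np.ndarray | None:
        f = self._file(key)
        return np.load(f) if f.exists() else None

    def put(self, key: str, latent: np.ndarray) -> None:
        np.save(self._file(key), latent)


def cache_latents(
    backbone,
    dataset: RegionDataset,
    items: Sequence[TrainItem],
    store_path: str | Path,
) -> LatentCache:
    """Persist the frozen backbone's latent for every unique input."""
    cache = LatentCache(store_path, backbone.state_hash())
    seen: set[str] = set()
    for item in items:
        key = dataset.latent_key(item)
        if key in seen:
            continue
        seen.add(key)
        if cache.get(key) is None:
            latent = backbone.forward_full(Tensor(dataset.onehot(item)[None])).data[0]
            cache.put(key, latent)
    return cache


def _batch_latents(
    backbone, dataset: RegionDataset, items: Sequence[TrainItem],
    cache: LatentCache | None,
) -> np.ndarray:
    out = []
    for item in items:
        key = dataset.latent_key(item)
        latent = cache.get(key) if cache is not None else None
        if latent is None:
            latent = backbone.forward_full(Tensor(dataset.onehot(item)[None])).data[0]
            if cache is not None:
                cache.put(key, latent)
        out.append(latent)
    return np.stack(out)


def _check_finite(loss: float, state: TrainState, traces: dict) -> None:
    if not np.isfinite(loss):
        err = TrainingDivergedError(
            f"non-finite loss at stage={state.stage} step={state.step}"
        )
        err.state = state          # state dump for post-mortem
        err.traces = traces
        raise err


# ---------------------------------------------------------------------------
# training stages


def pretrain(
    model: EpitypeModel,
    dataset: RegionDataset,
    items: Sequence[TrainItem],
    state: TrainState,
    steps: int = 200,
    cache: LatentCache | None = None,
) -> dict[str, list[float]]:
    """Stage-1 training; returns per-step loss traces."""
    rng = np.random.default_rng(state.seed)
    state.stage = "pretrain"
    dna_params = (
        model.dna_trunk.trainable_parameters()
        + model.avg_head.trainable_parameters()
        + model.dist_head.trainable_parameters()
    )
    ct_params = [
        p
        for p in model.trainable_parameters()
        if not any(p is q for q in dna_params)
        and not any(p is q for q in model.comb_conv.parameters())
        and not any(p is q for q in model.comb_out.parameters())
    ]
    opt_dna = Adam(dna_params, lr=state.lr_pretrain)
    opt_ct = Adam(ct_params, lr=state.lr_pretrain)
    # the avg/dist targets are cell-independent: deduplicate DNA inputs
    uniq: dict[str, TrainItem] = {}
    for it in items:
        uniq.setdefault(dataset.latent_key(it), it)
    dna_items = list(uniq.values())
    traces: dict[str, list[float]] = {"avg": [], "dist": [], "delta": []}
    crop = (model.cfg.latent_positions - model.cfg.n_bins) // 2
    sl = slice(crop, crop + model.cfg.n_bins)
    for _ in range(steps):
        state.step += 1
        # --- DNA submodule
        batch = [dna_items[i] for i in
                 rng.integers(len(dna_items), size=state.batch_size)]
        latents = _batch_latents(model.backbone, dataset, batch, cache)
        avg_pred, dist_pred = model.dna_branch(Tensor(latents))
        tgt = [dataset.targets(b) for b in batch]
        avg_t = np.stack([t.avg for t in tgt])
        dist_t = np.stack([t.dist for t in tgt])
        loss_avg = poisson_nll(avg_pred[:, sl, :], avg_t)
        loss_dist = soft_cross_entropy(dist_pred[:, sl, :, :], dist_t)
        opt_dna.zero_grad()
        (loss_avg + loss_dist).backward()
        opt_dna.step()
        # --- celltyping submodule
        batch_ct = [items[i] for i in
                    rng.integers(len(items), size=state.batch_size)]
        feats = [dataset.features(b) for b in batch_ct]
        delta_pred = model.celltyping_branch(
            Tensor(np.stack([f.local_delta for f in feats])),
            Tensor(np.stack([f.global_vec for f in feats])),
        )
        delta_t = np.stack([dataset.targets(b).delta for b in batch_ct])
        loss_delta = mse(delta_pred[:, sl, :], delta_t)
        opt_ct.zero_grad()
        loss_delta.backward()
        opt_ct.step()
        traces["avg"].append(float(loss_avg.data))
        traces["dist"].append(float(loss_dist.data))
        traces["delta"].append(float(loss_delta.data))
        for k in traces:
            _check_finite(traces[k][-1], state, traces)
    return traces


def _full_loss(
    model: EpitypeModel,
    dataset: RegionDataset,
    batch: Sequence[TrainItem],
    cache: LatentCache | None,
) -> Tensor:
    latents = _batch_latents(model.backbone, dataset, batch, cache)
    feats = [dataset.features(b) for b in batch]
    out = model.forward(
        Tensor(np.zeros((len(batch), 4, model.cfg.data.input_len))),
        Tensor(np.stack([f.local_delta for f in feats])),
        Tensor(np.stack([f.global_vec for f in feats])),
        latent=Tensor(latents),
    )
    target = np.stack([dataset.targets(b).cell_signal for b in batch])
    return poisson_nll(out["combined"], target)


def train_full(
    model: EpitypeModel,
    dataset: RegionDataset,
    train_items: Sequence[TrainItem],
    val_items: Sequence[TrainItem],
    state: TrainState,
    steps: int = 500,
    cache: LatentCache | None = None,
    max_val_items: int = 16,
) -> dict[str, list[float]]:
    """Stage-2 combined training with early stopping on validation loss.

    The best-validation parameters are restored before returning.
    """
    if not val_items:
        raise ConfigError("validation set is empty")
    rng = np.random.default_rng(state.seed + 1)
    state.stage = "full"
    params = model.trainable_parameters()
    opt = Adam(params, lr=state.lr_full)
    traces: dict[str, list[float]] = {"train": [], "val": [], "val_step": []}
    val_sub = list(val_items)
    if len(val_sub) > max_val_items:
        idx = rng.choice(len(val_sub), size=max_val_items, replace=False)
        val_sub = [val_sub[i] for i in idx]
    best = None
    bad_evals = 0
    for _ in range(steps):
        state.step += 1
        batch = [train_items[i] for i in
                 rng.integers(len(train_items), size=state.batch_size)]
        loss = _full_loss(model, dataset, batch, cache)
        opt.zero_grad()
        loss.backward()
        opt.step()
        traces["train"].append(float(loss.data))
        _check_finite(traces["train"][-1], state, traces)
        if state.step % state.eval_every == 0 or state.step == steps:
            val_loss = float(_full_loss(model, dataset, val_sub, cache).data)
            traces["val"].append(val_loss)
            traces["val_step"].append(state.step)
            _check_finite(val_loss, state, traces)
            if val_loss < state.best_val:
                state.best_val = val_loss
                best = [p.data.copy() for p in params]
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals >= state.patience:
                    break
    if best is not None:
        for p, b in zip(params, best):
            p.data[...] = b
    return traces
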