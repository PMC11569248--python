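"""The dual-branch architecture at any configured scale.

A frozen, pluggable DNA *backbone* (a convolution/pooling stack standing
behind the same contract a chopped pre-trained sequence transformer
would satisfy) maps one-hot DNA at base resolution to a latent grid at
bin resolution.  Two trainable branches sit on top:

* the **DNA branch** predicts, per output bin and histone mark, the
  cross-cell average signal (positive rate, soft-plus link, suitable for
  a Poisson likelihood) and the distribution of signal across training
  cells (a K-simplex per bin and mark);
* the **celltyping branch** embeds the cell's local chromatin
  accessibility (expressed as arcsinh-scale deviation from the training
  average) and a fixed-length global accessibility summary at marker
  gene TSSs, and predicts the signed cell-minus-average delta.

A combined head concatenates [avg ∥ dist ∥ delta] channelwise per bin,
applies a convolutional block and per-mark dense heads with a positive
link, and predicts the cell-type-specific arcsinh signal over the
centre predictive window; sinh converts back to the -log10 p scale.

Internally every stage keeps the full input-resolution grid and only
the final step crops to the predictive window, so a purely
convolutional configuration is translation-equivariant over windows
whose receptive field stays inside the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, ShapeError
from .nn import Tensor, autograd as ag
from .nn.layers import Conv1d, Dense, Module, Parameter
from .regions import DataConfig


# ---------------------------------------------------------------------------
# backbone


class ConvBackbone(Module):
    """Frozen convolution/pooling stack: (L, 4) one-hot -> latent grid.

    ``log2(bin)`` stages of same-padded convolution + width-2 average
    pooling reduce base resolution to bin resolution.  The dependency
    interval of every latent position on the input is computed exactly
    by interval propagation, giving an analytic receptive field.
    """

    def __init__(self, cfg: "ModelConfig", seed: int):
        data = cfg.data
        n_pool = int(np.log2(data.bin))
        if 2**n_pool != data.bin:
            raise ConfigError("bin size must be a power of two for the toy backbone")
        rng = np.random.default_rng(seed)
        c = cfg.backbone_channels
        k = cfg.backbone_kernel
        self.stem = Conv1d(4, c, cfg.backbone_stem_kernel, rng)
        self.stages = [Conv1d(c, c, k, rng) for _ in range(n_pool)]
        self.kernel = k
        self.stem_kernel = cfg.backbone_stem_kernel
        self.activation = cfg.backbone_activation
        self.n_pool = n_pool
        self.channels = c
        self.input_len = data.input_len
        self.latent_positions = data.input_len // data.bin
        self.window_bins = data.n_bins
        self.bin = data.bin
        self.calls = 0  # forward-pass counter, used to verify cache hits
        self.freeze()

    # -- geometry ----------------------------------------------------------

    def _span(self, lo: int, hi: int) -> tuple[int, int]:
        # invert each forward stage back to front: first the width-2
        # pooling ([2a, 2b+1]), then the same-padded conv (± kernel//2)
        half = self.kernel // 2
        for _ in range(self.n_pool):
            lo, hi = 2 * lo - half, 2 * hi + 1 + half
        s = self.stem_kernel // 2
        return lo - s, hi + s  # stem conv

    def latent_span(self, lo: int, hi: int) -> tuple[int, int]:
        """Exact input-base dependency interval of latent positions [lo, hi]."""
        lo, hi = self._span(lo, hi)
        return max(lo, 0), min(hi, self.input_len - 1)

    @property
    def receptive_field(self) -> int:
        """Declared receptive field R in bp: the dependency width of a
        single latent position away from the input edges."""
        lo, hi = self._span(0, 0)
        return hi - lo + 1

    # -- forward -----------------------------------------------------------

    def forward_full(self, onehot: Tensor) -> Tensor:
        """Latent over the full input grid: (N, C, input_len/bin)."""
        if onehot.shape[-2:] != (4, self.input_len) and onehot.shape != (4, self.input_len):
            raise ShapeError(
                f"backbone expects (N, 4, {self.input_len}), got {onehot.shape}"
            )
        self.calls += 1
        act = ag.relu if self.activation == "relu" else ag.tanh
        h = act(self.stem(onehot))
        for conv in self.stages:
            h = ag.max_pool1d(act(conv(h)), 2)
        return h

    def __call__(self, onehot: np.ndarray) -> np.ndarray:
        """Contract forward: (L, 4) one-hot -> (T, C) latent over the
        centre predictive window."""
        x = Tensor(onehot.T[None])
        h = self.forward_full(x).data[0]  # (C, T_in)
        crop = (self.latent_positions - self.window_bins) // 2
        return h[:, crop : crop + self.window_bins].T


def make_toy_backbone(cfg: "ModelConfig", seed: int) -> ConvBackbone:
    """A deterministic, frozen stand-in DNA backbone with an analytically
    computable receptive field.

    The weights are random: sufficient for every geometry, determinism
    and receptive-field contract.  For end-to-end experiments that need
    the backbone to carry sequence features (as a chopped pre-trained
    sequence model would), see :func:`make_matched_backbone`.
    """
    return ConvBackbone(cfg, seed)


def make_matched_backbone(
    cfg: "ModelConfig", motifs: Sequence[str], seed: int
) -> ConvBackbone:
    """Synthetic stand-in for a *pre-trained* DNA backbone.

    A backbone chopped from a trained sequence model carries motif-level
    feature detectors in its convolution tower; a randomly initialised
    stack does not (its pooled features reduce to base composition, so
    nothing downstream can recover sequence-driven signal).  This
    constructor emulates the pre-trained artifact directly: one stem
    channel per motif (and per reverse complement) is set to an
    exact-match filter with a threshold bias, the pooling stages
    propagate detections by identity convolution under max pooling, and
    the remaining channels keep their random weights as texture
    features.  The result is deterministic, frozen, and satisfies the
    same contract as :func:`make_toy_backbone`.

    ``motifs`` is the motif vocabulary of the genome the backbone is
    notionally pre-trained on (for synthetic genomes, the planted
    grammar's consensus strings).
    """
    from .seq import reverse_complement, _IDX

    bb = ConvBackbone(cfg, seed)
    k = bb.stem_kernel
    n_matched = 2 * len(motifs)
    if n_matched > bb.channels:
        raise ConfigError(
            f"{len(motifs)} motifs need {n_matched} channels, have {bb.channels}"
        )
    if any(len(m) > k for m in motifs):
        raise ConfigError(f"motifs longer than the stem kernel ({k} bp)")
    w = bb.stem.w.data
    b = bb.stem.b.data
    w[:n_matched] = 0.0
    for i, motif in enumerate(motifs):
        for j, variant_motif in enumerate((motif, reverse_complement(motif))):
            c = 2 * i + j
            for off, base in enumerate(variant_motif):
                w[c, _IDX[base], off] = 1.0
            b[c] = -(len(variant_motif) - 0.5)  # fires only on exact match
    w[n_matched:] *= 0.25  # keep texture channels from drowning detections
    for conv in bb.stages:
        conv.w.data[:] = 0.0
        conv.b.data[:] = 0.0
        mid = conv.kernel // 2
        for c in range(bb.channels):
            conv.w.data[c, c, mid] = 1.0
    return bb


# ---------------------------------------------------------------------------
# configuration and feature container


@dataclass(frozen=True)
class ModelConfig:
    data: DataConfig = field(default_factory=DataConfig)
    n_marks: int = 3
    n_marker_genes: int = 8
    backbone_channels: int = 32
    backbone_kernel: int = 5
    backbone_stem_kernel: int = 9
    backbone_activation: str = "relu"  # "relu" or "tanh"
    trunk_channels: int = 32
    local_embed_dim: int = 8
    global_embed_dim: int = 16
    global_pool: int = 4
    hidden_dim: int = 64
    combined_channels: int = 32
    position_dependent_celltyping: bool = True
    positive_link: str = "softplus"  # or "exp"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_marks < 1:
            raise ConfigError("n_marks must be >= 1")
        if self.global_len % self.global_pool:
            raise ConfigError("global vector length must divide global_pool")

    @property
    def global_len(self) -> int:
        return self.n_marker_genes * (self.data.tss_window // self.data.global_bin)

    @property
    def local_len(self) -> int:
        return self.data.local_atac_len // self.data.bin

    @property
    def n_bins(self) -> int:
        return self.data.n_bins

    @property
    def latent_positions(self) -> int:
        return self.data.input_len // self.data.bin


@dataclass
class CelltypeFeatures:
    """Cell-identity inputs: local accessibility delta and global summary."""

    local_delta: np.ndarray  # (local_atac_len / bin,), arcsinh-delta scale
    global_vec: np.ndarray   # (n_marker_genes * tss_window / global_bin,)

    def validate(self, cfg: ModelConfig) -> None:
        if self.local_delta.shape != (cfg.local_len,):
            raise ShapeError(
                f"local_delta length {self.local_delta.shape} != ({cfg.local_len},)"
            )
        if self.global_vec.shape != (cfg.global_len,):
            raise ShapeError(
                f"global length {self.global_vec.shape} != ({cfg.global_len},)"
            )
        if not (np.all(np.isfinite(self.local_delta)) and np.all(np.isfinite(self.global_vec))):
            raise ShapeError("non-finite celltype features")


@dataclass
class PredictionGrid:
    """(window_len/bin × n_marks) prediction matrix with a scale tag."""

    values: np.ndarray
    scale: str  # "arcsinh" or "neglog10p"

    def __post_init__(self) -> None:
        if self.scale == "neglog10p" and np.any(self.values < 0):
            raise ShapeError("neglog10p predictions must be non-negative")


# ---------------------------------------------------------------------------
# model


def _positive(x: Tensor, link: str) -> Tensor:
    return ag.softplus(x) if link == "softplus" else ag.exp(x)


class EpitypeModel(Module):
    """Backbone + DNA heads + celltyping branch + combined head."""

    def __init__(self, cfg: ModelConfig, backbone: ConvBackbone | None = None):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed + 1)
        self.backbone = backbone if backbone is not None else make_toy_backbone(cfg, cfg.seed)
        c, m, k = cfg.trunk_channels, cfg.n_marks, cfg.data.n_dist_bins
        # DNA branch: trainable trunk conv over the frozen latent, then heads
        self.dna_trunk = Conv1d(self.backbone.channels, c, 5, rng)
        self.avg_head = Dense(c, m, rng)
        self.dist_head = Dense(c, m * k, rng)
        # celltyping branch
        self.local_conv = Conv1d(1, cfg.local_embed_dim, 5, rng)
        self.global_conv = Conv1d(1, cfg.global_embed_dim, 5, rng)
        self.global_dense = Dense(
            cfg.global_embed_dim * cfg.global_len // cfg.global_pool, cfg.hidden_dim, rng
        )
        if cfg.position_dependent_celltyping:
            flat = cfg.local_embed_dim * cfg.local_len + cfg.hidden_dim
            self.ct_dense1 = Dense(flat, cfg.hidden_dim, rng)
            self.ct_dense2 = Dense(cfg.hidden_dim, cfg.hidden_dim, rng)
            self.delta_heads = [
                Dense(cfg.hidden_dim, cfg.latent_positions, rng) for _ in range(m)
            ]
        else:
            # fully convolutional variant: per-bin heads, translation-equivariant
            self.ct_conv = Conv1d(
                cfg.local_embed_dim + cfg.hidden_dim, cfg.hidden_dim, 3, rng
            )
            self.ct_out = Conv1d(cfg.hidden_dim, m, 1, rng)
        # combined head
        self.comb_conv = Conv1d(m * (k + 2), cfg.combined_channels, 3, rng)
        self.comb_out = Conv1d(cfg.combined_channels, m, 1, rng)

    # -- branches ----------------------------------------------------------

    def dna_branch(self, latent: Tensor) -> tuple[Tensor, Tensor]:
        """(avg, dist) over the full latent grid.

        avg: (N, T_in, M) strictly positive; dist: (N, T_in, M, K) simplex.
        """
        cfg = self.cfg
        if latent.shape[-2:] != (self.backbone.channels, cfg.latent_positions):
            raise ShapeError(f"latent shape {latent.shape} mismatches config")
        h = ag.tanh(self.dna_trunk(latent))               # (N, c, T_in)
        hp = h.transpose(0, 2, 1)                          # (N, T_in, c)
        avg = _positive(self.avg_head(hp), cfg.positive_link)
        logits = self.dist_head(hp).reshape(
            -1, cfg.latent_positions, cfg.n_marks, cfg.data.n_dist_bins
        )
        dist = ag.softmax(logits, axis=-1)
        return avg, dist

    def celltyping_branch(self, local_delta: Tensor, global_vec: Tensor) -> Tensor:
        """Signed delta prediction over the full latent grid: (N, T_in, M)."""
        cfg = self.cfg
        if local_delta.shape[-1] != cfg.local_len:
            raise ShapeError("local feature length mismatches config")
        if global_vec.shape[-1] != cfg.global_len:
            raise ShapeError("global feature length mismatches config")
        n = local_delta.shape[0]
        loc = ag.tanh(self.local_conv(local_delta.reshape(n, 1, cfg.local_len)))
        glo = ag.tanh(self.global_conv(global_vec.reshape(n, 1, cfg.global_len)))
        glo = ag.avg_pool1d(glo, cfg.global_pool)
        g = ag.tanh(self.global_dense(glo.reshape(n, -1)))  # (N, hidden)
        if cfg.position_dependent_celltyping:
            flat = ag.concat([loc.reshape(n, -1), g], axis=-1)
            h = ag.tanh(self.ct_dense2(ag.tanh(self.ct_dense1(flat))))
            per_mark = [head(h) for head in self.delta_heads]  # each (N, T_in)
            stacked = ag.concat(
                [p.reshape(n, cfg.latent_positions, 1) for p in per_mark], axis=-1
            )
            return stacked                                    # (N, T_in, M)
        # convolutional variant: crop the local grid to the input grid and
        # broadcast the global embedding as constant channels
        off = (cfg.local_len - cfg.latent_positions) // 2
        loc_in = loc[:, :, off : off + cfg.latent_positions]
        g_map = (g.reshape(n, cfg.hidden_dim, 1)
                 * Tensor(np.ones((1, 1, cfg.latent_positions))))
        h = ag.tanh(self.ct_conv(ag.concat([loc_in, g_map], axis=1)))
        return self.ct_out(h).transpose(0, 2, 1)

    def combined_head(self, avg: Tensor, dist: Tensor, delta: Tensor) -> Tensor:
        """Fuse the three outputs; (N, T, M) on the arcsinh scale."""
        cfg = self.cfg
        n, t_in = avg.shape[0], cfg.latent_positions
        feats = ag.concat(
            [
                avg.transpose(0, 2, 1),                             # (N, M, T_in)
                dist.reshape(n, t_in, -1).transpose(0, 2, 1),       # (N, M*K, T_in)
                delta.transpose(0, 2, 1),                           # (N, M, T_in)
            ],
            axis=1,
        )
        h = ag.tanh(self.comb_conv(feats))
        out = _positive(self.comb_out(h).transpose(0, 2, 1), cfg.positive_link)
        crop = (t_in - cfg.n_bins) // 2
        return out[:, crop : crop + cfg.n_bins, :]

    # -- full forward ------------------------------------------------------

    def forward(
        self,
        onehot: Tensor,
        local_delta: Tensor,
        global_vec: Tensor,
        latent: Tensor | None = None,
    ) -> dict[str, Tensor]:
        """All four outputs with the autodiff graph attached.

        ``latent`` short-circuits the frozen backbone (latent caching).
        """
        if latent is None:
            latent = self.backbone.forward_full(onehot)
        avg, dist = self.dna_branch(latent)
        delta = self.celltyping_branch(local_delta, global_vec)
        combined = self.combined_head(avg, dist, delta)
        crop = (self.cfg.latent_positions - self.cfg.n_bins) // 2
        sl = slice(crop, crop + self.cfg.n_bins)
        return {
            "avg": avg[:, sl, :],
            "dist": dist[:, sl, :, :],
            "delta": delta[:, sl, :],
            "combined": combined,
        }

    # -- geometry ----------------------------------------------------------

    @property
    def head_reach_bins(self) -> int:
        """Extra per-side reach, in bins, added by post-backbone convolutions."""
        return (self.dna_trunk.kernel // 2) + (self.comb_conv.kernel // 2)

    @property
    def receptive_field(self) -> int:
        """Total DNA receptive field of one output bin, in bp."""
        return self.backbone.receptive_field + 2 * self.head_reach_bins * self.cfg.data.bin

    def output_bin_input_span(self, bin_lo: int, bin_hi: int) -> tuple[int, int]:
        """Exact input-base interval that can influence output bins
        [bin_lo, bin_hi] (indices within the predictive window)."""
        crop = (self.cfg.latent_positions - self.cfg.n_bins) // 2
        reach = self.head_reach_bins
        lo = max(bin_lo + crop - reach, 0)
        hi = min(bin_hi + crop + reach, self.cfg.latent_positions - 1)
        return self.backbone.latent_span(lo, hi)


def save_model(model: EpitypeModel, directory) -> None:
    """Persist config and all parameters (backbone included) to a directory."""
    import dataclasses
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(model.cfg)
    (d / "config.json").write_text(json.dumps(cfg, indent=1))
    params = model.parameters()
    np.savez(d / "params.npz", **{f"p{i}": p.data for i, p in enumerate(params)})


def load_model(directory) -> EpitypeModel:
    """Rebuild a model saved by :func:`save_model`."""
    import json
    from pathlib import Path

    d = Path(directory)
    cfg = json.loads((d / "config.json").read_text())
    data = cfg.pop("data")
    data["dist_edges"] = tuple(data["dist_edges"])
    data["val_chroms"] = tuple(data["val_chroms"])
    mcfg = ModelConfig(data=DataConfig(**data), **cfg)
    model = EpitypeModel(mcfg)
    with np.load(d / "params.npz") as npz:
        params = model.parameters()
        if len(npz.files) != len(params):
            raise ConfigError("checkpoint parameter count mismatches model")
        for i, p in enumerate(params):
            p.data[...] = npz[f"p{i}"]
    return model


def combined_forward(
    model: EpitypeModel,
    onehot: np.ndarray,
    features: CelltypeFeatures,
    output_scale: str = "neglog10p",
) -> PredictionGrid:
    """Inference convenience: numpy in, :class:`PredictionGrid` out."""
    features.validate(model.cfg)
    if onehot.shape != (model.cfg.data.input_len, 4):
        raise ShapeError(
            f"expected one-hot ({model.cfg.data.input_len}, 4), got {onehot.shape}"
        )
    out = model.forward(
        Tensor(onehot.T[None]),
        Tensor(features.local_delta[None]),
        Tensor(features.global_vec[None]),
    )
    values = out["combined"].data[0]
    if output_scale == "neglog10p":
        return PredictionGrid(np.sinh(values), "neglog10p")
    if output_scale == "arcsinh":
        return PredictionGrid(values, "arcsinh")
    raise ConfigError(f"unknown output scale {output_scale!r}")


def dna_branch(latent: np.ndarray, model: EpitypeModel) -> tuple[np.ndarray, np.ndarray]:
    """Module-level wrapper: (T, C) latent -> (avg, dist) over the window."""
    cfg = model.cfg
    crop = (cfg.latent_positions - cfg.n_bins) // 2
    if latent.shape == (cfg.n_bins, model.backbone.channels):
        # contract-shaped latent: embed into the full grid at the centre
        full = np.zeros((cfg.latent_positions, model.backbone.channels))
        full[crop : crop + cfg.n_bins] = latent
        latent = full
    avg, dist = model.dna_branch(Tensor(latent.T[None]))
    sl = slice(crop, crop + cfg.n_bins)
    return avg.data[0, sl], dist.data[0, sl]


def celltyping_branch(features: CelltypeFeatures, model: EpitypeModel) -> np.ndarray:
    """Module-level wrapper: features -> (n_bins, n_marks) delta."""
    features.validate(model.cfg)
    delta = model.celltyping_branch(
        Tensor(features.local_delta[None]), Tensor(features.global_vec[None])
    )
    crop = (model.cfg.latent_positions - model.cfg.n_bins) // 2
    return delta.data[0, crop : crop + model.cfg.n_bins]
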