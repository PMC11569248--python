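"""Receptive-field probing, off-centre consistency and attribution.

The empirical receptive field is measured by perturbing the input —
random single-base variants for DNA, replacing a block of the cell's
local accessibility with the training average (i.e. zeroing the delta)
for ATAC — at increasing distances from the window centre, and
recording the mean absolute change of the prediction over the centre
span (default 512 bp, four output bins), averaged over all mark
channels on the arcsinh scale.

Off-centre consistency checks that predictions for the same genomic
bins agree when the input window is slid, and gradient attribution
ranks predicted peaks by how strongly they depend on the global
accessibility input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, GeometryError
from .model import CelltypeFeatures, EpitypeModel, combined_forward
from .nn import Tensor
from .regions import RegionSpec
from .seq import BASES, one_hot
from .variants import Variant


@dataclass
class ProbeResult:
    distances: np.ndarray   # bp offsets from the window centre, sorted
    effect: np.ndarray      # mean |Δ prediction| per distance
    replicates: int
    centre_span: int = 512

    def __post_init__(self) -> None:
        if np.any(self.effect < 0):
            raise ConfigError("effects must be non-negative")
        if np.any(np.diff(self.distances) <= 0):
            raise ConfigError("distance grid must be sorted")


@dataclass
class AttributionReport:
    peaks: list[dict] = field(default_factory=list)     # interval, signal, attribution
    selected: list[dict] = field(default_factory=list)  # top fraction by |attribution|
    top_fraction: float = 0.1


def _zero_features(model: EpitypeModel) -> CelltypeFeatures:
    cfg = model.cfg
    return CelltypeFeatures(np.zeros(cfg.local_len), np.zeros(cfg.global_len))


def _centre_slice(model: EpitypeModel, centre_span: int) -> slice:
    span_bins = max(centre_span // model.cfg.data.bin, 1)
    mid = model.cfg.n_bins // 2
    return slice(mid - span_bins // 2, mid - span_bins // 2 + span_bins)


def dna_permutation_scan(
    model: EpitypeModel,
    n_positions: int = 32,
    reps: int = 3,
    seed: int = 0,
    centre_span: int = 512,
    features: CelltypeFeatures | None = None,
) -> ProbeResult:
    """Effect of random single-base variants at evenly spaced positions.

    For each replicate a fresh random sequence is drawn; a single random
    variant is inserted at each grid position and the mean absolute
    change over the centre span of the prediction, averaged over marks
    and replicates, is recorded per distance.
    """
    cfg = model.cfg.data
    if n_positions > cfg.input_len:
        raise ConfigError("more probe positions than input bases")
    rng = np.random.default_rng(seed)
    feats = features if features is not None else _zero_features(model)
    positions = np.linspace(0, cfg.input_len - 1, n_positions).astype(int)
    sl = _centre_slice(model, centre_span)
    effects = np.zeros(n_positions)
    for _ in range(reps):
        seq = "".join(rng.choice(list(BASES), size=cfg.input_len))
        ref = combined_forward(model, one_hot(seq), feats, "arcsinh").values
        for i, pos in enumerate(positions):
            alt_base = rng.choice([b for b in BASES if b != seq[pos]])
            alt = seq[:pos] + alt_base + seq[pos + 1 :]
            pred = combined_forward(model, one_hot(alt), feats, "arcsinh").values
            effects[i] += np.abs(pred[sl] - ref[sl]).mean()
    effects /= reps
    distances = positions - cfg.input_len // 2
    order = np.argsort(distances)
    return ProbeResult(distances[order].astype(float), effects[order], reps,
                       centre_span)


def atac_permutation_scan(
    model: EpitypeModel,
    distances: Sequence[int],
    block: int = 640,
    reps: int = 3,
    seed: int = 0,
    centre_span: int = 512,
    features: CelltypeFeatures | None = None,
) -> ProbeResult:
    """Effect of replacing a block of the cell's local accessibility
    with the training average (delta -> 0) at increasing distances."""
    cfg = model.cfg.data
    if block % cfg.bin:
        raise ConfigError("block must be a multiple of the bin size")
    block_bins = block // cfg.bin
    rng = np.random.default_rng(seed)
    sl = _centre_slice(model, centre_span)
    distances = np.asarray(sorted(distances), dtype=float)
    effects = np.zeros(len(distances))
    centre_bin = model.cfg.local_len // 2
    for _ in range(reps):
        seq = "".join(rng.choice(list(BASES), size=cfg.input_len))
        oh = one_hot(seq)
        if features is None:
            local = rng.normal(0.0, 1.0, size=model.cfg.local_len)
            feats = CelltypeFeatures(local, np.zeros(model.cfg.global_len))
        else:
            feats = features
        ref = combined_forward(model, oh, feats, "arcsinh").values
        for i, d in enumerate(distances):
            b0 = centre_bin + int(d) // cfg.bin - block_bins // 2
            if b0 < 0 or b0 + block_bins > model.cfg.local_len:
                raise ConfigError(f"block at distance {d:+.0f} falls off the local window")
            local_mod = feats.local_delta.copy()
            local_mod[b0 : b0 + block_bins] = 0.0
            pred = combined_forward(
                model, oh, CelltypeFeatures(local_mod, feats.global_vec), "arcsinh"
            ).values
            effects[i] += np.abs(pred[sl] - ref[sl]).mean()
    effects /= reps
    return ProbeResult(distances, effects, reps, centre_span)


# ---------------------------------------------------------------------------
# off-centre consistency


def offcentre_consistency(
    model: EpitypeModel,
    sequences: Mapping[str, str],
    regions: Sequence[RegionSpec],
    feature_provider: Callable[[str, int], CelltypeFeatures],
    variants: Sequence[Variant | None] | None = None,
) -> list[float]:
    """Pearson correlation between centred and off-centre predictions at
    matching genomic bins, one value per (region, direction).

    ``variants`` optionally inserts one SNP per region into both the
    centred and shifted inputs.  Constant predictions have undefined
    correlation and are reported as NaN.
    """
    cfg = model.cfg.data
    shift_bins = cfg.margin // cfg.bin
    out: list[float] = []
    variants = variants if variants is not None else [None] * len(regions)
    for region, var in zip(regions, variants):
        chrom_seq = sequences[region.chrom]
        if var is not None:
            chrom_seq = (
                chrom_seq[: var.pos] + var.alt + chrom_seq[var.pos + 1 :]
            )

        def predict(window_start: int) -> np.ndarray:
            input_start = window_start - cfg.margin
            if input_start < 0 or input_start + cfg.input_len > len(chrom_seq):
                raise GeometryError("shifted window off chromosome")
            seq = chrom_seq[input_start : input_start + cfg.input_len]
            feats = feature_provider(region.chrom, window_start)
            return combined_forward(model, one_hot(seq), feats, "arcsinh").values

        centre = predict(region.window_start)
        for direction in (+1, -1):
            shifted = predict(region.window_start + direction * cfg.margin)
            if direction > 0:
                a, b = centre[shift_bins:], shifted[: cfg.n_bins - shift_bins]
            else:
                a, b = centre[: cfg.n_bins - shift_bins], shifted[shift_bins:]
            if a.size == 0:
                raise GeometryError("no overlapping bins between placements")
            af, bf = a.ravel(), b.ravel()
            if af.std() == 0 or bf.std() == 0:
                out.append(float("nan"))
            else:
                out.append(float(np.corrcoef(af, bf)[0, 1]))
    return out


# ---------------------------------------------------------------------------
# global-input attribution


def global_attribution(
    model: EpitypeModel,
    region: RegionSpec,
    sequences: Mapping[str, str],
    features: CelltypeFeatures,
    peak_window: int = 1024,
    peak_cutoff: float = 2.0,
    top_fraction: float = 0.1,
    marks_idx: Sequence[int] | None = None,
    fasta_path: str | Path | None = None,
) -> AttributionReport:
    """Rank predicted peaks by their dependence on the global input.

    Peaks are non-overlapping ``peak_window``-bp windows whose mean
    predicted -log10 p exceeds ``peak_cutoff``.  Per peak, attribution
    is the summed absolute gradient of the mean peak output with
    respect to the global accessibility vector; the top fraction by
    absolute attribution is selected and its DNA written to FASTA."""
    cfg = model.cfg.data
    if peak_window % cfg.bin:
        raise ConfigError("peak window must be a multiple of the bin size")
    w_bins = peak_window // cfg.bin
    marks_idx = list(marks_idx) if marks_idx is not None else list(range(model.cfg.n_marks))
    seq = sequences[region.chrom][region.input_start : region.input_end]
    oh = Tensor(one_hot(seq).T[None])
    local = Tensor(features.local_delta[None])
    glob = Tensor(features.global_vec[None], requires_grad=True)
    out = model.forward(oh, local, glob)["combined"]  # (1, T, M) arcsinh
    pred_raw = np.sinh(out.data[0])
    report = AttributionReport(top_fraction=top_fraction)
    for b0 in range(0, cfg.n_bins - w_bins + 1, w_bins):
        mean_sig = pred_raw[b0 : b0 + w_bins, marks_idx].mean()
        if mean_sig <= peak_cutoff:
            continue
        scalar = out[0, b0 : b0 + w_bins, marks_idx].mean()
        scalar.backward()
        grad = glob.grad[0].copy()
        start = region.window_start + b0 * cfg.bin
        report.peaks.append(
            {
                "chrom": region.chrom,
                "start": start,
                "end": start + peak_window,
                "mean_signal": float(mean_sig),
                "attribution": float(np.abs(grad).sum()),
            }
        )
    if report.peaks:
        ranked = sorted(report.peaks, key=lambda p: -abs(p["attribution"]))
        k = math.ceil(top_fraction * len(ranked))
        report.selected = ranked[:k]
        if fasta_path is not None:
            with open(fasta_path, "w") as fh:
                for p in report.selected:
                    fh.write(f">{p['chrom']}:{p['start']}-{p['end']}\n")
                    fh.write(sequences[p["chrom"]][p["start"] : p["end"]] + "\n")
    return report
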