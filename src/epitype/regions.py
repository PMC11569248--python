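"""Training-window selection, per-window targets and train/val splits.

The genome is tiled by the model's predictive window; windows are kept
when the full input window (plus the shift-augmentation margin) fits on
the chromosome and no blacklist interval overlaps the predictive
window.  Each histone mark then admits the windows where it has peak
coverage above a threshold, marks are balanced by downsampling to the
least-represented mark, and per-window targets are built: the cross-cell
average signal, the per-bin distribution of signal across cells, and the
cell-minus-average delta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, GeometryError, ScaleError
from .tracks import BinnedTrack, GenomeIndex, IntervalSet

FULL_SCALE = dict(
    window_len=114_688,
    input_len=196_608,
    local_atac_len=199_936,
    bin=128,
    global_bin=250,
    tss_window=3000,
    n_marks=6,
)


@dataclass(frozen=True)
class DataConfig:
    """Window geometry and filter thresholds.

    Defaults are a desk-scale profile; :func:`DataConfig.paper_profile`
    returns the full-scale geometry (196,608 bp input, 114,688 bp
    predictive window, 128 bp bins).
    """

    window_len: int = 2048
    input_len: int = 4096
    local_atac_len: int = 4352
    bin: int = 128
    global_bin: int = 250
    tss_window: int = 3000
    n_dist_bins: int = 10
    dist_edges: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5)
    dist_on_raw: bool = True
    peak_cutoff: float = 2.0
    coverage_frac: float = 0.125
    val_cell_frac: float = 0.2
    val_chroms: tuple[str, ...] = ()
    shift_max: int = 384
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("window_len", "input_len", "local_atac_len"):
            if getattr(self, name) % self.bin:
                raise ConfigError(f"{name} must be a multiple of bin")
        if not self.window_len < self.input_len:
            raise ConfigError("window_len must be smaller than input_len")
        if not 0 < self.coverage_frac < 1:
            raise ConfigError("coverage_frac must lie in (0, 1)")
        edges = self.dist_edges
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigError("dist_edges must be strictly increasing")
        if len(edges) != self.n_dist_bins - 1:
            raise ConfigError("need n_dist_bins - 1 edges (open top bin)")
        if self.shift_max > (self.input_len - self.window_len) // 2:
            raise ConfigError("shift_max exceeds the cropping margin")

    @property
    def n_bins(self) -> int:
        return self.window_len // self.bin

    @property
    def margin(self) -> int:
        """Crop margin between input and predictive window, per side."""
        return (self.input_len - self.window_len) // 2

    @property
    def local_overhang(self) -> int:
        """Extra local-accessibility span beyond the input window, per side."""
        return (self.local_atac_len - self.input_len) // 2

    @classmethod
    def paper_profile(cls, **overrides) -> "DataConfig":
        kw = dict(
            window_len=114_688,
            input_len=196_608,
            local_atac_len=199_936,
            bin=128,
            global_bin=250,
            tss_window=3000,
        )
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class RegionSpec:
    """One training window: the predictive window plus derived geometry."""

    chrom: str
    window_start: int
    cfg: DataConfig
    admitting_mark: str = "dna-only"

    @property
    def window_end(self) -> int:
        return self.window_start + self.cfg.window_len

    @property
    def input_start(self) -> int:
        return self.window_start - self.cfg.margin

    @property
    def input_end(self) -> int:
        return self.input_start + self.cfg.input_len

    @property
    def local_start(self) -> int:
        return self.input_start - self.cfg.local_overhang

    @property
    def local_end(self) -> int:
        return self.local_start + self.cfg.local_atac_len

    def shifted(self, shift_bp: int) -> "RegionSpec":
        return RegionSpec(self.chrom, self.window_start + shift_bp, self.cfg,
                          self.admitting_mark)


@dataclass
class TargetBundle:
    """Per-window targets: average, cross-cell distribution and delta.

    ``avg`` and ``cell_signal`` are on the arcsinh scale; ``dist`` rows
    are simplex vectors; ``delta = cell_signal - avg``.
    """

    avg: np.ndarray          # (n_bins, n_marks)
    dist: np.ndarray         # (n_bins, n_marks, K)
    delta: np.ndarray        # (n_bins, n_marks)
    cell_signal: np.ndarray  # (n_bins, n_marks)

    def __post_init__(self) -> None:
        sums = self.dist.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise GeometryError("distribution targets do not sum to 1")
        if not np.allclose(self.cell_signal, self.avg + self.delta, atol=1e-6):
            raise GeometryError("cell_signal != avg + delta")


@dataclass(frozen=True)
class TrainItem:
    """One training example: a window, a cell, and its augmentation."""

    region: RegionSpec
    cell: str
    strand: str = "+"   # "+" or "-"
    shift: int = 0      # bp, applied to the window start


# ---------------------------------------------------------------------------
# window selection


def enumerate_candidates(
    genome: GenomeIndex, blacklist: IntervalSet, cfg: DataConfig
) -> list[RegionSpec]:
    """Tile each chromosome by ``window_len`` and keep feasible windows.

    A window survives when the whole input window (and the wider local
    accessibility window) plus ``shift_max`` fits on the chromosome and
    the predictive window does not overlap the blacklist.
    """
    out: list[RegionSpec] = []
    reach = max(cfg.margin, cfg.margin + cfg.local_overhang) + cfg.shift_max
    for chrom, length in genome.items():
        for k in range(length // cfg.window_len):
            ws = k * cfg.window_len
            if ws - reach < 0 or ws + cfg.window_len + reach > length:
                continue
            if blacklist.overlaps(chrom, ws, ws + cfg.window_len):
                continue
            out.append(RegionSpec(chrom, ws, cfg))
    return out


def coverage_filter(
    regions: Sequence[RegionSpec],
    mark_tracks: Mapping[str, Mapping[str, BinnedTrack]],
    cfg: DataConfig,
) -> dict[str, list[RegionSpec]]:
    """Admit a region for a mark when, in at least one cell's track, the
    fraction of window bins at or above ``peak_cutoff`` strictly exceeds
    ``coverage_frac``.

    ``mark_tracks`` maps mark -> cell -> neglog10p-scale track at
    ``cfg.bin`` resolution.
    """
    out: dict[str, list[RegionSpec]] = {}
    for mark, by_cell in mark_tracks.items():
        keep: list[RegionSpec] = []
        for region in regions:
            passed = False
            for track in by_cell.values():
                if track.scale != "neglog10p":
                    raise ScaleError("coverage filter needs neglog10p tracks")
                if track.bin_size != cfg.bin:
                    raise GeometryError("track bin size != cfg.bin")
                win = track.window(region.chrom, region.window_start, cfg.n_bins)
                frac = np.count_nonzero(win >= cfg.peak_cutoff) / cfg.n_bins
                if frac > cfg.coverage_frac:
                    passed = True
                    break
            if passed:
                keep.append(RegionSpec(region.chrom, region.window_start, cfg, mark))
        out[mark] = keep
    return out


def balance_marks(
    per_mark_regions: Mapping[str, Sequence[RegionSpec]], seed: int
) -> list[RegionSpec]:
    """Downsample every mark's admitted regions to the smallest mark count."""
    counts = {m: len(r) for m, r in per_mark_regions.items()}
    if not counts or min(counts.values()) == 0:
        raise ConfigError("every mark needs at least one admitted region")
    n = min(counts.values())
    rng = np.random.default_rng(seed)
    out: list[RegionSpec] = []
    for mark in sorted(per_mark_regions):
        regions = list(per_mark_regions[mark])
        idx = rng.choice(len(regions), size=n, replace=False)
        out.extend(regions[i] for i in sorted(idx))
    return out


# ---------------------------------------------------------------------------
# targets


def build_distribution(values: np.ndarray, edges: Sequence[float]) -> np.ndarray:
    """Fraction of cell types falling in each signal bin.

    Bins are [0, e₁), [e₁, e₂), …, [e_{K−1}, ∞); K = len(edges) + 1.
    ``values`` may be a vector (cells,) or an array (..., cells); the
    histogram runs over the last axis and the K components sum to 1.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ScaleError("distribution input must be non-negative (-log10 p scale)")
    edges = np.asarray(edges, dtype=float)
    k = np.searchsorted(edges, values, side="right")  # bin index per value
    n_cells = values.shape[-1]
    counts = np.stack(
        [(k == i).sum(axis=-1) for i in range(len(edges) + 1)], axis=-1
    )
    return counts / n_cells


def build_targets(
    region: RegionSpec,
    mark_tracks_by_cell: Mapping[str, Mapping[str, BinnedTrack]],
    cell: str,
    cfg: DataConfig,
    exclude_cell_from_avg: bool = False,
    window_start: int | None = None,
    cell_pool: Sequence[str] | None = None,
) -> TargetBundle:
    """Targets for one (window, cell) pair.

    ``mark_tracks_by_cell`` maps mark -> cell -> arcsinh-scale track.
    The distribution is built on raw -log10 p values (recovered exactly
    through sinh) unless ``cfg.dist_on_raw`` is False.  ``cell_pool``
    restricts the cells entering avg and dist (normally the training
    cells); when the target cell is flagged held out it is excluded too.
    """
    marks = sorted(mark_tracks_by_cell)
    ws = region.window_start if window_start is None else window_start
    n_bins = cfg.n_bins
    avg = np.zeros((n_bins, len(marks)))
    dist = np.zeros((n_bins, len(marks), cfg.n_dist_bins))
    cell_signal = np.zeros((n_bins, len(marks)))
    for j, mark in enumerate(marks):
        by_cell = mark_tracks_by_cell[mark]
        if cell not in by_cell:
            raise ConfigError(f"cell {cell!r} absent from {mark} tracks")
        base = sorted(by_cell) if cell_pool is None else list(cell_pool)
        pool = [c for c in base if not (exclude_cell_from_avg and c == cell)]
        mat = np.stack(
            [by_cell[c].window(region.chrom, ws, n_bins) for c in pool], axis=-1
        )  # (n_bins, cells), arcsinh scale
        for c in pool:
            if by_cell[c].scale != "arcsinh":
                raise ScaleError("build_targets expects arcsinh tracks")
        avg[:, j] = mat.mean(axis=-1)
        hist_input = np.sinh(mat) if cfg.dist_on_raw else mat
        dist[:, j, :] = build_distribution(hist_input, cfg.dist_edges)
        cell_signal[:, j] = by_cell[cell].window(region.chrom, ws, n_bins)
    return TargetBundle(avg, dist, cell_signal - avg, cell_signal)


# ---------------------------------------------------------------------------
# splits + augmentation


def make_splits_and_augment(
    regions: Sequence[RegionSpec],
    cells: Sequence[str],
    cfg: DataConfig,
) -> tuple[list[TrainItem], list[TrainItem]]:
    """Train/validation items.

    Validation holds out both ``cfg.val_chroms`` and a seeded
    ``val_cell_frac`` fraction of cells; validation window starts are
    jittered uniformly within ±shift_max.  Training items enumerate both
    strands with one seeded random shift per (region, strand), so frozen
    backbone latents can be cached per unique input.
    """
    rng = np.random.default_rng(cfg.seed)
    max_shift_bins = cfg.shift_max // cfg.bin

    def draw_shift() -> int:
        # shifts are drawn at bin granularity so shifted windows stay
        # bin-aligned with the 128-bp target tracks
        return int(rng.integers(-max_shift_bins, max_shift_bins + 1)) * cfg.bin

    cells = list(cells)
    n_val = round(cfg.val_cell_frac * len(cells))
    if n_val == 0:
        raise ConfigError("val_cell_frac rounds to zero validation cells")
    val_cells = set(np.array(cells)[rng.choice(len(cells), n_val, replace=False)])
    train_cells = [c for c in cells if c not in val_cells]

    train: list[TrainItem] = []
    val: list[TrainItem] = []
    for region in regions:
        if region.chrom in cfg.val_chroms:
            jitter = draw_shift()
            for cell in sorted(val_cells):
                val.append(TrainItem(region, cell, "+", jitter))
        else:
            for strand in "+-":
                shift = draw_shift()
                for cell in train_cells:
                    train.append(TrainItem(region, cell, strand, shift))
    return train, val
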