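"""Cell-identity feature construction from chromatin accessibility.

Two representations feed the celltyping branch:

* **local**: the cell's accessibility over the local window around a
  region, minus the training-average accessibility (both arcsinh
  scale), at bin resolution;
* **global**: the cell's accessibility in a fixed window around every
  marker-gene TSS, averaged at the coarser global bin resolution and
  concatenated gene by gene.  This vector is the same for a cell
  regardless of the genomic region being predicted, so it acts as a
  cell-identity embedding input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import GeometryError, ScaleError
from .model import CelltypeFeatures, ModelConfig
from .regions import DataConfig, RegionSpec
from .tracks import BinnedTrack


def read_marker_genes(path) -> pd.DataFrame:
    """TSV with columns gene, chrom, tss (0-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"gene", "chrom", "tss"} - set(df.columns)
    if missing:
        raise GeometryError(f"marker gene table missing columns {sorted(missing)}")
    return df


def _window_mean_coarse(
    track: BinnedTrack, chrom: str, start: int, end: int, out_bin: int
) -> np.ndarray:
    """Mean signal of ``out_bin``-bp chunks of [start, end), exact for the
    stepwise per-base signal the binned track represents."""
    v = track.values[chrom]
    b = track.bin_size
    length = track.genome.length_of(chrom)
    edges = np.minimum(np.arange(len(v) + 1) * b, length)
    cum = np.concatenate([[0.0], np.cumsum(v * np.diff(edges))])
    lo = np.arange(start, end, out_bin, dtype=float)
    hi = np.minimum(lo + out_bin, end)
    lo_c, hi_c = np.clip(lo, 0, length), np.clip(hi, 0, length)
    s = np.interp(hi_c, edges, cum) - np.interp(lo_c, edges, cum)
    width = np.maximum(hi_c - lo_c, 1e-12)
    return s / width


def global_accessibility_vector(
    atac: BinnedTrack, markers: pd.DataFrame, cfg: DataConfig, mcfg: ModelConfig
) -> np.ndarray:
    """Concatenated per-marker-gene TSS accessibility at global_bin resolution."""
    if atac.scale != "arcsinh":
        raise ScaleError("global features expect arcsinh accessibility")
    per_gene = cfg.tss_window // cfg.global_bin
    if len(markers) != mcfg.n_marker_genes:
        raise GeometryError(
            f"{len(markers)} marker genes but config expects {mcfg.n_marker_genes}"
        )
    chunks = []
    for row in markers.itertuples():
        start = int(row.tss) - cfg.tss_window // 2
        chunks.append(
            _window_mean_coarse(atac, row.chrom, start, start + cfg.tss_window,
                                cfg.global_bin)[:per_gene]
        )
    return np.concatenate(chunks)


def build_celltype_features(
    region: RegionSpec,
    atac_cell: BinnedTrack,
    atac_avg: BinnedTrack,
    markers: pd.DataFrame,
    mcfg: ModelConfig,
    window_start: int | None = None,
) -> CelltypeFeatures:
    """Features for one (region, cell): local arcsinh delta + global vector."""
    cfg = mcfg.data
    if atac_cell.scale != "arcsinh" or atac_avg.scale != "arcsinh":
        raise ScaleError("local features expect arcsinh accessibility")
    ws = region.window_start if window_start is None else window_start
    local_start = ws - cfg.margin - cfg.local_overhang
    n_local = cfg.local_atac_len // cfg.bin
    local = atac_cell.window(region.chrom, local_start, n_local)
    avg = atac_avg.window(region.chrom, local_start, n_local)
    feats = CelltypeFeatures(
        local_delta=np.asarray(local - avg, dtype=float),
        global_vec=global_accessibility_vector(atac_cell, markers, cfg, mcfg),
    )
    feats.validate(mcfg)
    return feats
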