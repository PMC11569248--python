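"""End-to-end synthetic benchmark: simulate → build data → train → evaluate.

This is the package's desk-scale analogue of the full study: a toy
genome with planted cell-type-specific regulatory grammar, a toy-profile
two-stage training run, and two read-outs:

* **held-out-cell recovery** — Pearson correlation with the true signal
  inside planted cell-specific peak regions of each held-out cell,
  compared per (cell, chromosome) against the training-average
  baseline (the tally of "model beats average" comparisons);
* **hQTL sign concordance** — signed variant-effect scores for
  simulated hQTLs with large planted local effects in a held-out cell,
  compared against the aggregated study marginals.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import build_celltype_features
from .model import CelltypeFeatures, EpitypeModel, ModelConfig, combined_forward, \
    make_matched_backbone
from .regions import (
    DataConfig,
    RegionSpec,
    TrainItem,
    balance_marks,
    coverage_filter,
    enumerate_candidates,
    make_splits_and_augment,
)
from .seq import one_hot
from .simulate import SimConfig, SimGenome, simulate_genome, simulate_hqtl, \
    simulate_marker_genes, simulate_tracks
from .tracks import BinnedTrack, arcsinh_transform, average_tracks
from .trainer import RegionDataset, TrainProfile, TrainState, cache_latents, \
    pretrain, train_full
from .variants import ConcordanceReport, aggregate_all, export_and_concord, \
    munge_hqtl, score_variant


def toy_data_config(seed: int, val_chroms: tuple[str, ...] = ("chr3",)) -> DataConfig:
    return DataConfig(val_chroms=val_chroms, seed=seed)


@dataclass
class BenchSetup:
    """Everything the benchmark trains on, bundled for reuse."""

    sim: SimGenome
    histone_raw: dict
    atac_raw: dict
    markers: pd.DataFrame
    dataset: RegionDataset
    train_items: list[TrainItem]
    val_items: list[TrainItem]
    model: EpitypeModel
    dcfg: DataConfig
    mcfg: ModelConfig
    scfg: SimConfig
    val_cells: list[str]
    train_cells: list[str]
    grammar: object
    atac_avg_arc: BinnedTrack


def build_setup(seed: int, scfg: SimConfig | None = None,
                position_dependent: bool = True) -> BenchSetup:
    scfg = scfg or SimConfig(seed=seed)
    grammar = scfg.resolved_grammar()
    sim = simulate_genome(scfg)
    histone_raw, atac_raw = simulate_tracks(sim, grammar, scfg)
    markers = simulate_marker_genes(sim, grammar, scfg, atac=atac_raw)

    dcfg = toy_data_config(seed, val_chroms=(sim.genome.names[-1],))
    mcfg = ModelConfig(
        data=dcfg,
        n_marks=scfg.n_marks,
        n_marker_genes=scfg.n_marker_genes,
        position_dependent_celltyping=position_dependent,
        seed=seed,
    )

    candidates = enumerate_candidates(sim.genome, sim.blacklist, dcfg)
    # determine held-out cells first (same seeded draw the splitter makes)
    # so the coverage filter and averages see training cells only
    rng = np.random.default_rng(dcfg.seed)
    n_val = round(dcfg.val_cell_frac * scfg.n_cells)
    val_cells = sorted(
        np.array(scfg.cells)[rng.choice(scfg.n_cells, n_val, replace=False)]
    )
    train_cells = [c for c in scfg.cells if c not in val_cells]

    train_histone = {
        m: {c: t for c, t in by_cell.items() if c in train_cells}
        for m, by_cell in histone_raw.items()
    }
    per_mark = coverage_filter(candidates, train_histone, dcfg)
    balanced = balance_marks(per_mark, dcfg.seed)
    train_items, val_items = make_splits_and_augment(balanced, scfg.cells, dcfg)

    histone_arc = {
        m: {c: arcsinh_transform(t) for c, t in by_cell.items()}
        for m, by_cell in histone_raw.items()
    }
    atac_arc = {c: arcsinh_transform(t) for c, t in atac_raw.items()}
    atac_avg = average_tracks([atac_arc[c] for c in train_cells])
    dataset = RegionDataset(
        sim.sequences, histone_arc, atac_arc, atac_avg, markers, mcfg, train_cells
    )
    # the backbone stands in for a chopped pre-trained sequence model:
    # constructed motif-matched filters over the genome's planted grammar
    backbone = make_matched_backbone(mcfg, grammar.motifs, seed)
    model = EpitypeModel(mcfg, backbone=backbone)
    return BenchSetup(
        sim, histone_raw, atac_raw, markers, dataset, train_items, val_items,
        model, dcfg, mcfg, scfg, val_cells, train_cells, grammar, atac_avg
    )


def train_toy(setup: BenchSetup, profile: TrainProfile | None = None,
              cache_dir: str | None = None) -> dict:
    """Two-stage toy training; returns the loss traces."""
    profile = profile or TrainProfile.toy()
    cache_dir = cache_dir or tempfile.mkdtemp(prefix="epitype-latents-")
    cache = cache_latents(
        setup.model.backbone, setup.dataset, setup.train_items, cache_dir
    )
    state = TrainState(batch_size=profile.batch_size, seed=setup.dcfg.seed,
                       lr_pretrain=2e-3, lr_full=2e-3)
    traces_pre = pretrain(
        setup.model, setup.dataset, setup.train_items, state,
        steps=profile.steps_pretrain, cache=cache,
    )
    traces_full = train_full(
        setup.model, setup.dataset, setup.train_items, setup.val_items, state,
        steps=profile.steps_full, cache=cache,
    )
    return {"pretrain": traces_pre, "full": traces_full}


# ---------------------------------------------------------------------------
# read-out 1: held-out-cell recovery at planted cell-specific peaks


def _private_site_mask(setup: BenchSetup, cell: str, chrom: str) -> np.ndarray:
    """Bin mask of the cell's private-motif peak regions on one chromosome."""
    grammar = setup.grammar
    ci = setup.scfg.cells.index(cell)
    private = [
        m for m in range(grammar.usage.shape[1])
        if np.count_nonzero(grammar.usage[:, m]) == 1 and grammar.usage[ci, m] > 0
    ]
    occ = setup.sim.occurrences.query("chrom == @chrom and motif in @private and not broken")
    n_bins = setup.sim.genome.n_bins(chrom, setup.dcfg.bin)
    mask = np.zeros(n_bins, dtype=bool)
    hw_bins = int(np.ceil(grammar.peak_half_width / setup.dcfg.bin))
    for row in occ.itertuples():
        b = row.pos // setup.dcfg.bin
        mask[max(b - hw_bins, 0) : b + hw_bins + 1] = True
    return mask


def predict_cell_track(
    setup: BenchSetup, cell: str, regions: list[RegionSpec]
) -> dict[str, dict[str, np.ndarray]]:
    """Predicted neglog10p values and coverage masks per chromosome.

    Returns {chrom: {"values": (n_bins, n_marks), "covered": bool mask}}.
    """
    dcfg = setup.dcfg
    out = {
        chrom: {
            "values": np.zeros((setup.sim.genome.n_bins(chrom, dcfg.bin),
                                setup.mcfg.n_marks)),
            "covered": np.zeros(setup.sim.genome.n_bins(chrom, dcfg.bin), dtype=bool),
        }
        for chrom in setup.sim.genome.names
    }
    for region in regions:
        seq = setup.sim.sequences[region.chrom][region.input_start : region.input_end]
        feats = build_celltype_features(
            region, setup.dataset.atac[cell], setup.dataset.atac_avg,
            setup.markers, setup.mcfg,
        )
        pred = combined_forward(setup.model, one_hot(seq), feats, "neglog10p").values
        b0 = region.window_start // dcfg.bin
        out[region.chrom]["values"][b0 : b0 + dcfg.n_bins] = pred
        out[region.chrom]["covered"][b0 : b0 + dcfg.n_bins] = True
    return out


@dataclass
class RecoveryResult:
    wins: int
    comparisons: int
    details: list[dict] = field(default_factory=list)

    @property
    def win_fraction(self) -> float:
        return self.wins / max(self.comparisons, 1)


def heldout_recovery(setup: BenchSetup) -> RecoveryResult:
    """Per (held-out cell, chromosome): does the trained model correlate
    better with truth than the training-average baseline inside the
    cell's planted cell-specific peak regions?"""
    dcfg = setup.dcfg
    candidates = enumerate_candidates(setup.sim.genome, setup.sim.blacklist, dcfg)
    result = RecoveryResult(0, 0)
    marks = setup.dataset.marks
    avg_by_mark = {
        m: average_tracks([setup.histone_raw[m][c] for c in setup.train_cells])
        for m in marks
    }
    for cell in setup.val_cells:
        preds = predict_cell_track(setup, cell, candidates)
        for chrom in setup.sim.genome.names:
            mask = _private_site_mask(setup, cell, chrom) & preds[chrom]["covered"]
            if mask.sum() < 3:
                continue
            truth = np.stack(
                [setup.histone_raw[m][cell].values[chrom][mask] for m in marks],
                axis=-1,
            ).ravel()
            model_pred = preds[chrom]["values"][mask].ravel()
            avg_pred = np.stack(
                [avg_by_mark[m].values[chrom][mask] for m in marks], axis=-1
            ).ravel()
            if truth.std() == 0:
                continue
            r_model = np.corrcoef(model_pred, truth)[0, 1]
            r_avg = np.corrcoef(avg_pred, truth)[0, 1]
            result.comparisons += 1
            result.wins += int(r_model > r_avg)
            result.details.append(
                dict(cell=cell, chrom=chrom, r_model=float(r_model),
                     r_avg=float(r_avg), n_bins=int(mask.sum()))
            )
    return result


# ---------------------------------------------------------------------------
# read-out 2: hQTL sign concordance


def hqtl_concordance(
    setup: BenchSetup, seed: int, study_cell: str | None = None,
    sumstats_path=None,
) -> ConcordanceReport:
    study_cell = study_cell or setup.val_cells[0]
    study_mark = setup.dataset.marks[0]
    variants, records, truth = simulate_hqtl(
        setup.sim, setup.grammar, setup.scfg, seed + 101, study_cell=study_cell,
        study_mark=0,
    )
    kept = munge_hqtl(records, setup.model.receptive_field)
    marginals = aggregate_all(kept)
    cfg = setup.dcfg

    def feature_provider(chrom: str, window_start: int) -> CelltypeFeatures:
        region = RegionSpec(chrom, window_start, cfg)
        return build_celltype_features(
            region, setup.dataset.atac[study_cell], setup.dataset.atac_avg,
            setup.markers, setup.mcfg,
        )

    scores = [
        score_variant(
            setup.model, setup.sim.sequences, feature_provider, v,
            setup.dataset.marks, cell=study_cell, seed=seed,
        )
        for v in variants
    ]
    return export_and_concord(scores, marginals, study_mark, sumstats_path)
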