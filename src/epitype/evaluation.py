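"""Comparison protocols: stratified MSE, per-chromosome Pearson over
region sets, and the binarise-and-coarsen classification comparison.

Peak/no-peak stratification uses a -log10 p cutoff (default 2, the bin
is a peak when the true value is at or above it).  Classification
against a coarser-resolution model averages both tracks to the lowest
common multiple of the two bin sizes, binarises the truth at the
cutoff, and reports AUROC and average precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import GeometryError
from .tracks import BinnedTrack, IntervalSet, rebin

log = logging.getLogger(__name__)


@dataclass
class MseSlice:
    stratum: str
    mse: float
    sd: float          # standard deviation of the squared errors
    n_bins: int


@dataclass
class EvalReport:
    mse: dict[str, MseSlice] = field(default_factory=dict)
    pearson: dict[str, float] = field(default_factory=dict)        # chrom -> r
    model_beats_baseline: tuple[int, int] | None = None            # (wins, total)
    auroc: float | None = None
    average_precision: float | None = None


def _check_geometry(pred: BinnedTrack, truth: BinnedTrack) -> None:
    if pred.genome != truth.genome or pred.bin_size != truth.bin_size:
        raise GeometryError("prediction and truth tracks have mismatched geometry")
    if pred.scale != truth.scale:
        raise GeometryError("prediction and truth tracks are on different scales")


def mse_report(
    pred: BinnedTrack, truth: BinnedTrack, cutoff: float = 2.0
) -> EvalReport:
    """MSE over all bins and over peak (truth >= cutoff) / no-peak strata."""
    _check_geometry(pred, truth)
    p = np.concatenate([pred.values[c] for c in pred.genome.names])
    t = np.concatenate([truth.values[c] for c in truth.genome.names])
    sq = (p - t) ** 2
    peak = t >= cutoff
    report = EvalReport()
    for name, mask in [("all", np.ones_like(peak)), ("peak", peak), ("no-peak", ~peak)]:
        if not mask.any():
            continue  # empty stratum reported as absent
        report.mse[name] = MseSlice(
            name, float(sq[mask].mean()), float(sq[mask].std()), int(mask.sum())
        )
    return report


def pearson_by_region(
    pred: BinnedTrack,
    truth: BinnedTrack,
    regions: IntervalSet,
    baseline: BinnedTrack | None = None,
) -> EvalReport:
    """Pearson r over region bins, grouped per chromosome.

    With a ``baseline`` prediction the report also tallies on how many
    chromosomes the model's r beats the baseline's.
    """
    _check_geometry(pred, truth)
    report = EvalReport()
    wins = total = 0
    for chrom in pred.genome.names:
        mask = np.zeros(len(pred.values[chrom]), dtype=bool)
        for c, s, e, _ in regions:
            if c == chrom:
                mask[s // pred.bin_size : math.ceil(e / pred.bin_size)] = True
        if mask.sum() < 3:
            log.info("pearson_by_region: %s skipped (<3 region bins)", chrom)
            continue
        t = truth.values[chrom][mask]
        if np.std(t) == 0 or np.std(pred.values[chrom][mask]) == 0:
            log.info("pearson_by_region: %s skipped (constant signal)", chrom)
            continue
        r, _ = stats.pearsonr(pred.values[chrom][mask], t)
        report.pearson[chrom] = float(r)
        if baseline is not None and np.std(baseline.values[chrom][mask]) > 0:
            rb, _ = stats.pearsonr(baseline.values[chrom][mask], t)
            total += 1
            wins += int(r > rb)
    if baseline is not None:
        report.model_beats_baseline = (wins, total)
    return report


def classification_compare(
    pred: BinnedTrack, truth: BinnedTrack, cutoff: float = 2.0
) -> EvalReport:
    """AUROC/AP at the lowest common multiple of the two bin sizes.

    Both tracks are averaged to the common resolution; the truth is
    binarised at ``cutoff`` on the coarse bins.
    """
    common = math.lcm(pred.bin_size, truth.bin_size)
    if any(common > l for l in pred.genome.lengths):
        raise GeometryError(
            f"common resolution {common} bp exceeds a chromosome length"
        )
    p = rebin(pred, common)
    t = rebin(truth, common)
    scores = np.concatenate([p.values[c] for c in p.genome.names])
    labels = np.concatenate([t.values[c] for c in t.genome.names]) >= cutoff
    if labels.all() or not labels.any():
        raise GeometryError("truth is single-class after binarisation")
    report = EvalReport()
    report.auroc = float(roc_auc_score(labels, scores))
    report.average_precision = float(average_precision_score(labels, scores))
    return report
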