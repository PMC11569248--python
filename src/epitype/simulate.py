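"""Synthetic epigenome generator with a planted regulatory grammar.

Everything the other modules consume can be generated here: a random
genome with motif instances planted at Poisson-spaced sites, a small
blacklist, per-cell ATAC and per-cell per-mark histone tracks on the
-log10 p scale, a marker-gene TSS table whose accessibility separates
cell types, and hQTL records with known signed effects.

The grammar is deliberately simple: each motif carries a per-mark
affinity and each cell uses each motif with a weight in [0, 1].  A
motif instance contributes, for cell c and mark j, a truncated-Gaussian
bump of height ``max_amplitude · usage[c, motif] · affinity[motif, j]``
centred on the site; ATAC for a cell is the cell's total site activity
(a monotone function of regulatory usage) plus noise.  Every cell owns
at least one *private* motif, giving guaranteed cell-type-specific
peaks.  A configurable fraction of instances are planted *broken* (the
central consensus base is mutated): they contribute no signal and are
the substrate for restoring hQTL variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, GeometryError
from .seq import BASES, reverse_complement
from .tracks import BinnedTrack, GenomeIndex, IntervalSet
from .variants import HqtlRecord, Variant


@dataclass(frozen=True)
class RegulatoryGrammar:
    """Planted motif set, per-mark affinities and cell-usage matrix."""

    motifs: tuple[str, ...]
    affinity: np.ndarray        # (n_motifs, n_marks), >= 0
    usage: np.ndarray           # (n_cells, n_motifs), in [0, 1]
    peak_half_width: int = 256  # bp, half-width at half maximum
    max_amplitude: float = 5.0  # -log10 p at the peak centre for usage*affinity = 1
    noise_scale: float = 0.2    # nonneg background noise scale

    def __post_init__(self) -> None:
        if np.any(self.usage < 0) or np.any(self.usage > 1):
            raise ConfigError("usage entries must lie in [0, 1]")
        if np.any(self.affinity < 0) or self.max_amplitude < 0:
            raise ConfigError("affinities and amplitude must be non-negative")
        if self.affinity.shape[0] != len(self.motifs):
            raise ConfigError("affinity rows must match motif count")
        if self.usage.shape[1] != len(self.motifs):
            raise ConfigError("usage columns must match motif count")


def default_grammar(
    n_cells: int, n_marks: int, seed: int, n_shared: int = 2, motif_len: int = 8
) -> RegulatoryGrammar:
    """One private motif per cell plus ``n_shared`` motifs used by all cells."""
    rng = np.random.default_rng(seed)
    n_motifs = n_cells + n_shared
    motifs = tuple(
        "".join(rng.choice(list(BASES), size=motif_len)) for _ in range(n_motifs)
    )
    usage = np.zeros((n_cells, n_motifs))
    usage[:, :n_cells] = np.eye(n_cells)          # private motifs
    usage[:, n_cells:] = 1.0                      # shared motifs
    affinity = rng.uniform(0.6, 1.0, size=(n_motifs, n_marks))
    return RegulatoryGrammar(motifs, affinity, usage)


@dataclass(frozen=True)
class SimConfig:
    n_chroms: int = 3
    chrom_len: int = 65_536
    n_cells: int = 8
    n_marks: int = 3
    n_marker_genes: int = 8
    motif_spacing: int = 640        # mean bp between planted sites (Poisson)
    frac_broken: float = 0.25       # fraction of instances planted broken
    bin: int = 128
    n_hqtl: int = 40
    n_trans_decoys: int = 3
    n_far_decoys: int = 3
    beta_noise: float = 0.15        # sd of noise on hQTL betas
    atac_noise: float = 0.15
    seed: int = 0
    grammar: RegulatoryGrammar | None = None

    def resolved_grammar(self) -> RegulatoryGrammar:
        if self.grammar is not None:
            return self.grammar
        return default_grammar(self.n_cells, self.n_marks, self.seed + 17)

    @property
    def cells(self) -> list[str]:
        return [f"cell{i}" for i in range(self.n_cells)]

    @property
    def marks(self) -> list[str]:
        return [f"mark{i}" for i in range(self.n_marks)]


@dataclass
class SimGenome:
    genome: GenomeIndex
    sequences: dict[str, str]
    blacklist: IntervalSet
    occurrences: pd.DataFrame  # chrom, pos (motif centre), motif, strand, broken

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.genome.names:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


def _broken_motif(motif: str, rng: np.random.Generator) -> str:
    """Mutate the central base to a different one."""
    mid = len(motif) // 2
    alt = rng.choice([b for b in BASES if b != motif[mid]])
    return motif[:mid] + alt + motif[mid + 1 :]


def simulate_genome(cfg: SimConfig) -> SimGenome:
    """Random genome with Poisson-spaced planted motif instances.

    Site centres snap to bin centres so that a zero-noise peak maximum
    equals the planted amplitude exactly.  A few small blacklist
    intervals are planted per chromosome.
    """
    rng = np.random.default_rng(cfg.seed)
    grammar = cfg.resolved_grammar()
    if max(len(m) for m in grammar.motifs) >= cfg.chrom_len:
        raise GeometryError("motif longer than chromosome")
    names = tuple(f"chr{i + 1}" for i in range(cfg.n_chroms))
    genome = GenomeIndex(names, (cfg.chrom_len,) * cfg.n_chroms)
    sequences: dict[str, str] = {}
    rows = []
    margin = 4 * cfg.bin
    forced = list(range(len(grammar.motifs)))  # every motif gets early sites
    for chrom in names:
        seq = rng.choice(list(BASES), size=cfg.chrom_len)
        pos = margin
        while True:
            pos += int(rng.exponential(cfg.motif_spacing)) + 2 * cfg.bin
            if pos >= cfg.chrom_len - margin:
                break
            centre = (pos // cfg.bin) * cfg.bin + cfg.bin // 2
            if centre >= cfg.chrom_len - margin:
                break
            m = forced.pop(0) if forced else int(rng.integers(len(grammar.motifs)))
            motif = grammar.motifs[m]
            broken = bool(rng.random() < cfg.frac_broken)
            planted = _broken_motif(motif, rng) if broken else motif
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                planted = reverse_complement(planted)
            start = centre - len(motif) // 2
            seq[start : start + len(motif)] = list(planted)
            rows.append((chrom, centre, m, strand, broken))
        sequences[chrom] = "".join(seq)
    occurrences = pd.DataFrame(
        rows, columns=["chrom", "pos", "motif", "strand", "broken"]
    )
    blacklist = IntervalSet()
    for chrom in names:
        s = int(rng.integers(margin, cfg.chrom_len - margin - 512))
        blacklist.add(chrom, s, s + 512, "sim_blacklist")
    return SimGenome(genome, sequences, blacklist, occurrences)


def _bump(n_bins: int, centre_bin: int, half_width_bins: float) -> np.ndarray:
    """Truncated Gaussian with value 1 at the centre bin, 0.5 at the
    half-width, zeroed beyond three sigma."""
    sigma = half_width_bins / math.sqrt(2.0 * math.log(2.0))
    d = np.arange(n_bins) - centre_bin
    out = np.exp(-0.5 * (d / sigma) ** 2)
    out[np.abs(d) > 3 * sigma] = 0.0
    return out


def simulate_tracks(
    sim: SimGenome, grammar: RegulatoryGrammar, cfg: SimConfig
) -> tuple[dict[str, dict[str, BinnedTrack]], dict[str, BinnedTrack]]:
    """Per-cell per-mark histone tracks and per-cell ATAC tracks (neglog10p).

    Returns (histone, atac) where histone[mark][cell] and atac[cell] are
    :class:`BinnedTrack` at ``cfg.bin`` resolution.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    hw_bins = grammar.peak_half_width / cfg.bin
    n_bins = math.ceil(cfg.chrom_len / cfg.bin)
    # per-chromosome site activity profiles per motif
    site_profiles: dict[str, np.ndarray] = {}
    for chrom in sim.genome.names:
        occ = sim.occurrences.query("chrom == @chrom and not broken")
        profile = np.zeros((len(grammar.motifs), n_bins))
        for row in occ.itertuples():
            profile[row.motif] += _bump(n_bins, row.pos // cfg.bin, hw_bins)
        site_profiles[chrom] = profile
    histone: dict[str, dict[str, BinnedTrack]] = {m: {} for m in cfg.marks}
    atac: dict[str, BinnedTrack] = {}
    for ci, cell in enumerate(cfg.cells):
        activity = {
            chrom: grammar.usage[ci] @ site_profiles[chrom]
            for chrom in sim.genome.names
        }  # (n_bins,) total motif activity for this cell
        for mi, mark in enumerate(cfg.marks):
            values = {}
            for chrom in sim.genome.names:
                sig = grammar.max_amplitude * (
                    (grammar.usage[ci] * grammar.affinity[:, mi])
                    @ site_profiles[chrom]
                )
                noise = np.abs(rng.normal(0.0, grammar.noise_scale, size=n_bins))
                values[chrom] = sig + noise
            histone[mark][cell] = BinnedTrack(
                sim.genome, cfg.bin, values, assay=mark, cell=cell
            )
        atac_values = {
            chrom: grammar.max_amplitude * activity[chrom]
            + np.abs(rng.normal(0.0, cfg.atac_noise, size=n_bins))
            for chrom in sim.genome.names
        }
        atac[cell] = BinnedTrack(sim.genome, cfg.bin, atac_values, assay="ATAC", cell=cell)
    return histone, atac


# ---------------------------------------------------------------------------
# marker genes


def marker_separation_statistic(
    atac: dict[str, BinnedTrack],
    markers: pd.DataFrame,
    tss_window: int,
    global_bin: int,
    rng: np.random.Generator,
    noise_scale: float = 0.15,
) -> tuple[float, float]:
    """(actual, null) mean pairwise distance between cells' global
    accessibility vectors.

    The null sets every cell's motif usage to zero — accessibility is
    then background noise only — so it measures the distance two cells
    would show with no planted cell identity at all.  Marker genes
    separate cells when the actual distance clearly exceeds this floor.
    """
    from .features import _window_mean_coarse

    per_gene = tss_window // global_bin
    cells = sorted(atac)

    def vectors(tracks: dict[str, BinnedTrack]) -> np.ndarray:
        vecs = []
        for cell in cells:
            track = tracks[cell]
            chunks = []
            for row in markers.itertuples():
                start = int(row.tss) - tss_window // 2
                chunks.append(
                    _window_mean_coarse(
                        track, row.chrom, start, start + tss_window, global_bin
                    )[:per_gene]
                )
            vecs.append(np.concatenate(chunks))
        return np.stack(vecs)

    def mean_dist(m: np.ndarray) -> float:
        d = np.linalg.norm(m[:, None, :] - m[None, :, :], axis=-1)
        iu = np.triu_indices(len(m), 1)
        return float(d[iu].mean())

    genome = atac[cells[0]].genome
    bin_size = atac[cells[0]].bin_size
    null_tracks = {
        cell: BinnedTrack(
            genome, bin_size,
            {
                c: np.abs(rng.normal(0.0, noise_scale,
                                     size=genome.n_bins(c, bin_size)))
                for c in genome.names
            },
            assay="ATAC", cell=cell,
        )
        for cell in cells
    }
    return mean_dist(vectors(atac)), mean_dist(vectors(null_tracks))


def simulate_marker_genes(
    sim: SimGenome, grammar: RegulatoryGrammar, cfg: SimConfig,
    atac: dict[str, BinnedTrack] | None = None,
) -> pd.DataFrame:
    """Marker-gene TSS table anchored at cell-discriminative (private)
    motif sites, cycling over cells.

    When ``atac`` is given, the cell-separation of the resulting global
    vectors is checked against a shuffled-usage null at generation time.
    """
    n_cells = grammar.usage.shape[0]
    private = [
        m for m in range(grammar.usage.shape[1])
        if np.count_nonzero(grammar.usage[:, m]) == 1
    ]
    pool = sim.occurrences.query("motif in @private and not broken")
    margin = max(2048, 2 * cfg.bin)
    pool = pool[(pool.pos > margin) & (pool.pos < cfg.chrom_len - margin)]
    rows = []
    used = {m: 0 for m in private}
    for g in range(cfg.n_marker_genes):
        placed = False
        # cycle private motifs, taking each motif's next unused site
        for step in range(len(private)):
            m = private[(g + step) % len(private)]
            sites = pool[pool.motif == m]
            if len(sites) > used[m]:
                site = sites.iloc[used[m]]
                used[m] += 1
                rows.append((f"gene{g}", site.chrom, int(site.pos)))
                placed = True
                break
        if not placed:
            raise ConfigError("not enough private sites to place marker genes")
    markers = pd.DataFrame(rows, columns=["gene", "chrom", "tss"])
    if atac is not None:
        rng = np.random.default_rng(cfg.seed + 3)
        actual, null = marker_separation_statistic(
            atac, markers, 3000, 250, rng, noise_scale=cfg.atac_noise
        )
        if not actual > null:
            raise ConfigError(
                "marker genes do not separate cells better than shuffled null"
            )
    return markers


# ---------------------------------------------------------------------------
# hQTL


def simulate_hqtl(
    sim: SimGenome,
    grammar: RegulatoryGrammar,
    cfg: SimConfig,
    seed: int,
    study_cell: str | None = None,
    study_mark: int = 0,
) -> tuple[list[Variant], list[HqtlRecord], pd.DataFrame]:
    """Variants hitting planted motif instances, with known signed effects.

    A variant at an intact instance breaks the consensus (negative true
    effect on overlapping peaks); a variant at a broken instance
    restores it (positive effect).  Decoy trans and far-distance records
    are appended for munging tests.  Betas are the true effects plus
    Gaussian noise; p-values come from a one-sided normal on β/noise.
    """
    rng = np.random.default_rng(seed)
    study_cell = study_cell or cfg.cells[0]
    ci = cfg.cells.index(study_cell)
    occ = sim.occurrences
    # keep sites whose motif is active in the study cell
    active = [m for m in range(grammar.usage.shape[1]) if grammar.usage[ci, m] > 0]
    pool = occ.query("motif in @active").sample(
        frac=1.0, random_state=int(rng.integers(2**31))
    )
    variants: list[Variant] = []
    records: list[HqtlRecord] = []
    truth_rows = []
    hw = grammar.peak_half_width
    for row in pool.itertuples():
        if len(variants) >= cfg.n_hqtl:
            break
        motif = grammar.motifs[row.motif]
        mid = len(motif) // 2
        pos = row.pos - len(motif) // 2 + mid  # genome position of central base
        ref = sim.sequences[row.chrom][pos]
        consensus_mid = (
            motif[mid] if row.strand == "+" else reverse_complement(motif)[mid]
        )
        if row.broken:
            alt = consensus_mid      # restoring variant
            sign = +1.0
        else:
            alt = _broken_motif(motif if row.strand == "+" else
                                reverse_complement(motif), rng)[mid]
            sign = -1.0
        if ref == alt:
            continue
        amp = grammar.max_amplitude * grammar.usage[ci, row.motif] * \
            grammar.affinity[row.motif, study_mark]
        vid = f"rs{len(variants)}"
        var = Variant(row.chrom, pos, ref, alt, vid)
        true_effect = sign * amp
        beta = true_effect + rng.normal(0.0, cfg.beta_noise)
        p = float(stats.norm.sf(abs(beta) / cfg.beta_noise))
        records.append(
            HqtlRecord(var, row.chrom, max(row.pos - hw, 0), row.pos + hw,
                       beta, max(p, 1e-300))
        )
        variants.append(var)
        truth_rows.append((vid, row.chrom, pos, true_effect))
    if len(variants) < cfg.n_hqtl:
        raise ConfigError("not enough eligible motif instances for requested hQTLs")
    # decoys reuse the first variants with displaced peaks
    chroms = list(sim.genome.names)
    for d in range(cfg.n_trans_decoys):
        v = variants[d % len(variants)]
        other = next(c for c in chroms if c != v.chrom)
        records.append(
            HqtlRecord(v, other, 1000, 1000 + 2 * hw,
                       float(rng.normal(0.0, cfg.beta_noise)), 0.5)
        )
    for d in range(cfg.n_far_decoys):
        v = variants[d % len(variants)]
        far = (v.pos + cfg.chrom_len // 2) % (cfg.chrom_len - 4 * hw) + hw
        records.append(
            HqtlRecord(v, v.chrom, far, far + 2 * hw,
                       float(rng.normal(0.0, cfg.beta_noise)), 0.5)
        )
    truth = pd.DataFrame(truth_rows, columns=["snp", "chrom", "pos", "true_effect"])
    return variants, records, truth
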