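"""Binned genomic signal tracks and interval sets.

This module is the single home of the package's coordinate and scale
conventions:

* coordinates are 0-based, half-open everywhere internally;
* signal tracks are stored at a fixed bin size as one vector per
  chromosome, with a trailing partial bin at the chromosome end when the
  length is not a multiple of the bin size;
* every track carries a ``scale`` tag.  ``neglog10p`` is the MACS2-style
  -log10 adjusted p-value of binding; ``arcsinh`` is its
  variance-stabilised transform sinh⁻¹x = ln(x + √(1+x²)) used as the
  training scale; ``delta`` is a signed difference between two arcsinh
  tracks (cell minus training average).

bedGraph is the canonical on-disk format; wiggle fixedStep is read for
interoperability and bigWig is supported when pyBigWig is importable.
Positions a bedGraph does not mention are zero, matching the "no
evidence of binding" semantics of a -log10 p-value track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    GeometryError,
    OverlappingIntervalsError,
    RebinError,
    ScaleError,
    UnknownChromosomeError,
)

SCALES = ("neglog10p", "arcsinh", "delta")


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths in base pairs."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise GeometryError("chromosome names must be unique")
        if any(l <= 0 for l in self.lengths):
            raise GeometryError("chromosome lengths must be positive")
        if len(self.names) != len(self.lengths):
            raise GeometryError("names and lengths differ in count")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeIndex":
        return cls(tuple(d), tuple(int(v) for v in d.values()))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise UnknownChromosomeError(chrom) from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(zip(self.names, self.lengths))

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return math.ceil(self.length_of(chrom) / bin_size)


@dataclass
class BinnedTrack:
    """Fixed-resolution signal vectors, one per chromosome.

    ``values[chrom]`` has length ``ceil(chrom_length / bin_size)``; the
    last bin averages over covered bases only.
    """

    genome: GenomeIndex
    bin_size: int
    values: dict[str, np.ndarray]
    assay: str = "signal"
    cell: str = "unknown"
    scale: str = "neglog10p"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}")
        for chrom, v in self.values.items():
            expect = self.genome.n_bins(chrom, self.bin_size)
            if len(v) != expect:
                raise GeometryError(
                    f"{chrom}: {len(v)} bins, expected {expect} at {self.bin_size} bp"
                )
            if not np.all(np.isfinite(v)):
                raise GeometryError(f"{chrom}: non-finite values")
            if self.scale == "neglog10p" and np.any(v < 0):
                raise ScaleError("neglog10p values must be non-negative")

    @classmethod
    def zeros(
        cls,
        genome: GenomeIndex,
        bin_size: int,
        assay: str = "signal",
        cell: str = "unknown",
        scale: str = "neglog10p",
    ) -> "BinnedTrack":
        values = {
            c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.names
        }
        return cls(genome, bin_size, values, assay, cell, scale)

    def copy(self) -> "BinnedTrack":
        return replace(self, values={c: v.copy() for c, v in self.values.items()})

    def window(self, chrom: str, start_bp: int, n_bins: int) -> np.ndarray:
        """Values of ``n_bins`` bins starting at base ``start_bp`` (bin-aligned)."""
        if start_bp % self.bin_size:
            raise GeometryError("window start is not bin-aligned")
        b0 = start_bp // self.bin_size
        v = self.values[chrom]
        if b0 < 0 or b0 + n_bins > len(v):
            raise GeometryError("window outside chromosome")
        return v[b0 : b0 + n_bins]


@dataclass
class IntervalSet:
    """0-based half-open genomic intervals with optional names."""

    chroms: list[str] = field(default_factory=list)
    starts: list[int] = field(default_factory=list)
    ends: list[int] = field(default_factory=list)
    names: list[str] = field(default_factory=list)

    def add(self, chrom: str, start: int, end: int, name: str = ".") -> None:
        if start >= end:
            raise GeometryError(f"start {start} >= end {end}")
        self.chroms.append(chrom)
        self.starts.append(int(start))
        self.ends.append(int(end))
        self.names.append(name)

    def __len__(self) -> int:
        return len(self.chroms)

    def __iter__(self) -> Iterator[tuple[str, int, int, str]]:
        return iter(zip(self.chroms, self.starts, self.ends, self.names))

    def validate(self, genome: GenomeIndex) -> None:
        for chrom, start, end, _ in self:
            if chrom not in genome:
                raise UnknownChromosomeError(chrom)
            if start < 0 or end > genome.length_of(chrom):
                raise GeometryError(f"{chrom}:{start}-{end} out of bounds")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        for c, s, e, _ in self:
            if c == chrom and s < end and e > start:
                return True
        return False

    @classmethod
    def read_bed(cls, path: str | Path) -> "IntervalSet":
        out = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                name = parts[3] if len(parts) > 3 else "."
                out.add(parts[0], int(parts[1]), int(parts[2]), name)
        return out

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, name in self:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


# ---------------------------------------------------------------------------
# io


def read_bedgraph(
    path: str | Path,
    genome: GenomeIndex,
    bin_size: int,
    assay: str = "signal",
    cell: str = "unknown",
    scale: str = "neglog10p",
) -> BinnedTrack:
    """Read a bedGraph into a :class:`BinnedTrack`.

    Records must be bin-aligned at ``bin_size`` (the way the track writer
    emits them); unmentioned positions are 0.  Overlapping records and
    unknown chromosomes raise named errors.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        float_precision="round_trip",  # repr-written values read back exactly
    )
    track = BinnedTrack.zeros(genome, bin_size, assay, cell, scale)
    seen: dict[str, np.ndarray] = {
        c: np.zeros(len(v), dtype=bool) for c, v in track.values.items()
    }
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise UnknownChromosomeError(str(chrom))
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        vals = sub["value"].to_numpy(dtype=float)
        if np.any(starts % bin_size) or np.any(
            (ends % bin_size) & (ends != genome.length_of(str(chrom)))
        ):
            raise GeometryError(
                f"{chrom}: bedGraph records not aligned to {bin_size} bp bins"
            )
        tv = track.values[str(chrom)]
        sv = seen[str(chrom)]
        for s, e, val in zip(starts, ends, vals):
            b0, b1 = s // bin_size, math.ceil(e / bin_size)
            if sv[b0:b1].any():
                raise OverlappingIntervalsError(f"{chrom}:{s}-{e}")
            sv[b0:b1] = True
            tv[b0:b1] = val
    return BinnedTrack(genome, bin_size, track.values, assay, cell, scale)


def write_bedgraph(track: BinnedTrack, path: str | Path, sparse: bool = True) -> None:
    """Write a track as bedGraph; zero runs are omitted when ``sparse``."""
    with open(path, "w") as fh:
        for chrom, n in track.genome.items():
            v = track.values[chrom]
            for i, val in enumerate(v):
                if sparse and val == 0.0:
                    continue
                s = i * track.bin_size
                e = min(s + track.bin_size, n)
                fh.write(f"{chrom}\t{s}\t{e}\t{float(val)!r}\n")


def read_wiggle(
    path: str | Path,
    genome: GenomeIndex,
    bin_size: int,
    assay: str = "signal",
    cell: str = "unknown",
    scale: str = "neglog10p",
) -> BinnedTrack:
    """Read a wiggle fixedStep file whose step/span equal ``bin_size``."""
    track = BinnedTrack.zeros(genome, bin_size, assay, cell, scale)
    chrom, pos = None, 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                if chrom not in genome:
                    raise UnknownChromosomeError(chrom)
                if int(fields.get("step", bin_size)) != bin_size:
                    raise GeometryError("fixedStep step must equal bin_size")
                pos = int(fields["start"]) - 1  # wiggle is 1-based
                if pos % bin_size:
                    raise GeometryError("fixedStep start not bin-aligned")
                continue
            if chrom is None:
                raise GeometryError("value before fixedStep header")
            track.values[chrom][pos // bin_size] = float(line)
            pos += bin_size
    return track


def read_bigwig(
    path: str | Path,
    genome: GenomeIndex,
    bin_size: int,
    assay: str = "signal",
    cell: str = "unknown",
    scale: str = "neglog10p",
) -> BinnedTrack:  # pragma: no cover - optional dependency
    import pyBigWig

    bw = pyBigWig.open(str(path))
    track = BinnedTrack.zeros(genome, bin_size, assay, cell, scale)
    for chrom, length in genome.items():
        if chrom not in bw.chroms():
            continue
        n = genome.n_bins(chrom, bin_size)
        vals = np.array(bw.stats(chrom, 0, length, nBins=n, type="mean"), dtype=float)
        vals[~np.isfinite(vals)] = 0.0
        track.values[chrom] = vals
    bw.close()
    return track


_READERS = {"bedGraph": read_bedgraph, "wig": read_wiggle, "bigWig": read_bigwig}


def track_io(
    path: str | Path,
    mode: str,
    genome: GenomeIndex,
    fmt: str = "bedGraph",
    track: BinnedTrack | None = None,
    bin_size: int | None = None,
    **labels,
) -> BinnedTrack | None:
    """Single entry point for reading/writing tracks in any supported format."""
    if mode == "read":
        if bin_size is None:
            raise GeometryError("bin_size required for reading")
        return _READERS[fmt](path, genome, bin_size, **labels)
    if mode == "write":
        if track is None:
            raise GeometryError("track required for writing")
        if fmt != "bedGraph":
            raise GeometryError("only bedGraph writing is supported")
        write_bedgraph(track, path)
        return None
    raise ValueError(f"mode must be read or write, got {mode!r}")


# ---------------------------------------------------------------------------
# transforms


def _cumulative_bp(values: np.ndarray, bin_size: int, length: int) -> np.ndarray:
    """S[x] = integral of the per-base signal over bases [0, x)."""
    # per-base value of bin i is values[i]; vectorised exact integral
    edges = np.minimum(np.arange(len(values) + 1) * bin_size, length)
    widths = np.diff(edges)
    return np.concatenate([[0.0], np.cumsum(values * widths)])


def rebin(track: BinnedTrack, new_bin: int) -> BinnedTrack:
    """Rebin to a coarser resolution by base-pair-overlap-weighted averaging.

    Exact for any bin-size pair (128 is not a multiple of 25, so output
    bins weight the input bins they partially cover by fractional
    overlap).  Trailing partial bins average over covered bases only.
    """
    if new_bin < track.bin_size:
        raise RebinError(f"cannot upsample {track.bin_size} -> {new_bin} bp")
    if new_bin == track.bin_size:
        return track.copy()
    out: dict[str, np.ndarray] = {}
    for chrom, length in track.genome.items():
        v = track.values[chrom]
        cum = _cumulative_bp(v, track.bin_size, length)
        n_new = math.ceil(length / new_bin)
        lo = np.minimum(np.arange(n_new) * new_bin, length)
        hi = np.minimum(lo + new_bin, length)
        # integral over [lo, hi) via interpolation of the piecewise-linear cumsum
        grid = np.minimum(np.arange(len(cum)) * track.bin_size, length)
        s_lo = np.interp(lo, grid, cum)
        s_hi = np.interp(hi, grid, cum)
        out[chrom] = (s_hi - s_lo) / (hi - lo)
    return replace(track, bin_size=new_bin, values=out)


def arcsinh_transform(track: BinnedTrack, direction: str = "forward") -> BinnedTrack:
    """Elementwise sinh⁻¹x = ln(x + √(1+x²)) (or its inverse sinh)."""
    if direction == "forward":
        if track.scale != "neglog10p":
            raise ScaleError(f"forward transform expects neglog10p, got {track.scale}")
        values = {c: np.arcsinh(v) for c, v in track.values.items()}
        return replace(track, values=values, scale="arcsinh")
    if direction == "inverse":
        if track.scale != "arcsinh":
            raise ScaleError(f"inverse transform expects arcsinh, got {track.scale}")
        values = {c: np.sinh(v) for c, v in track.values.items()}
        return replace(track, values=values, scale="neglog10p")
    raise ValueError(f"direction must be forward or inverse, got {direction!r}")


def average_tracks(tracks: Sequence[BinnedTrack]) -> BinnedTrack:
    """Elementwise arithmetic mean across cell types; cell label "average"."""
    if not tracks:
        raise GeometryError("no tracks to average")
    first = tracks[0]
    for t in tracks[1:]:
        if (
            t.genome != first.genome
            or t.bin_size != first.bin_size
            or t.scale != first.scale
            or t.assay != first.assay
        ):
            raise GeometryError("tracks disagree in genome, bin size, scale or assay")
    values = {
        c: np.mean([t.values[c] for t in tracks], axis=0) for c in first.genome.names
    }
    return replace(first, values=values, cell="average")
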