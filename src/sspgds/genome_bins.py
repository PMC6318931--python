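"""Genome tilings for read-depth analysis.

The pipeline works on three nested fixed-width tilings of the reference
genome: 20 kb working bins (counting, GC correction), 500 kb bins
(segmentation) and 1 Mb bins (the CV quality metric).  A :class:`BinGrid`
holds one tiling together with per-bin GC fraction and a boolean mask;
coordinates are 0-based half-open (BED convention) and chromosomes are kept
in karyotype order chr1..chr22, chrX, chrY.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

KARYOTYPE_ORDER: tuple[str, ...] = tuple(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
)
AUTOSOMES: tuple[str, ...] = KARYOTYPE_ORDER[:22]

#: default working / segmentation / QC bin sizes in bp
BIN_SIZE_20KB = 20_000
BIN_SIZE_500KB = 500_000
BIN_SIZE_1MB = 1_000_000


def _normalize_chrom(name: str) -> str:
    name = str(name).strip()
    if not name.lower().startswith("chr"):
        name = "chr" + name
    return "chr" + name[3:].upper() if name[3:] in ("x", "y") else name


@dataclass(frozen=True, eq=False)
class BinGrid:
    """A fixed-width tiling of the genome.

    Attributes
    ----------
    bin_size : int
        Nominal bin width in bp; the last bin of each chromosome may be
        shorter.
    chroms : tuple of str
        Chromosome names present, in karyotype order.
    chrom_sizes : dict
        Chromosome lengths in bp.
    chrom_index : ndarray of int
        Per-bin index into ``chroms``.
    start, end : ndarray of int
        Per-bin 0-based half-open coordinates.
    gc : ndarray of float
        Per-bin GC fraction in [0, 1]; NaN where unknown.
    masked : ndarray of bool
        Structural mask (e.g. N-rich bins).
    """

    bin_size: int
    chroms: tuple[str, ...]
    chrom_sizes: dict[str, int]
    chrom_index: np.ndarray
    start: np.ndarray
    end: np.ndarray
    gc: np.ndarray
    masked: np.ndarray
    _slices: dict[str, slice] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._slices is None:
            sl = {}
            for ci, name in enumerate(self.chroms):
                idx = np.flatnonzero(self.chrom_index == ci)
                sl[name] = slice(int(idx[0]), int(idx[-1]) + 1)
            object.__setattr__(self, "_slices", sl)

    # -- basic accessors -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return self.start.size

    @property
    def widths(self) -> np.ndarray:
        return self.end - self.start

    @property
    def is_autosome(self) -> np.ndarray:
        auto = np.array([c in AUTOSOMES for c in self.chroms])
        return auto[self.chrom_index]

    def chrom_slice(self, chrom: str) -> slice:
        return self._slices[chrom]

    def bin_chrom_names(self) -> np.ndarray:
        return np.asarray(self.chroms, dtype=object)[self.chrom_index]

    # -- invariant check -------------------------------------------------
    def validate(self) -> None:
        w = self.widths
        if np.any(w <= 0):
            raise ValueError("bins with non-positive width")
        for name in self.chroms:
            sl = self.chrom_slice(name)
            s, e = self.start[sl], self.end[sl]
            if s[0] != 0 or e[-1] != self.chrom_sizes[name]:
                raise ValueError(f"{name}: tiling does not cover chromosome")
            if np.any(s[1:] != e[:-1]):
                raise ValueError(f"{name}: bins not contiguous")
            if np.any((e - s)[:-1] != self.bin_size):
                raise ValueError(f"{name}: interior bin width != bin_size")
        gc_ok = np.isnan(self.gc) | ((self.gc >= 0) & (self.gc <= 1))
        if not np.all(gc_ok):
            raise ValueError("gc outside [0, 1]")

    # -- aggregation -----------------------------------------------------
    def superbin_index(self, factor: int) -> np.ndarray:
        """Map each bin to the index of its parent bin in the
        ``factor``-fold aggregated grid."""
        if factor <= 0:
            raise ValueError("factor must be positive")
        out = np.empty(self.n_bins, dtype=np.int64)
        offset = 0
        for name in self.chroms:
            sl = self.chrom_slice(name)
            n = sl.stop - sl.start
            local = np.arange(n) // factor
            out[sl] = local + offset
            offset += int(local[-1]) + 1
        return out

    def aggregate(self, factor: int) -> "BinGrid":
        """Aggregate ``factor`` consecutive bins per chromosome into one.

        Each superbin covers a whole number of child bins; boundaries equal
        those of ``make_bins(chrom_sizes, bin_size * factor)`` exactly.
        GC is the width-weighted mean of child GC; a superbin is masked only
        if all its children are masked.
        """
        parent = self.superbin_index(factor)
        n_super = int(parent[-1]) + 1
        start = np.full(n_super, np.iinfo(np.int64).max, dtype=np.int64)
        end = np.zeros(n_super, dtype=np.int64)
        np.minimum.at(start, parent, self.start)
        np.maximum.at(end, parent, self.end)
        chrom_index = np.zeros(n_super, dtype=np.int64)
        chrom_index[parent] = self.chrom_index

        w = self.widths.astype(float)
        has_gc = ~np.isnan(self.gc)
        wg = np.where(has_gc, w, 0.0)
        num = np.zeros(n_super)
        den = np.zeros(n_super)
        np.add.at(num, parent, np.where(has_gc, self.gc * w, 0.0))
        np.add.at(den, parent, wg)
        with np.errstate(invalid="ignore"):
            gc = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

        n_unmasked = np.zeros(n_super)
        np.add.at(n_unmasked, parent, (~self.masked).astype(float))
        masked = n_unmasked == 0
        return BinGrid(
            bin_size=self.bin_size * factor,
            chroms=self.chroms,
            chrom_sizes=self.chrom_sizes,
            chrom_index=chrom_index,
            start=start,
            end=end,
            gc=gc,
            masked=masked,
        )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column (name, length) TSV of chromosome sizes."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     comment="#", dtype={0: str})
    if df.empty:
        raise ValueError(f"empty chromosome-sizes table: {path}")
    return {str(c): int(l) for c, l in zip(df["chrom"], df["length"])}


def load_hg19_chrom_sizes() -> dict[str, int]:
    """The packaged hg19 chromosome sizes (24 screening chromosomes)."""
    ref = importlib.resources.files("sspgds").joinpath("data/hg19.chrom.sizes")
    with importlib.resources.as_file(ref) as p:
        return read_chrom_sizes(p)


def make_bins(chrom_sizes: dict[str, int], bin_size: int) -> BinGrid:
    """Tile every chromosome with fixed-width bins.

    Chromosomes are reordered into karyotype order; contigs outside
    chr1..chr22, chrX, chrY (mitochondrial, alternates) are dropped.  Each
    chromosome gets ``ceil(length / bin_size)`` bins; the last bin absorbs
    the remainder.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not chrom_sizes:
        raise ValueError("empty chromosome-sizes table")
    sizes = {_normalize_chrom(c): int(l) for c, l in chrom_sizes.items()}
    chroms = tuple(c for c in KARYOTYPE_ORDER if c in sizes)
    if not chroms:
        raise ValueError("no karyotype chromosomes (chr1..chr22, chrX, chrY) found")
    for c in chroms:
        if sizes[c] <= 0:
            raise ValueError(f"non-positive length for {c}")
    starts, ends, cidx = [], [], []
    for ci, name in enumerate(chroms):
        length = sizes[name]
        edges = np.arange(0, length + bin_size, bin_size)
        edges[-1] = min(edges[-1], length)
        if edges[-1] == edges[-2]:
            edges = edges[:-1]
        starts.append(edges[:-1])
        ends.append(edges[1:])
        cidx.append(np.full(edges.size - 1, ci, dtype=np.int64))
    start = np.concatenate(starts)
    n = start.size
    grid = BinGrid(
        bin_size=int(bin_size),
        chroms=chroms,
        chrom_sizes={c: sizes[c] for c in chroms},
        chrom_index=np.concatenate(cidx),
        start=start,
        end=np.concatenate(ends),
        gc=np.full(n, np.nan),
        masked=np.zeros(n, dtype=bool),
    )
    grid.validate()
    return grid


def annotate_gc(grid: BinGrid, genome, n_mask_fraction: float = 0.5) -> BinGrid:
    """Annotate per-bin GC fraction from a genome FASTA.

    ``genome`` is a path to an (indexed) FASTA or a ``pyfaidx.Fasta``-like
    mapping of chromosome name to sequence.  GC is (G+C)/(A+C+G+T); bins
    with more than ``n_mask_fraction`` N bases get missing GC and are
    masked.
    """
    if isinstance(genome, (str, Path)):
        from pyfaidx import Fasta

        genome = Fasta(str(genome))
    gc = np.full(grid.n_bins, np.nan)
    masked = grid.masked.copy()
    for name in grid.chroms:
        if name not in genome:
            raise KeyError(f"chromosome {name!r} missing from FASTA")
        seq = str(genome[name][:]).upper()
        sl = grid.chrom_slice(name)
        for i in range(sl.start, sl.stop):
            s = seq[grid.start[i]:grid.end[i]]
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            n_n = int(np.sum(arr == ord("N")))
            if n_n > n_mask_fraction * arr.size:
                masked[i] = True
                continue
            acgt = arr.size - n_n
            if acgt == 0:
                masked[i] = True
                continue
            n_gc = int(np.sum((arr == ord("G")) | (arr == ord("C"))))
            gc[i] = n_gc / acgt
    return replace(grid, gc=gc, masked=masked)


def write_bed(grid: BinGrid, path: str | Path) -> None:
    """Persist a grid as BED4+2 (chrom, start, end, bin_id, gc, masked)."""
    names = grid.bin_chrom_names()
    df = pd.DataFrame(
        {
            "chrom": names,
            "start": grid.start,
            "end": grid.end,
            "bin_id": np.arange(grid.n_bins),
            "gc": np.round(grid.gc, 6),
            "masked": grid.masked.astype(int),
        }
    )
    with open(path, "w") as fh:
        fh.write(f"#bin_size={grid.bin_size}\n")
        df.to_csv(fh, sep="\t", header=False, index=False, na_rep="NA")


def read_bed(path: str | Path) -> BinGrid:
    """Read a grid written by :func:`write_bed`."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#bin_size="):
            raise ValueError("missing #bin_size header")
        bin_size = int(header.strip().split("=")[1])
        df = pd.read_csv(
            fh, sep="\t", header=None,
            names=["chrom", "start", "end", "bin_id", "gc", "masked"],
            na_values="NA",
        )
    chroms = tuple(dict.fromkeys(df["chrom"]))
    cmap = {c: i for i, c in enumerate(chroms)}
    sizes = df.groupby("chrom", sort=False)["end"].max().to_dict()
    grid = BinGrid(
        bin_size=bin_size,
        chroms=chroms,
        chrom_sizes={c: int(sizes[c]) for c in chroms},
        chrom_index=df["chrom"].map(cmap).to_numpy(dtype=np.int64),
        start=df["start"].to_numpy(dtype=np.int64),
        end=df["end"].to_numpy(dtype=np.int64),
        gc=df["gc"].to_numpy(dtype=float),
        masked=df["masked"].to_numpy(dtype=bool),
    )
    grid.validate()
    return grid
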