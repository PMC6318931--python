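"""Per-bin unique-read counting from alignment files.

Reads are filtered the way low-pass single-cell pipelines filter them:
unmapped reads, multi-hit reads (secondary/supplementary records, or primary
records with mapping quality 0) and duplicates are removed; every retained
read increments exactly one 20 kb bin, chosen by its leftmost mapped
coordinate.  When the aligner did not flag duplicates, exact
(chrom, start, strand) collisions are treated as duplicates, which is exact
for coordinate-sorted input and keeps memory bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_bins import BinGrid


@dataclass
class CountProfile:
    """Raw per-bin unique-read counts for one sample plus filter tallies."""

    sample_id: str
    counts: np.ndarray  # int per 20 kb bin, aligned with the grid
    n_total_reads: int = 0
    n_unmapped: int = 0
    n_multimapped: int = 0
    n_duplicates: int = 0
    n_unique_mapped: int = 0
    n_other_filtered: int = 0
    read_length: int = 150
    meta: dict = field(default_factory=dict)

    def validate(self, grid: BinGrid | None = None) -> None:
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")
        if int(self.counts.sum()) != self.n_unique_mapped:
            raise ValueError("sum(counts) != n_unique_mapped")
        parts = (self.n_unmapped + self.n_multimapped + self.n_duplicates
                 + self.n_unique_mapped + self.n_other_filtered)
        if parts != self.n_total_reads:
            raise ValueError("filter tallies do not partition total reads")
        if grid is not None and self.counts.size != grid.n_bins:
            raise ValueError(
                f"profile has {self.counts.size} bins, grid has {grid.n_bins}"
            )


def count_reads(alignments: str | Path, grid: BinGrid,
                sample_id: str | None = None) -> CountProfile:
    """Count retained reads per bin from a coordinate-sorted SAM/BAM file.

    Retained = mapped, primary, MAPQ > 0, not a duplicate.  Duplicate
    detection honors the duplicate FLAG when the input carries it and
    otherwise marks exact (chrom, start, strand) collisions.
    """
    import pysam

    path = str(alignments)
    mode = "rb" if path.endswith(".bam") else "r"
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    n_total = n_unmapped = n_multi = n_dup = n_unique = n_other = 0
    read_lengths: list[int] = []
    chrom_offsets = {c: grid.chrom_slice(c).start for c in grid.chroms}
    unknown_chroms: set[str] = set()

    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        so = (af.header.get("HD") or {}).get("SO")
        last_pos: tuple[int, int] | None = None
        seen_strands: set[bool] = set()
        for rec in af:
            n_total += 1
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                n_multi += 1
                continue
            if rec.mapping_quality == 0:
                n_multi += 1
                continue
            if rec.is_duplicate:
                n_dup += 1
                continue
            key = (rec.reference_id, rec.reference_start)
            if key == last_pos:
                if rec.is_reverse in seen_strands:
                    n_dup += 1
                    continue
                seen_strands.add(rec.is_reverse)
            else:
                if last_pos is not None and key < last_pos:
                    raise ValueError(
                        f"{path}: input is not coordinate-sorted "
                        f"(SO={so!r}); sort before counting"
                    )
                last_pos = key
                seen_strands = {rec.is_reverse}
            chrom = rec.reference_name
            if chrom not in chrom_offsets:
                unknown_chroms.add(chrom)
                n_other += 1
                continue
            sl = grid.chrom_slice(chrom)
            b = sl.start + rec.reference_start // grid.bin_size
            if b >= sl.stop:  # read beyond declared chromosome end
                n_other += 1
                continue
            counts[b] += 1
            n_unique += 1
            if rec.query_length:
                read_lengths.append(rec.query_length)

    prof = CountProfile(
        sample_id=sample_id or Path(path).stem,
        counts=counts,
        n_total_reads=n_total,
        n_unmapped=n_unmapped,
        n_multimapped=n_multi,
        n_duplicates=n_dup,
        n_unique_mapped=n_unique,
        n_other_filtered=n_other,
        read_length=int(np.median(read_lengths)) if read_lengths else 0,
        meta={"skipped_chroms": sorted(unknown_chroms)} if unknown_chroms else {},
    )
    prof.validate(grid)
    return prof


def duplication_ratio(profile: CountProfile) -> float:
    """Duplicate fraction among mapped unique+duplicate reads."""
    denom = profile.n_duplicates + profile.n_unique_mapped
    if profile.n_total_reads <= 0 or denom <= 0:
        raise ValueError("no mapped reads: duplication ratio undefined")
    return profile.n_duplicates / denom


_TALLY_FIELDS = ("n_total_reads", "n_unmapped", "n_multimapped",
                 "n_duplicates", "n_unique_mapped", "n_other_filtered",
                 "read_length")


def write_counts_table(profile: CountProfile, path: str | Path) -> None:
    """Write a counts TSV: '#key=value' header block, then bin_id<TAB>count."""
    with open(path, "w") as fh:
        fh.write(f"#sample_id={profile.sample_id}\n")
        for k in _TALLY_FIELDS:
            fh.write(f"#{k}={getattr(profile, k)}\n")
        for i, c in enumerate(profile.counts):
            fh.write(f"{i}\t{c}\n")


def read_counts_table(path: str | Path, grid: BinGrid | None = None) -> CountProfile:
    """Read a counts TSV written by :func:`write_counts_table`."""
    meta: dict[str, str] = {}
    bin_ids: list[int] = []
    counts: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: malformed header line")
                k, v = line[1:].split("=", 1)
                meta[k] = v
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                b, c = int(parts[0]), int(parts[1])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer field") from e
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative count")
            bin_ids.append(b)
            counts.append(c)
    if bin_ids != list(range(len(bin_ids))):
        raise ValueError(f"{path}: bin_id column must be 0..n-1 in order")
    arr = np.asarray(counts, dtype=np.int64)
    if grid is not None and arr.size != grid.n_bins:
        raise ValueError(
            f"{path}: {arr.size} bins in table but grid has {grid.n_bins}"
        )
    prof = CountProfile(
        sample_id=meta.get("sample_id", Path(path).stem),
        counts=arr,
        **{k: int(meta.get(k, 0)) for k in _TALLY_FIELDS},
    )
    prof.validate(grid)
    return prof
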