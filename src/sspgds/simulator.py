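"""Synthetic single-cell WGA count profiles.

The generator emulates low-pass (4-5 M unique reads) sequencing of
whole-genome-amplified single-cell DNA on the 20 kb grid.  Per-bin expected
counts are

    lambda_i  proportional to  copy_i/2 * bias(gc_i) * W_block(i) * width_i,

where ``bias`` is a smooth GC curve, ``W`` is a reproducible lognormal
"amplification wave" at 1 Mb scale (fixed per grid and kit preset, shared
across samples — the reproducible part of WGA bias that reference-panel
normalization removes) and each sample additionally draws an independent
per-bin lognormal effect.  Counts are Poisson around that mean, giving
negative-binomial-like overdispersion.  The per-sample noise scale is
calibrated so the coefficient of variation of 1 Mb-aggregated corrected
ratios matches the kit's observed value (SurePlex 0.133, DOP-PCR 0.11)
at the kit's nominal unique-read count.

Mixtures model mosaicism: a sample at mixing proportion p carries per-bin
copy p * abnormal + (1-p) * euploid, mirroring DNA mixing experiments at
proportions 0.3 and 0.7.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_bins import (
    BIN_SIZE_20KB,
    BinGrid,
    load_hg19_chrom_sizes,
    make_bins,
)
from .read_counting import CountProfile


@dataclass(frozen=True)
class NoisePreset:
    """Kit-specific noise calibration."""

    name: str
    cv_1mb_target: float     # CV of 1 Mb corrected ratios to reproduce
    gc_mean: float           # mean bin GC fraction
    gc_concentration: float  # Beta concentration (a+b) of bin GC
    gc_slope: float          # log-linear GC bias coefficient
    wave_sd: float           # sd of the reproducible 1 Mb amplification wave
    dup_ratio: float         # duplicate fraction dup/(dup+unique)
    unique_ratio: float      # unique mapped / total reads
    n_unique_reads: int      # nominal unique read count for calibration
    read_length: int = 150

    def bin_noise_sd(self, mean_count: float) -> float:
        """Per-sample per-bin lognormal sd closing the CV(1 Mb) budget.

        Solves  cv^2 = wave_sd^2 + (1/mean_count + (1+wave_sd^2) s^2)/50
        for s, the three variance sources being the shared wave, Poisson
        sampling and the sample-specific bin effect (50 bins of 20 kb per
        1 Mb).
        """
        resid = 50.0 * (self.cv_1mb_target**2 - self.wave_sd**2) - 1.0 / mean_count
        if resid <= 0:
            return 0.0
        return float(np.sqrt(resid / (1.0 + self.wave_sd**2)))


PRESETS: dict[str, NoisePreset] = {
    "sureplex": NoisePreset(
        name="sureplex", cv_1mb_target=0.133, gc_mean=0.448,
        gc_concentration=80.0, gc_slope=1.0, wave_sd=0.12,
        dup_ratio=0.187, unique_ratio=0.517, n_unique_reads=4_100_000,
    ),
    "doppcr": NoisePreset(
        name="doppcr", cv_1mb_target=0.11, gc_mean=0.414,
        gc_concentration=80.0, gc_slope=1.0, wave_sd=0.099,
        dup_ratio=0.199, unique_ratio=0.515, n_unique_reads=3_950_000,
    ),
}


AneuploidyEvent = tuple[str, str]            # (chrom, "trisomy"|"monosomy")
CnvEvent = tuple[str, int, int, int]         # (chrom, start, end, copies 1|3)


@dataclass(frozen=True)
class SimSpec:
    """One synthetic sample: karyotype events, mixing proportion, depth."""

    sample_id: str
    aneuploidies: tuple[AneuploidyEvent, ...] = ()
    cnvs: tuple[CnvEvent, ...] = ()
    mixing_proportion: float = 1.0  # fraction of the abnormal component
    n_unique_reads: int = 4_100_000
    sex: str = "XY"
    gc_slope: float | None = None      # None -> preset default
    bin_noise_sd: float | None = None  # None -> preset-calibrated
    wave_sd: float | None = None       # None -> preset default
    dup_ratio: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mixing_proportion <= 1.0:
            raise ValueError("mixing_proportion must be in [0, 1]")
        if self.n_unique_reads <= 0:
            raise ValueError("n_unique_reads must be positive")


def _grid_fixed_rng(grid: BinGrid, preset: NoisePreset, what: str):
    """Deterministic RNG for grid+preset-level fixtures (GC landscape,
    amplification wave) — fixed properties, independent of sample seeds."""
    entropy = [zlib.crc32(f"{preset.name}:{what}".encode()), grid.n_bins,
               grid.bin_size]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def synthetic_gc(grid: BinGrid, preset: NoisePreset) -> np.ndarray:
    """Draw a per-bin GC landscape from a Beta distribution (fixed per
    grid+preset), for running GC-correction logic without a genome."""
    rng = _grid_fixed_rng(grid, preset, "gc")
    a = preset.gc_mean * preset.gc_concentration
    b = (1.0 - preset.gc_mean) * preset.gc_concentration
    return rng.beta(a, b, grid.n_bins)


def make_synthetic_grid(preset: NoisePreset | str = "sureplex",
                        chrom_sizes: dict[str, int] | None = None,
                        bin_size: int = BIN_SIZE_20KB) -> BinGrid:
    """An hg19-sized working grid with synthetic GC annotations."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if chrom_sizes is None:
        chrom_sizes = load_hg19_chrom_sizes()
    grid = make_bins(chrom_sizes, bin_size)
    return replace(grid, gc=synthetic_gc(grid, preset))


def amplification_wave(grid: BinGrid, preset: NoisePreset,
                       wave_sd: float | None = None) -> np.ndarray:
    """The reproducible per-bin amplification propensity (lognormal, mean
    1, constant within 1 Mb blocks, fixed per grid+preset)."""
    sd = preset.wave_sd if wave_sd is None else wave_sd
    if sd <= 0:
        return np.ones(grid.n_bins)
    factor = max(1, 1_000_000 // grid.bin_size)
    block = grid.superbin_index(factor)
    rng = _grid_fixed_rng(grid, preset, "wave")
    sigma = np.sqrt(np.log1p(sd**2))
    w_block = rng.lognormal(-0.5 * sigma**2, sigma, int(block[-1]) + 1)
    return w_block[block]


def _base_copy(grid: BinGrid, sex: str) -> np.ndarray:
    copy = np.full(grid.n_bins, 2.0)
    names = grid.bin_chrom_names()
    if sex.upper() == "XY":
        copy[names == "chrX"] = 1.0
        copy[names == "chrY"] = 1.0
    elif sex.upper() == "XX":
        copy[names == "chrY"] = 0.0
    else:
        raise ValueError(f"unknown sex {sex!r}")
    return copy


def expected_copy_track(spec: SimSpec, grid: BinGrid) -> np.ndarray:
    """Per-bin expected copy number of the mixture.

    copy = p * copy_abnormal + (1 - p) * copy_euploid, with p the mixing
    proportion; purely diploid bins are exactly 2.
    """
    base = _base_copy(grid, spec.sex)
    abnormal = base.copy()
    names = grid.bin_chrom_names()
    for chrom, kind in spec.aneuploidies:
        sel = names == chrom
        if not sel.any():
            raise ValueError(f"unknown chromosome {chrom!r}")
        abnormal[sel] = abnormal[sel] + (1 if kind == "trisomy" else -1)
    touched = np.zeros(grid.n_bins, dtype=bool)
    for chrom, start, end, copies in spec.cnvs:
        sl = grid.chrom_slice(chrom)
        if not (0 <= start < end <= grid.chrom_sizes[chrom]):
            raise ValueError(f"CNV {chrom}:{start}-{end} outside chromosome")
        sel = np.zeros(grid.n_bins, dtype=bool)
        sel[sl] = (grid.start[sl] < end) & (grid.end[sl] > start)
        if np.any(sel & touched):
            raise ValueError("overlapping CNV events")
        touched |= sel
        abnormal[sel] = float(copies)
    p = spec.mixing_proportion
    return p * abnormal + (1.0 - p) * base


def simulate_counts(spec: SimSpec, grid: BinGrid,
                    preset: NoisePreset | str = "sureplex") -> CountProfile:
    """Simulate one sample's per-bin unique-read counts (seeded)."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if np.all(np.isnan(grid.gc)):
        raise ValueError("grid has no GC annotation; use make_synthetic_grid "
                         "or annotate_gc first")
    copy = expected_copy_track(spec, grid)
    gc = np.where(np.isfinite(grid.gc), grid.gc, preset.gc_mean)
    slope = preset.gc_slope if spec.gc_slope is None else spec.gc_slope
    bias = np.exp(slope * (gc - preset.gc_mean))
    wave = amplification_wave(grid, preset, wave_sd=spec.wave_sd)
    lam = (copy / 2.0) * bias * wave * (grid.widths / grid.bin_size)
    lam[grid.masked] = 0.0

    lam_scale = spec.n_unique_reads / np.sum(lam)
    # lam_scale is the expected count of a diploid, bias-free, full-width bin
    mean_diploid = lam_scale
    if mean_diploid < 1.0:
        import warnings

        warnings.warn("expected count per bin < 1; grid too fine for depth")
    s = (preset.bin_noise_sd(mean_diploid) if spec.bin_noise_sd is None
         else spec.bin_noise_sd)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF,
                                                        zlib.crc32(spec.sample_id.encode())]))
    if s > 0:
        sigma = np.sqrt(np.log1p(s**2))
        lam = lam * rng.lognormal(-0.5 * sigma**2, sigma, grid.n_bins)
    counts = rng.poisson(lam * lam_scale)

    n_unique = int(counts.sum())
    dup_ratio = preset.dup_ratio if spec.dup_ratio is None else spec.dup_ratio
    n_dup = int(round(n_unique * dup_ratio / max(1e-9, 1.0 - dup_ratio)))
    n_total = int(round(n_unique / preset.unique_ratio))
    n_rest = max(0, n_total - n_unique - n_dup)
    n_unmapped = int(0.8 * n_rest)
    n_multi = n_rest - n_unmapped
    prof = CountProfile(
        sample_id=spec.sample_id,
        counts=counts.astype(np.int64),
        n_total_reads=n_unique + n_dup + n_unmapped + n_multi,
        n_unmapped=n_unmapped,
        n_multimapped=n_multi,
        n_duplicates=n_dup,
        n_unique_mapped=n_unique,
        n_other_filtered=0,
        read_length=preset.read_length,
        meta={"preset": preset.name, "seed": spec.seed,
              "mixing_proportion": spec.mixing_proportion},
    )
    prof.validate(grid)
    return prof


# -- the detection-limit experiment design -------------------------------

MB = 1_000_000


def _cnv(chrom: str, size_mb: float, copies: int,
         start_mb: float = 20.0) -> CnvEvent:
    return (chrom, int(start_mb * MB), int((start_mb + size_mb) * MB), copies)


def table2_design() -> list[dict]:
    """The mixing-experiment design: category, mixing proportion, size
    class and the event carried by each sample (one event per sample)."""
    rows: list[dict] = []

    def add(category, proportion, size_class, aneuploidies=(), cnvs=()):
        rows.append(dict(category=category, mixing_proportion=proportion,
                         size_class=size_class, aneuploidies=aneuploidies,
                         cnvs=cnvs))

    # pure aneuploidies
    add("aneuploidy", 1.0, None, aneuploidies=(("chr21", "trisomy"),))
    add("aneuploidy", 1.0, None, aneuploidies=(("chr16", "monosomy"),))
    # pure CNVs
    for chrom, size, cp in [("chr1", 2.2, 3), ("chr3", 2.6, 1),
                            ("chr4", 3.0, 3), ("chr6", 3.5, 1)]:
        add("cnv", 1.0, "<4", cnvs=(_cnv(chrom, size, cp),))
    add("cnv", 1.0, "4-10", cnvs=(_cnv("chr5", 6.0, 3),))
    add("cnv", 1.0, ">10", cnvs=(_cnv("chr2", 15.0, 1),))
    # 0.3 mixing CNVs
    add("mixing_cnv", 0.3, "<4", cnvs=(_cnv("chr7", 3.0, 3),))
    for chrom, size, cp in [("chr8", 5.0, 3), ("chr9", 7.0, 1),
                            ("chr10", 9.0, 3)]:
        add("mixing_cnv", 0.3, "4-10", cnvs=(_cnv(chrom, size, cp),))
    big03 = [("chr1", 12.0, 3), ("chr2", 14.0, 1), ("chr3", 16.0, 3),
             ("chr4", 18.0, 1), ("chr5", 20.0, 3), ("chr6", 24.0, 1),
             ("chr7", 28.0, 3), ("chr8", 32.0, 1), ("chr12", 36.0, 3)]
    for chrom, size, cp in big03:
        add("mixing_cnv", 0.3, ">10", cnvs=(_cnv(chrom, size, cp),))
    # 0.7 mixing CNVs
    for chrom, size, cp in [("chr11", 4.5, 3), ("chr12", 5.5, 1),
                            ("chr13", 6.5, 3), ("chr14", 8.0, 1),
                            ("chr15", 9.5, 3)]:
        add("mixing_cnv", 0.7, "4-10", cnvs=(_cnv(chrom, size, cp),))
    big07 = [("chr1", 11.0, 1), ("chr2", 13.0, 3), ("chr3", 15.0, 1),
             ("chr4", 18.0, 3), ("chr5", 22.0, 1), ("chr6", 26.0, 3),
             ("chr7", 30.0, 1), ("chr10", 34.0, 3)]
    for chrom, size, cp in big07:
        add("mixing_cnv", 0.7, ">10", cnvs=(_cnv(chrom, size, cp),))
    # mixing aneuploidies
    for chrom, kind in [("chr13", "trisomy"), ("chr18", "monosomy"),
                        ("chr21", "trisomy"), ("chr22", "monosomy")]:
        add("mixing_aneuploidy", 0.3, None, aneuploidies=((chrom, kind),))
    for chrom, kind in [("chr9", "trisomy"), ("chr6", "monosomy"),
                        ("chr15", "trisomy"), ("chr20", "monosomy")]:
        add("mixing_aneuploidy", 0.7, None, aneuploidies=((chrom, kind),))
    return rows


def simulate_table2_panel(seed: int, grid: BinGrid | None = None,
                          preset: NoisePreset | str = "sureplex",
                          n_controls: int = 16,
                          n_unique_reads: int | None = None):
    """Simulate the full detection-limit experiment plus euploid controls.

    Returns (profiles, truth): a list of CountProfile and a parallel dict
    sample_id -> truth record with category, mixing proportion, size class
    and the carried events.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if grid is None:
        grid = make_synthetic_grid(preset)
    if n_unique_reads is None:
        n_unique_reads = preset.n_unique_reads
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(1000) % (2**31)
    profiles: list[CountProfile] = []
    truth: dict[str, dict] = {}
    k = 0
    for i in range(n_controls):
        spec = SimSpec(sample_id=f"control_{i:02d}",
                       n_unique_reads=n_unique_reads, seed=int(child[k])); k += 1
        profiles.append(simulate_counts(spec, grid, preset))
        truth[spec.sample_id] = dict(category="control", mixing_proportion=None,
                                     size_class=None, aneuploidies=[], cnvs=[])
    for i, row in enumerate(table2_design()):
        spec = SimSpec(
            sample_id=f"{row['category']}_{i:02d}",
            aneuploidies=tuple(row["aneuploidies"]),
            cnvs=tuple(row["cnvs"]),
            mixing_proportion=row["mixing_proportion"],
            n_unique_reads=n_unique_reads, seed=int(child[k])); k += 1
        profiles.append(simulate_counts(spec, grid, preset))
        truth[spec.sample_id] = dict(
            category=row["category"],
            mixing_proportion=row["mixing_proportion"],
            size_class=row["size_class"],
            aneuploidies=[list(a) for a in row["aneuploidies"]],
            cnvs=[list(c) for c in row["cnvs"]],
        )
    return profiles, truth


def simulate_sam(profile: CountProfile, grid: BinGrid, path,
                 seed: int = 0) -> None:
    """Write a small SAM file realizing a count profile (uniform positions
    within bins, MAPQ 60).  A thin layer for exercising read counting;
    counts-level simulation is the primary path."""
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name in grid.chroms:
            fh.write(f"@SQ\tSN:{name}\tLN:{grid.chrom_sizes[name]}\n")
        rid = 0
        for name in grid.chroms:
            sl = grid.chrom_slice(name)
            for b in range(sl.start, sl.stop):
                n = int(profile.counts[b])
                if n == 0:
                    continue
                width = int(grid.end[b] - grid.start[b])
                pos = np.sort(rng.choice(width, size=min(n, width),
                                         replace=False)) + grid.start[b]
                for p in pos:
                    fh.write(f"r{rid}\t0\t{name}\t{p + 1}\t60\t10M\t*\t0\t0\t"
                             f"{'A' * 10}\t*\n")
                    rid += 1
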