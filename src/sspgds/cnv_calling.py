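"""Aneuploidy and segmental CNV calling, and the embryo decision.

Whole-chromosome gains/losses are called with a Z-score of the chromosome
mean ratio against a euploid reference panel (Z > 3 trisomy, Z < -3
monosomy).  Segmental events are found by circular binary segmentation
(CBS) on 500 kb superbin ratios, assigned a within-chromosome permutation
P value, and classified on the copy-number scale (diploid = 2): segment
mean < 1.4 is a microdeletion, > 2.6 a microduplication, and a
permutation-significant segment inside that band with an effect of at
least ``delta_min`` copies is reported as an intermediate (mosaic-range)
event.  An embryo is "implantable" when there is no aneuploidy call and no
detected CNV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .genome_bins import BinGrid, KARYOTYPE_ORDER
from .normalization import (
    RatioProfile,
    ReferencePanel,
    build_reference_panel,
    normalize_profile,
    raw_ratio,
)
from .read_counting import CountProfile

TRISOMY, MONOSOMY, DISOMY = "trisomy", "monosomy", "disomy"
MICRODELETION, MICRODUPLICATION = "microdeletion", "microduplication"
INTERMEDIATE, NEUTRAL = "intermediate", "neutral"


@dataclass
class ChromCall:
    chrom: str
    chrom_ratio: float
    z: float
    call: str  # trisomy / monosomy / disomy


@dataclass
class CnvCall:
    chrom: str
    start: int
    end: int
    n_bins: int
    mean_copy: float
    p_perm: float
    label: str
    detected: bool


@dataclass
class EmbryoReport:
    sample_id: str
    chrom_calls: list[ChromCall]
    cnv_calls: list[CnvCall]
    implantable: bool
    failed: bool = False  # > max allowed aneuploidies (assay failure)
    qc: dict = field(default_factory=dict)

    @property
    def positive(self) -> bool:
        """Any abnormality (aneuploidy or detected CNV)."""
        return not self.implantable

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "implantable": self.implantable,
            "failed": self.failed,
            "qc": self.qc,
            "chrom_calls": [asdict(c) for c in self.chrom_calls],
            "cnv_calls": [asdict(c) for c in self.cnv_calls],
        }


# -- aneuploidy ----------------------------------------------------------

def call_aneuploidy(profile: RatioProfile | np.ndarray, panel: ReferencePanel,
                    z_gain: float = 3.0, z_loss: float = -3.0,
                    min_chrom_sd: float = 0.035) -> list[ChromCall]:
    """Z-score each chromosome's mean ratio against the panel.

    ``min_chrom_sd`` (ratio units) floors the panel scale so a call always
    requires a minimum absolute deviation as well as statistical surprise;
    set it to 0 for the plain empirical-sd Z-score.
    """
    if getattr(panel, "n_controls_", 0) < 3:
        raise ValueError("panel needs >= 3 controls for Z-scoring")
    ratio = profile.ratio if isinstance(profile, RatioProfile) else np.asarray(profile)
    calls = []
    for name in panel.grid.chroms:
        sd = max(panel.per_chrom_sd_[name], min_chrom_sd)
        if sd < 1e-12:
            raise ValueError(f"degenerate panel: zero sd for {name}")
        cr = panel.chrom_mean(ratio, name)
        z = (cr - panel.per_chrom_mean_[name]) / sd
        call = TRISOMY if z > z_gain else MONOSOMY if z < z_loss else DISOMY
        calls.append(ChromCall(chrom=name, chrom_ratio=cr, z=float(z), call=call))
    return calls


# -- 500 kb accumulation -------------------------------------------------

def accumulate_to_superbins(profile: RatioProfile | np.ndarray, grid20: BinGrid,
                            grid500: BinGrid, min_children: int = 5):
    """Mean corrected ratio per 500 kb superbin.

    Superbins with fewer than ``min_children`` unmasked 20 kb children are
    masked.  Returns (values, mask) aligned with ``grid500``.
    """
    if grid500.bin_size % grid20.bin_size:
        raise ValueError("grids are not nested")
    factor = grid500.bin_size // grid20.bin_size
    parent = grid20.superbin_index(factor)
    if int(parent[-1]) + 1 != grid500.n_bins:
        raise ValueError("superbin grid does not aggregate the working grid")
    if isinstance(profile, RatioProfile):
        ratio, child_mask = profile.ratio, profile.mask
    else:
        ratio = np.asarray(profile, float)
        child_mask = ~np.isfinite(ratio)
    ok = ~child_mask & np.isfinite(ratio)
    num = np.zeros(grid500.n_bins)
    den = np.zeros(grid500.n_bins)
    np.add.at(num, parent[ok], ratio[ok])
    np.add.at(den, parent[ok], 1.0)
    mask = den < min_children
    with np.errstate(invalid="ignore"):
        values = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    values[mask] = np.nan
    return values, mask


# -- circular binary segmentation ---------------------------------------

def _max_t_arc(x: np.ndarray, min_width: int):
    """Best arc (i, j] by the two-sample t-like statistic between the arc
    and its complement.  Returns (i, j, |t|)."""
    n = x.size
    s = float(np.std(x, ddof=1))
    if s <= 0:
        return 0, n, 0.0
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    # arcs (i, j] with min_width <= k <= n - min_width
    i_idx, j_idx = np.triu_indices(n + 1, k=min_width)
    k = (j_idx - i_idx).astype(float)
    keep = k <= n - min_width
    i_idx, j_idx, k = i_idx[keep], j_idx[keep], k[keep]
    mean_in = (S[j_idx] - S[i_idx]) / k
    mean_out = (total - (S[j_idx] - S[i_idx])) / (n - k)
    t = np.abs(mean_in - mean_out) / (s * np.sqrt(1.0 / k + 1.0 / (n - k)))
    best = int(np.argmax(t))
    return int(i_idx[best]), int(j_idx[best]), float(t[best])


class CBSSegmenter(BaseEstimator):
    """Recursive circular binary segmentation of a ratio track.

    At each step the arc maximizing the two-sample t-like statistic between
    in-arc and out-of-arc bins is found; the split is accepted when the
    statistic exceeds a significance threshold, and the pieces are segmented
    recursively.  Adjacent segments whose means differ by less than
    ``delta_merge`` copies (0.5 ratio units per copy) are merged.

    ``split_method="analytic"`` (default) thresholds max |t| at the normal
    quantile Bonferroni-corrected over the number of candidate arcs, which
    controls the per-chromosome split false-positive rate at or below
    ``alpha_split``; ``"permutation"`` estimates the null of max |t| by
    shuffling the track (``n_split_perm`` permutations).
    """

    def __init__(self, alpha_split: float = 1e-4, min_width: int = 3,
                 delta_merge: float = 0.2, split_method: str = "analytic",
                 n_split_perm: int = 200, seed: int = 0):
        self.alpha_split = alpha_split
        self.min_width = min_width
        self.delta_merge = delta_merge
        self.split_method = split_method
        self.n_split_perm = n_split_perm
        self.seed = seed

    # breakpoints -------------------------------------------------------
    def _accept(self, x: np.ndarray, tmax: float, i: int, j: int,
                rng: np.random.Generator) -> bool:
        n = x.size
        if self.split_method == "analytic":
            n_arcs = max(1, ((n - 2 * self.min_width + 1)
                             * (n - 2 * self.min_width + 2)) // 2)
            thr = stats.norm.isf(self.alpha_split / (2.0 * n_arcs))
            return tmax > thr
        elif self.split_method == "permutation":
            null = np.empty(self.n_split_perm)
            for p in range(self.n_split_perm):
                null[p] = _max_t_arc(rng.permutation(x), self.min_width)[2]
            return tmax > np.quantile(null, 1.0 - self.alpha_split)
        raise ValueError(f"unknown split_method {self.split_method!r}")

    def segment(self, values: np.ndarray, seed: int | None = None):
        """Segment a 1-D track (no NaNs) into constant-mean pieces.

        Returns a list of (start, end) half-open index pairs partitioning
        the track.
        """
        x = np.asarray(values, float)
        if x.ndim != 1 or x.size == 0:
            raise ValueError("track must be a non-empty 1-D array")
        if np.any(~np.isfinite(x)):
            raise ValueError("track contains non-finite values")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        bounds: list[int] = [0, x.size]
        stack = [(0, x.size)]
        while stack:
            a, b = stack.pop()
            n = b - a
            if n < 2 * self.min_width:
                continue
            i, j, tmax = _max_t_arc(x[a:b], self.min_width)
            if not self._accept(x[a:b], tmax, i, j, rng):
                continue
            for cut in (a + i, a + j):
                if cut not in bounds:
                    bounds.append(cut)
            for lo, hi in ((a, a + i), (a + i, a + j), (a + j, b)):
                if hi - lo >= 2 * self.min_width:
                    stack.append((lo, hi))
        bounds = sorted(set(bounds))
        segs = list(zip(bounds[:-1], bounds[1:]))
        return self._merge(x, segs)

    def _merge(self, x: np.ndarray, segs):
        # delta_merge is in copy units; ratios differ by half as much
        thr = 0.5 * self.delta_merge
        merged = [list(segs[0])]
        for a, b in segs[1:]:
            pa, pb = merged[-1]
            if abs(x[a:b].mean() - x[pa:pb].mean()) < thr:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        return [(a, b) for a, b in merged]


def cbs_segment(super_values: np.ndarray, super_mask: np.ndarray,
                grid500: BinGrid, segmenter: CBSSegmenter | None = None,
                seed: int | None = None) -> dict[str, list[dict]]:
    """Segment each chromosome's unmasked 500 kb track.

    Returns {chrom: [segment dicts]} where each segment carries genomic
    coordinates (from its first/last unmasked superbin), the unmasked bin
    count, the mean ratio, and the compacted-track index range used for the
    permutation test.  A chromosome shorter than the minimum width yields a
    single segment flagged ``unsplittable``.
    """
    if segmenter is None:
        segmenter = CBSSegmenter()
    out: dict[str, list[dict]] = {}
    for name in grid500.chroms:
        sl = grid500.chrom_slice(name)
        idx = np.arange(sl.start, sl.stop)
        ok = ~super_mask[sl] & np.isfinite(super_values[sl])
        idx = idx[ok]
        if idx.size == 0:
            out[name] = []
            continue
        x = super_values[idx]
        if idx.size < 2 * segmenter.min_width:
            segs = [(0, idx.size)]
            unsplittable = True
        else:
            segs = segmenter.segment(x, seed=seed)
            unsplittable = False
        out[name] = [
            {
                "chrom": name,
                "start": int(grid500.start[idx[a]]),
                "end": int(grid500.end[idx[b - 1]]),
                "n_bins": b - a,
                "mean_ratio": float(x[a:b].mean()),
                "track_index": (a, b),
                "unsplittable": unsplittable,
            }
            for a, b in segs
        ]
    return out


def permutation_p(segment_index: tuple[int, int], track: np.ndarray,
                  n_perm: int = 10_000, seed: int = 0) -> float:
    """Permutation P for a candidate segment of a chromosome track.

    The statistic is the absolute deviation of the segment mean from the
    track mean; the null shuffles the (unmasked) superbin values within the
    chromosome and takes the best same-length contiguous window.  P uses
    the add-one estimator (1 + #extreme) / (n_perm + 1).
    """
    x = np.asarray(track, float)
    a, b = segment_index
    L = b - a
    n = x.size
    if L > n:
        raise ValueError("segment longer than track")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    track_mean = x.mean()
    observed = abs(x[a:b].mean() - track_mean)
    if L == n:
        return 1.0
    rng = np.random.default_rng(seed)
    # all permutations at once: rows are shuffled copies of the track
    perms = rng.permuted(np.broadcast_to(x, (n_perm, n)).copy(), axis=1)
    S = np.cumsum(perms, axis=1)
    S = np.concatenate([np.zeros((n_perm, 1)), S], axis=1)
    win = (S[:, L:] - S[:, :-L]) / L
    best = np.max(np.abs(win - track_mean), axis=1)
    return float((1 + np.sum(best >= observed - 1e-12)) / (n_perm + 1))


def classify_segments(segments: list[dict], alpha: float = 0.01,
                      del_thr: float = 1.4, dup_thr: float = 2.6,
                      delta_min: float = 0.25) -> list[CnvCall]:
    """Label segments on the copy-number scale and decide detection.

    ``segments`` are dicts as produced by :func:`cbs_segment`, each with a
    ``p_perm`` entry.  Detection requires permutation significance and a
    non-neutral label.
    """
    if not del_thr < 2 < dup_thr:
        raise ValueError("thresholds must satisfy del_thr < 2 < dup_thr")
    calls = []
    for seg in segments:
        mean_copy = 2.0 * seg["mean_ratio"]
        p = seg["p_perm"]
        if mean_copy < del_thr:
            label = MICRODELETION
        elif mean_copy > dup_thr:
            label = MICRODUPLICATION
        elif p < alpha and abs(mean_copy - 2.0) >= delta_min:
            label = INTERMEDIATE
        else:
            label = NEUTRAL
        calls.append(CnvCall(
            chrom=seg["chrom"], start=seg["start"], end=seg["end"],
            n_bins=seg["n_bins"], mean_copy=float(mean_copy), p_perm=float(p),
            label=label, detected=bool(p < alpha and label != NEUTRAL),
        ))
    return calls


def decide_implantable(chrom_calls: list[ChromCall], cnv_calls: list[CnvCall],
                       expected_chroms: tuple[str, ...] = KARYOTYPE_ORDER) -> bool:
    """True iff no trisomy/monosomy call and no detected CNV."""
    seen = {c.chrom for c in chrom_calls}
    missing = [c for c in expected_chroms if c not in seen]
    if missing:
        raise ValueError(f"missing chromosome calls: {missing}")
    any_aneu = any(c.call != DISOMY for c in chrom_calls)
    any_cnv = any(c.detected for c in cnv_calls)
    return not (any_aneu or any_cnv)


def arraycgh_like_call(median_log2: dict[str, float] | np.ndarray,
                       gain_thr: float = 0.3):
    """Array-CGH style comparator: per-chromosome median log2 ratio
    >= +0.3 is a gain, <= -0.3 a loss, otherwise neutral."""
    if isinstance(median_log2, dict):
        items = median_log2.items()
    else:
        arr = np.asarray(median_log2, float)
        items = zip(KARYOTYPE_ORDER[: arr.size], arr)
    out = {}
    for chrom, v in items:
        out[chrom] = "gain" if v >= gain_thr else "loss" if v <= -gain_thr else "neutral"
    return out


# -- full pipeline estimator --------------------------------------------

class EmbryoScreen(BaseEstimator):
    """End-to-end screen: fit a reference panel on euploid controls, then
    predict an :class:`EmbryoReport` per test sample.

    Parameters mirror the pipeline defaults: LOESS span 0.3, Z thresholds
    +/-3 with a 0.035 ratio-unit sd floor, CBS with min_width 3 superbins,
    permutation alpha 0.01 with 10,000 permutations, and the 1.4 / 2.6
    copy-number thresholds.
    """

    def __init__(self, grid: BinGrid, span: float = 0.3, t_loc: float = 0.5,
                 t_var_mult: float = 3.0, z_gain: float = 3.0,
                 z_loss: float = -3.0, min_chrom_sd: float = 0.035,
                 superbin_factor: int = 25, min_children: int = 5,
                 alpha_split: float = 1e-4, min_width: int = 3,
                 delta_merge: float = 0.2, n_perm: int = 10_000,
                 alpha: float = 0.01, del_thr: float = 1.4,
                 dup_thr: float = 2.6, delta_min: float = 0.25,
                 max_aneuploidies: int = 5, seed: int = 17):
        self.grid = grid
        self.span = span
        self.t_loc = t_loc
        self.t_var_mult = t_var_mult
        self.z_gain = z_gain
        self.z_loss = z_loss
        self.min_chrom_sd = min_chrom_sd
        self.superbin_factor = superbin_factor
        self.min_children = min_children
        self.alpha_split = alpha_split
        self.min_width = min_width
        self.delta_merge = delta_merge
        self.n_perm = n_perm
        self.alpha = alpha
        self.del_thr = del_thr
        self.dup_thr = dup_thr
        self.delta_min = delta_min
        self.max_aneuploidies = max_aneuploidies
        self.seed = seed

    # ------------------------------------------------------------------
    def fit(self, controls: list[CountProfile], y=None):
        """Build the reference panel from euploid control count profiles."""
        from .normalization import loess_gc_correct

        corrected = []
        for prof in controls:
            r = raw_ratio(prof, self.grid)
            corrected.append(loess_gc_correct(r, self.grid, span=self.span))
        self.panel_ = build_reference_panel(corrected, self.grid,
                                            t_loc=self.t_loc,
                                            t_var_mult=self.t_var_mult)
        self.grid500_ = self.grid.aggregate(self.superbin_factor)
        self.segmenter_ = CBSSegmenter(alpha_split=self.alpha_split,
                                       min_width=self.min_width,
                                       delta_merge=self.delta_merge,
                                       seed=self.seed)
        return self

    def _sample_seed(self, sample_id: str) -> int:
        import zlib

        return int(np.random.SeedSequence(
            [self.seed, zlib.crc32(sample_id.encode())]
        ).generate_state(1)[0] % (2**31))

    def predict(self, profile: CountProfile) -> EmbryoReport:
        """Run the full calling chain on one sample."""
        if not hasattr(self, "panel_"):
            raise RuntimeError("screen is not fitted")
        ratio = normalize_profile(profile, self.grid, panel=self.panel_,
                                  span=self.span)
        chrom_calls = call_aneuploidy(ratio, self.panel_, z_gain=self.z_gain,
                                      z_loss=self.z_loss,
                                      min_chrom_sd=self.min_chrom_sd)
        values, smask = accumulate_to_superbins(ratio, self.grid,
                                                self.grid500_,
                                                min_children=self.min_children)
        # anchor the segmentation track so the autosomal mean superbin is
        # exactly diploid (copy 2): the 1.4/2.6 thresholds and the minimum
        # mosaic effect are absolute copy numbers, so the scale must not
        # inherit the skew of the bin-level distribution
        use = ~smask & np.isfinite(values) & self.grid500_.is_autosome
        values = values / np.nanmean(values[use])
        sample_seed = self._sample_seed(profile.sample_id)
        segments = cbs_segment(values, smask, self.grid500_, self.segmenter_,
                               seed=sample_seed)
        cnv_calls: list[CnvCall] = []
        for chrom, segs in segments.items():
            if not segs:
                continue
            sl = self.grid500_.chrom_slice(chrom)
            ok = ~smask[sl] & np.isfinite(values[sl])
            track = values[sl][ok]
            for seg in segs:
                if len(segs) == 1:
                    seg["p_perm"] = 1.0
                else:
                    seg["p_perm"] = permutation_p(
                        seg["track_index"], track, n_perm=self.n_perm,
                        seed=sample_seed)
            cnv_calls.extend(classify_segments(
                segs, alpha=self.alpha, del_thr=self.del_thr,
                dup_thr=self.dup_thr, delta_min=self.delta_min))
        aneu = [c for c in chrom_calls if c.call != DISOMY]
        implantable = decide_implantable(chrom_calls, cnv_calls,
                                         expected_chroms=self.grid.chroms)
        from .qc_report import compute_qc

        qc = compute_qc(profile, self.grid, corrected_ratio=ratio.gc_corrected)
        return EmbryoReport(
            sample_id=profile.sample_id,
            chrom_calls=chrom_calls,
            cnv_calls=[c for c in cnv_calls if c.label != NEUTRAL],
            implantable=implantable,
            failed=len(aneu) > self.max_aneuploidies,
            qc=qc.to_dict(),
        )

    def predict_many(self, profiles: list[CountProfile]) -> list[EmbryoReport]:
        return [self.predict(p) for p in profiles]


def write_report(report: EmbryoReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


def write_segments_bed(report: EmbryoReport, path: str | Path) -> None:
    """Segments as BED6+3 (chrom, start, end, label, mean_copy, '.',
    n_bins, p_perm, detected)."""
    with open(path, "w") as fh:
        for c in report.cnv_calls:
            fh.write("\t".join(map(str, [
                c.chrom, c.start, c.end, c.label, round(c.mean_copy, 4), ".",
                c.n_bins, c.p_perm, int(c.detected)])) + "\n")
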