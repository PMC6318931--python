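"""Two-step bin-ratio normalization and the euploid reference panel.

A sample's per-bin counts are turned into ratios with diploid expectation
1.0 in three stages:

1. raw ratio — count density per bin divided by the mean density over
   unmasked autosomal bins (each sample is its own diploid baseline, so a
   genome-wide uniform ploidy change is invisible, as for read-depth
   methods generally);
2. LOESS GC correction — a locally weighted regression of ratio on GC
   fraction fitted on autosomal unmasked bins and divided out;
3. reference-panel normalization — division by the per-bin mean over a set
   of euploid control samples, which removes the reproducible component of
   the whole-genome-amplification bias, followed by outlier-bin masking.

The panel also stores per-chromosome location/scale statistics used by the
Z-score aneuploidy caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome_bins import BinGrid
from .read_counting import CountProfile

MIN_FIT_BINS = 100  # below this a LOESS fit is unreliable


@dataclass
class RatioProfile:
    """GC-corrected (and, when a panel is supplied, panel-normalized)
    per-bin ratios for one sample.

    ``ratio`` has diploid expectation 1.0 and is NaN on masked bins;
    ``gc_corrected`` keeps the sample-internal corrected ratios used for
    sequencing QC (the 1 Mb CV) before panel normalization.
    """

    sample_id: str
    ratio: np.ndarray
    mask: np.ndarray  # True = excluded
    gc_corrected: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def copy_number(self) -> np.ndarray:
        """Per-bin copy number on the diploid=2 scale."""
        return 2.0 * self.ratio


def raw_ratio(profile: CountProfile, grid: BinGrid,
              mask: np.ndarray | None = None) -> np.ndarray:
    """Per-bin reads ratio: count density / mean autosomal density.

    Counts are converted to density (per full-bin equivalent) so the short
    remainder bin at each chromosome end is on the same scale.  Multiplying
    all counts by a constant leaves the result unchanged.
    """
    profile.validate(grid)
    if mask is None:
        mask = grid.masked
    counts = profile.counts.astype(float)
    dens = counts * (grid.bin_size / grid.widths)
    use = ~mask & grid.is_autosome
    if not np.any(use):
        raise ValueError("all autosomal bins are masked")
    denom = dens[use].mean()
    if denom <= 0:
        raise ValueError("no reads in unmasked autosomal bins")
    return dens / denom


def loess_gc_correct(ratio: np.ndarray, grid: BinGrid, span: float = 0.3,
                     mask: np.ndarray | None = None,
                     max_fit_bins: int = 30_000) -> np.ndarray:
    """Divide out the GC-dependent trend of the bin ratios.

    A degree-1 LOESS curve f(gc) is fitted to (gc, ratio) over unmasked
    autosomal bins (subsampled evenly along the GC axis when there are more
    than ``max_fit_bins``) and the correction is
    ``ratio * median(ratio) / f(gc)``.  Sex chromosomes are corrected with
    the autosomal fit so their copy state cannot distort it.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if mask is None:
        mask = grid.masked
    gc = grid.gc
    fit_use = ~mask & grid.is_autosome & np.isfinite(gc) & np.isfinite(ratio)
    n_fit = int(fit_use.sum())
    if n_fit < MIN_FIT_BINS:
        raise ValueError(
            f"only {n_fit} usable autosomal bins with GC; need >= {MIN_FIT_BINS}"
        )
    x = gc[fit_use]
    y = ratio[fit_use]
    if n_fit > max_fit_bins:
        order = np.argsort(x, kind="stable")
        step = n_fit / max_fit_bins
        pick = order[(np.arange(max_fit_bins) * step).astype(int)]
        x, y = x[pick], y[pick]
    med = float(np.median(y))
    fitted = lowess(y, x, frac=span, it=1,
                    delta=0.005 * (x.max() - x.min()), return_sorted=True)
    fx, fy = fitted[:, 0], fitted[:, 1]
    f = np.interp(gc, fx, fy, left=fy[0], right=fy[-1])
    # guard against a vanishing fit in sparse GC tails
    floor = 0.05 * med if med > 0 else 1e-6
    f = np.maximum(f, floor)
    corrected = np.where(np.isfinite(gc), ratio * med / f, ratio)
    return corrected


def mask_outlier_bins(control_ratios: np.ndarray, grid: BinGrid,
                      t_loc: float = 0.5,
                      t_var_mult: float = 3.0) -> np.ndarray:
    """Mask bins that are systematically biased or unstable across controls.

    A bin is masked when the across-control median corrected ratio deviates
    from its chromosome's median level by more than ``t_loc`` (relative), or
    its across-control coefficient of variation exceeds ``t_var_mult`` times
    the median CV over all bins.  Judging location against the chromosome's
    own level keeps single-copy sex chromosomes of male controls usable
    while still catching bin-level WGA artifacts.  The result includes (is
    a superset of) the grid's structural mask.
    """
    X = np.asarray(control_ratios, float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 control profiles")
    if X.shape[1] != grid.n_bins:
        raise ValueError("control profiles do not match grid")
    med = np.nanmedian(X, axis=0)
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    rel = np.full(grid.n_bins, np.nan)
    for name in grid.chroms:
        sl = grid.chrom_slice(name)
        level = np.nanmedian(med[sl])
        if np.isfinite(level) and level > 0:
            rel[sl] = med[sl] / level
    bad_loc = ~np.isfinite(rel) | (np.abs(rel - 1.0) > t_loc)
    finite_cv = cv[np.isfinite(cv) & ~grid.masked]
    cv_thr = t_var_mult * np.median(finite_cv) if finite_cv.size else np.inf
    cv_thr = max(cv_thr, 0.05)  # a tiny CV is never evidence of instability
    bad_var = ~np.isfinite(cv) | (cv > cv_thr)
    return grid.masked | bad_loc | bad_var | (mean <= 0)


class ReferencePanel(BaseEstimator):
    """Per-bin and per-chromosome reference statistics over euploid controls.

    Parameters
    ----------
    grid : BinGrid
        The 20 kb working grid shared by all profiles.
    t_loc, t_var_mult : float
        Outlier-bin masking thresholds (see :func:`mask_outlier_bins`).

    Attributes (after :meth:`fit`)
    ------------------------------
    mask_ : boolean per bin, union of the structural and outlier masks.
    per_bin_mean_, per_bin_sd_ : across-control statistics of the corrected
        ratios (NaN on masked bins).
    per_chrom_mean_, per_chrom_sd_ : dict chrom -> statistics of the
        per-control chromosome-mean panel-normalized ratios.
    n_controls_ : number of control profiles.
    """

    def __init__(self, grid: BinGrid, t_loc: float = 0.5,
                 t_var_mult: float = 3.0):
        self.grid = grid
        self.t_loc = t_loc
        self.t_var_mult = t_var_mult

    def fit(self, X, y=None):
        """Fit the panel from corrected control ratios.

        ``X`` is (n_controls, n_bins); rows are GC-corrected (but not yet
        panel-normalized) ratio vectors.
        """
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[0] < 3:
            raise ValueError("need >= 3 control profiles to build a panel")
        if X.shape[1] != self.grid.n_bins:
            raise ValueError("control profiles do not match grid")
        self.n_controls_ = X.shape[0]
        self.mask_ = mask_outlier_bins(X, self.grid, self.t_loc, self.t_var_mult)
        mean = np.nanmean(X, axis=0)
        sd = np.nanstd(X, axis=0, ddof=1)
        mean[self.mask_] = np.nan
        sd[self.mask_] = np.nan
        self.per_bin_mean_ = mean
        self.per_bin_sd_ = sd
        # chromosome statistics on panel-normalized controls
        normed = np.stack([self.transform(row) for row in X])
        self.per_chrom_mean_ = {}
        self.per_chrom_sd_ = {}
        for name in self.grid.chroms:
            sl = self.grid.chrom_slice(name)
            vals = np.nanmean(normed[:, sl], axis=1)
            self.per_chrom_mean_[name] = float(np.mean(vals))
            self.per_chrom_sd_[name] = float(np.std(vals, ddof=1))
        return self

    def transform(self, ratio: np.ndarray) -> np.ndarray:
        """Panel-normalize one corrected ratio vector.

        Divides by the per-bin panel mean, rescales so the unmasked
        autosomal median is 1, and sets masked bins to NaN.
        """
        if not hasattr(self, "mask_"):
            raise RuntimeError("panel is not fitted")
        r = np.asarray(ratio, float).copy()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = r / self.per_bin_mean_
        r[self.mask_] = np.nan
        use = ~self.mask_ & self.grid.is_autosome & np.isfinite(r)
        med = np.nanmedian(r[use])
        if not np.isfinite(med) or med <= 0:
            raise ValueError("cannot rescale: no usable autosomal bins")
        return r / med

    def chrom_mean(self, ratio: np.ndarray, chrom: str) -> float:
        sl = self.grid.chrom_slice(chrom)
        return float(np.nanmean(ratio[sl]))


def build_reference_panel(controls, grid: BinGrid, t_loc: float = 0.5,
                          t_var_mult: float = 3.0) -> ReferencePanel:
    """Build a :class:`ReferencePanel` from control profiles.

    ``controls`` may be RatioProfile objects (their ``gc_corrected`` or
    ``ratio`` fields are used) or plain ratio vectors.
    """
    rows = []
    for c in controls:
        if isinstance(c, RatioProfile):
            rows.append(c.gc_corrected if c.gc_corrected is not None else c.ratio)
        else:
            rows.append(np.asarray(c, float))
    X = np.stack(rows)
    return ReferencePanel(grid, t_loc=t_loc, t_var_mult=t_var_mult).fit(X)


def normalize_profile(profile: CountProfile, grid: BinGrid,
                      panel: ReferencePanel | None = None,
                      span: float = 0.3) -> RatioProfile:
    """Full normalization chain for one sample: raw ratio, LOESS GC
    correction and (when a panel is given) panel normalization."""
    r = raw_ratio(profile, grid)
    corrected = loess_gc_correct(r, grid, span=span)
    if panel is None:
        mask = grid.masked.copy()
        final = corrected.copy()
        use = ~mask & grid.is_autosome
        final /= np.median(final[use])
        final[mask] = np.nan
    else:
        mask = panel.mask_.copy()
        final = panel.transform(corrected)
    return RatioProfile(sample_id=profile.sample_id, ratio=final, mask=mask,
                        gc_corrected=corrected)


# -- persistence ---------------------------------------------------------

def write_ratio_profile(profile: RatioProfile, path: str | Path) -> None:
    df = pd.DataFrame({
        "bin_id": np.arange(profile.ratio.size),
        "ratio": np.round(profile.ratio, 6),
        "copy_number": np.round(profile.copy_number, 6),
    })
    with open(path, "w") as fh:
        fh.write(f"#sample_id={profile.sample_id}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    """Persist a fitted panel as TSV plus a JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame({
        "bin_id": np.arange(panel.grid.n_bins),
        "mean": np.round(panel.per_bin_mean_, 6),
        "sd": np.round(panel.per_bin_sd_, 6),
        "masked": panel.mask_.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    sidecar = {
        "n_controls": panel.n_controls_,
        "t_loc": panel.t_loc,
        "t_var_mult": panel.t_var_mult,
        "bin_size": panel.grid.bin_size,
        "per_chrom_mean": panel.per_chrom_mean_,
        "per_chrom_sd": panel.per_chrom_sd_,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_panel(path: str | Path, grid: BinGrid) -> ReferencePanel:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values="NA")
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if len(df) != grid.n_bins:
        raise ValueError("panel does not match grid")
    panel = ReferencePanel(grid, t_loc=sidecar["t_loc"],
                           t_var_mult=sidecar["t_var_mult"])
    panel.n_controls_ = int(sidecar["n_controls"])
    panel.mask_ = df["masked"].to_numpy(dtype=bool)
    panel.per_bin_mean_ = df["mean"].to_numpy(dtype=float)
    panel.per_bin_sd_ = df["sd"].to_numpy(dtype=float)
    panel.per_chrom_mean_ = dict(sidecar["per_chrom_mean"])
    panel.per_chrom_sd_ = dict(sidecar["per_chrom_sd"])
    return panel
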