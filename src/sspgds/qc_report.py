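"""Sequencing QC statistics, detection-rate evaluation and concordance.

``compute_qc`` reproduces the per-sample quality panel used for low-pass
single-cell libraries: read-weighted GC content, the coefficient of
variation of 1 Mb-aggregated corrected ratios (the primary WGA noise
metric), duplicate fraction and theoretical genome coverage.
``evaluate_detection`` scores a set of reports against simulation truth in
the layout of the mixing experiment (category x proportion x size class),
and ``concordance`` reduces two report sets to positive/negative calls and
measures their agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cnv_calling import DISOMY, EmbryoReport
from .genome_bins import BIN_SIZE_1MB, BinGrid
from .read_counting import CountProfile, duplication_ratio

HG19_GENOME_SIZE = 3_095_677_412  # sum of the 24 screening chromosomes


@dataclass
class QCStats:
    gc_content: float
    cv_1mb: float
    duplication_ratio: float
    unique_mapped_reads: int
    theory_coverage: float
    actual_coverage: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def cv_1mb(ratio: np.ndarray, grid: BinGrid,
           mask: np.ndarray | None = None) -> float:
    """sd/mean of 1 Mb-aggregated ratios over unmasked autosomal bins."""
    factor = max(1, BIN_SIZE_1MB // grid.bin_size)
    parent = grid.superbin_index(factor)
    if mask is None:
        mask = grid.masked
    ok = ~mask & np.isfinite(ratio) & grid.is_autosome
    num = np.zeros(int(parent[-1]) + 1)
    den = np.zeros(num.size)
    np.add.at(num, parent[ok], ratio[ok])
    np.add.at(den, parent[ok], 1.0)
    full = den >= 0.5 * factor  # require a mostly covered 1 Mb bin
    agg = num[full] / den[full]
    if agg.size < 2:
        raise ValueError("too few 1 Mb bins for a CV")
    return float(np.std(agg) / np.mean(agg))


def compute_qc(profile: CountProfile, grid: BinGrid,
               corrected_ratio: np.ndarray | None = None,
               read_length: int | None = None,
               genome_size: int | None = None) -> QCStats:
    """Table-style QC for one sample.

    ``corrected_ratio`` are the sample-internal GC-corrected bin ratios;
    when omitted the CV is computed on raw count ratios.  Actual coverage
    requires alignment-level information and is omitted here.
    """
    if profile.n_unique_mapped <= 0:
        raise ValueError("empty profile")
    counts = profile.counts.astype(float)
    has_gc = np.isfinite(grid.gc)
    gc_content = float(np.sum(counts[has_gc] * grid.gc[has_gc])
                       / max(1.0, np.sum(counts[has_gc])))
    if corrected_ratio is None:
        from .normalization import raw_ratio

        corrected_ratio = raw_ratio(profile, grid)
    if read_length is None:
        read_length = profile.read_length or 150
    if genome_size is None:
        genome_size = sum(grid.chrom_sizes.values())
    return QCStats(
        gc_content=gc_content,
        cv_1mb=cv_1mb(corrected_ratio, grid),
        duplication_ratio=duplication_ratio(profile),
        unique_mapped_reads=profile.n_unique_mapped,
        theory_coverage=profile.n_unique_mapped * read_length / genome_size,
    )


# -- detection evaluation ------------------------------------------------

def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def _truth_detected(report: EmbryoReport, rec: dict,
                    min_reciprocal_overlap: float) -> bool:
    for chrom, kind in rec.get("aneuploidies", []):
        hit = any(c.chrom == chrom and c.call == kind
                  for c in report.chrom_calls)
        if not hit:
            return False
    for chrom, start, end, _copies in rec.get("cnvs", []):
        hit = any(
            c.chrom == chrom and c.detected and
            _reciprocal_overlap(c.start, c.end, start, end)
            >= min_reciprocal_overlap
            for c in report.cnv_calls)
        if not hit:
            return False
    return bool(rec.get("aneuploidies") or rec.get("cnvs"))


def evaluate_detection(reports: list[EmbryoReport], truth: dict[str, dict],
                       min_reciprocal_overlap: float = 0.5) -> pd.DataFrame:
    """Score reports against simulation truth.

    A truth event counts as detected when the report calls the same
    chromosome (and, for CNVs, a detected segment with at least the given
    reciprocal overlap).  Returns one row per (category, mixing proportion,
    size class) with detected/total, plus a ``false_positive`` row counting
    non-implantable euploid controls.
    """
    by_id = {r.sample_id: r for r in reports}
    missing = sorted(set(truth) - set(by_id))
    if missing:
        raise ValueError(f"reports missing for samples: {missing[:5]}")
    rows: dict[tuple, list[int]] = {}
    n_fp = 0
    n_controls = 0
    for sid, rec in truth.items():
        rep = by_id[sid]
        if rec["category"] == "control":
            n_controls += 1
            if not rep.implantable:
                n_fp += 1
            continue
        key = (rec["category"], rec["mixing_proportion"], rec["size_class"])
        d, t = rows.setdefault(key, [0, 0])
        rows[key][1] = t + 1
        if _truth_detected(rep, rec, min_reciprocal_overlap):
            rows[key][0] = d + 1
    records = [
        {"category": k[0], "mixing_proportion": k[1], "size_class": k[2],
         "detected": v[0], "total": v[1]}
        for k, v in sorted(rows.items(), key=lambda kv: str(kv[0]))
    ]
    records.append({"category": "false_positive", "mixing_proportion": None,
                    "size_class": None, "detected": n_fp, "total": n_controls})
    return pd.DataFrame(records)


def concordance(reports_a: list[EmbryoReport], reports_b: list[EmbryoReport]):
    """Positive/negative agreement between two report sets.

    Each report reduces to positive (any abnormality) or negative; returns
    (agreement fraction, list of discordant sample ids).  Symmetric in its
    arguments.
    """
    a = {r.sample_id: r.positive for r in reports_a}
    b = {r.sample_id: r.positive for r in reports_b}
    if set(a) != set(b):
        raise ValueError("report sets cover different samples")
    if not a:
        raise ValueError("empty report sets")
    discordant = sorted(sid for sid in a if a[sid] != b[sid])
    return 1.0 - len(discordant) / len(a), discordant
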