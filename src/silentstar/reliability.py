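"""Test-retest reliability: ICC(3,1) maps and intermodality comparisons.

The intra-class correlation ICC(3,1) (Shrout & Fleiss, consistency form)
is computed from the two-way mean squares of a subjects x sessions table:

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) EMS)

with BMS the between-subject mean square, EMS the residual mean square
after removing subject and session main effects, and k the number of
sessions.  ICC = 1 when every subject is perfectly consistent across
sessions (EMS = 0 with subject differences present); with k = 2 and no
between-subject variance the index reaches -1.  The intra-voxel variant
(ICC_v) applies the same decomposition with voxels of an ROI as rows and
sessions as columns, yielding one scalar per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ICCMap",
    "icc31",
    "icc31_map",
    "network_mask",
    "median_icc",
    "intravoxel_icc",
    "paired_compare",
    "spearman",
    "wilcoxon_exact",
]


@dataclass
class ICCMap:
    icc: np.ndarray
    bms: np.ndarray
    ems: np.ndarray
    k: int
    mask: np.ndarray


def _two_way_mean_squares(data: np.ndarray):
    """BMS and EMS of a (rows, columns, ...) table per trailing cell.

    rows = subjects (targets), columns = sessions (raters).  EMS is the
    residual (interaction) mean square after removing row and column main
    effects.
    """
    n, k = data.shape[0], data.shape[1]
    grand = data.mean(axis=(0, 1))
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = np.sum((data - grand) ** 2, axis=(0, 1))
    ss_rows = k * np.sum((row_means - grand) ** 2, axis=0)
    ss_cols = n * np.sum((col_means - grand) ** 2, axis=0)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    # numerical floor: tiny negative residual SS from cancellation
    ems = np.maximum(ems, 0.0)
    return bms, ems


def icc31(table: np.ndarray) -> float:
    """ICC(3,1) of a single (subjects, sessions) table."""
    m = icc31_map(table[:, :, None])
    return float(m.icc[0]) if m.mask[0] else float("nan")


def icc31_map(maps: np.ndarray, mask: np.ndarray | None = None) -> ICCMap:
    """Voxel-wise ICC(3,1) with BMS and EMS maps.

    ``maps`` is (subjects, sessions, ...spatial); all subject x session
    cells must be present.  Degenerate voxels (zero denominator) are
    masked out and set NaN.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim < 3:
        raise ValueError("maps must be (subjects, sessions, voxels...)")
    n, k = maps.shape[0], maps.shape[1]
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 sessions")
    if np.isnan(maps).any():
        raise ValueError("missing cells in the subject x session table")
    bms, ems = _two_way_mean_squares(maps)
    denom = bms + (k - 1) * ems
    ok = denom > 0
    if mask is not None:
        ok = ok & mask
    icc = np.full(bms.shape, np.nan)
    icc[ok] = (bms[ok] - ems[ok]) / denom[ok]
    return ICCMap(icc=icc, bms=bms, ems=ems, k=k, mask=ok)


def network_mask(
    session1_group_tmap: np.ndarray,
    gm_mask: np.ndarray,
    t_threshold: float = 1.0,
) -> np.ndarray:
    """Task-related network mask: grey matter AND session-1 group T > threshold.

    A deliberately low threshold keeps the mask comparable across
    modalities with different T-score amplitudes.
    """
    if session1_group_tmap.shape != gm_mask.shape:
        raise ValueError("T map and grey-matter mask must share a grid")
    t = np.nan_to_num(session1_group_tmap, nan=-np.inf)
    return np.asarray(gm_mask, bool) & (t > t_threshold)


def median_icc(iccmap: ICCMap, mask: np.ndarray) -> float:
    """Median ICC over the masked voxels."""
    sel = np.asarray(mask, bool) & iccmap.mask
    vals = iccmap.icc[sel]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(np.median(vals))


def intravoxel_icc(subject_maps: np.ndarray, roi: np.ndarray) -> float:
    """Intra-voxel reliability ICC_v for one subject.

    ``subject_maps`` is (sessions, ...spatial): the subject's contrast map
    per session.  The two-way decomposition is applied with ROI voxels as
    rows and sessions as columns.  Consistency form: adding a per-session
    constant or rescaling both sessions by a common positive factor leaves
    ICC_v unchanged.  Returns NaN when the ROI values carry no voxel
    variance.
    """
    subject_maps = np.asarray(subject_maps, dtype=float)
    roi = np.asarray(roi, bool)
    if roi.sum() < 10:
        raise ValueError("ROI must contain >= 10 voxels")
    if subject_maps.shape[0] < 2:
        raise ValueError("need >= 2 sessions")
    table = np.stack([m[roi] for m in subject_maps], axis=1)  # (voxels, sessions)
    bms, ems = _two_way_mean_squares(table[:, :, None])
    k = table.shape[1]
    denom = float(bms[0] + (k - 1) * ems[0])
    if denom <= 0:
        return float("nan")
    return float((bms[0] - ems[0]) / denom)


def wilcoxon_exact(diffs: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Wilcoxon signed-rank test by full enumeration.

    Zero differences are discarded; |differences| are midranked.  The
    null distribution of W+ is enumerated over all 2^n sign assignments
    (as a polynomial product, equivalent to full enumeration) and the
    two-sided p is min(1, 2 P(W+ <= min(W+, W-))).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))  # midranks
    w_plus = float(np.sum(ranks[d > 0]))
    w_minus = float(np.sum(ranks[d < 0]))
    w_min = min(w_plus, w_minus)
    # enumerate: distribution over doubled-integer rank sums
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    cdf = counts.cumsum() / 2.0**n
    idx = int(np.floor(round(2 * w_min, 6)))
    p = min(1.0, 2.0 * cdf[idx])
    return w_min, p


def paired_compare(
    values_a, values_b, method: str = "wilcoxon_signed_rank"
) -> tuple[float, float]:
    """Paired two-sided comparison between modalities.

    ``wilcoxon_signed_rank``: exact enumeration null for n <= 15
    (non-zero pairs), normal approximation otherwise.  ``paired_t``:
    standard paired t test.  All-zero differences are degenerate and
    reported as p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired samples of equal length >= 5")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if method == "paired_t":
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    if method != "wilcoxon_signed_rank":
        raise ValueError(f"unknown method {method!r}")
    nz = np.count_nonzero(d)
    if nz <= 15:
        return wilcoxon_exact(d)
    res = stats.wilcoxon(d, correction=True, method="approx")
    return float(res.statistic), float(res.pvalue)


def spearman(values_a, values_b) -> float:
    """Spearman rank correlation (Pearson on midranks)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 5:
        raise ValueError("need paired samples of equal length >= 5")
    return float(stats.spearmanr(a, b).statistic)
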