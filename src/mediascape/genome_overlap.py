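"""Summit-based colocalization of ChIP-seq factors and site categorization.

For each factor the most significant binding sites are retained (top 5000 by
default); two sites colocalize when their summits lie within 200 bp on the
same chromosome. Sites are split into promoter (TSS), super-enhancer, typical
enhancer and other non-TSS categories by summit position, and overlap
percentages can be recomputed per category.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, Peak, TssRecord

__all__ = [
    "CATEGORIES",
    "top_n_by_score",
    "summit_overlap_percent",
    "categorize_sites",
    "overlap_matrix",
]

CATEGORIES = ("TSS", "SE", "typical_enhancer", "other_nonTSS")


def top_n_by_score(peaks: Sequence[Peak], n: int = 5000) -> List[Peak]:
    """The n most significant peaks (score descending, coordinate-ascending
    tie-break). Returns everything, with a warning, if fewer are available."""
    if n <= 0:
        raise ValueError("n must be > 0")
    ordered = sorted(
        peaks,
        key=lambda p: (-p.score, p.interval.chrom, p.interval.start, p.interval.end),
    )
    if len(ordered) < n:
        warnings.warn(f"only {len(ordered)} peaks available for top {n}")
        return ordered
    return ordered[:n]


def _summits_by_chrom(peaks: Sequence[Peak]) -> Dict[str, np.ndarray]:
    by_chrom: Dict[str, List[int]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p.summit)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}


def summit_overlap_percent(
    a_peaks: Sequence[Peak], b_peaks: Sequence[Peak], window: int = 200
) -> float:
    """Percentage of A peaks with at least one B summit within `window` bp.

    Each A peak is counted once. Uses a sorted binary-search sweep
    (O(n log n)); equivalent to the all-pairs scan.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not a_peaks:
        raise ValueError("A peak set is empty")
    b_summits = _summits_by_chrom(b_peaks)
    hits = 0
    for p in a_peaks:
        summits = b_summits.get(p.chrom)
        if summits is None:
            continue
        lo = np.searchsorted(summits, p.summit - window, side="left")
        hi = np.searchsorted(summits, p.summit + window, side="right")
        if hi > lo:
            hits += 1
    return 100.0 * hits / len(a_peaks)


def categorize_sites(
    peaks: Sequence[Peak],
    tss_records: Sequence[TssRecord],
    typical_enhancers: Sequence[GenomicInterval] = (),
    se_regions: Sequence[GenomicInterval] = (),
    promoter_halfwidth: int = 1500,
) -> Dict[str, List[Peak]]:
    """Partition peaks into TSS / SE / typical_enhancer / other_nonTSS.

    Membership is decided by the summit position; a summit within
    `promoter_halfwidth` bp of a TSS is a promoter site regardless of
    enhancer overlap (priority TSS > SE > typical enhancer > other).
    """
    tss_pos: Dict[str, np.ndarray] = {}
    for t in tss_records:
        tss_pos.setdefault(t.chrom, []).append(t.pos)  # type: ignore[arg-type]
    tss_pos = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tss_pos.items()}

    def tree(regions: Sequence[GenomicInterval]) -> Dict[str, IntervalTree]:
        trees: Dict[str, IntervalTree] = {}
        for r in regions:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
        return trees

    se_trees = tree(se_regions)
    te_trees = tree(typical_enhancers)
    out: Dict[str, List[Peak]] = {c: [] for c in CATEGORIES}
    for p in peaks:
        pos = tss_pos.get(p.chrom)
        near_tss = False
        if pos is not None and len(pos):
            lo = np.searchsorted(pos, p.summit - promoter_halfwidth, side="left")
            hi = np.searchsorted(pos, p.summit + promoter_halfwidth, side="right")
            near_tss = hi > lo
        if near_tss:
            out["TSS"].append(p)
        elif p.chrom in se_trees and se_trees[p.chrom].overlaps(p.summit):
            out["SE"].append(p)
        elif p.chrom in te_trees and te_trees[p.chrom].overlaps(p.summit):
            out["typical_enhancer"].append(p)
        else:
            out["other_nonTSS"].append(p)
    return out


def overlap_matrix(
    factor_peaks: Mapping[str, Sequence[Peak]], window: int = 200
) -> pd.DataFrame:
    """Ordered-pair summit-overlap percentages between factors.

    Entry (A, B) is the percentage of A peaks with a B summit within the
    window; the matrix is not symmetric when set sizes differ.
    """
    names = list(factor_peaks)
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            mat.loc[a, b] = summit_overlap_percent(
                factor_peaks[a], factor_peaks[b], window
            )
    return mat
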