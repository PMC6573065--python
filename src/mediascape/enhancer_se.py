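"""Enhancer definition and ROSE-style super-enhancer calling.

Constituent enhancers are Ep300 peaks that overlap an H3K27ac region.
Elements within 1 kb of a TSS are discarded, the remainder are stitched when
their inner gap is at most 12.5 kb, stitched regions are ranked by their total
Med1 (Mediator) ChIP signal, and the hockey-stick cutoff — the point where a
line of slope 1 is tangent to the scaled rank/signal curve — separates super
enhancers (SEs) from typical enhancers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, Peak, SignalTrack, TssRecord

__all__ = [
    "Enhancer",
    "StitchedEnhancer",
    "SECallResult",
    "define_enhancers",
    "exclude_tss_overlapping",
    "stitch_enhancers",
    "quantify_region_signal",
    "call_se_cutoff",
    "hockey_curve",
    "se_table",
]


@dataclass(frozen=True)
class Enhancer:
    """A constituent enhancer (an Ep300 peak supported by H3K27ac)."""

    interval: GenomicInterval
    id: str
    source_peak_ids: Tuple[str, ...] = ()


@dataclass(frozen=True)
class StitchedEnhancer:
    """A stitched enhancer region spanning its constituents."""

    interval: GenomicInterval
    constituent_ids: Tuple[str, ...]
    total_signal: float = 0.0

    def with_signal(self, signal: float) -> "StitchedEnhancer":
        return StitchedEnhancer(self.interval, self.constituent_ids, signal)


@dataclass
class SECallResult:
    """Stitched regions sorted by ascending signal, with SE/typical labels."""

    regions: List[StitchedEnhancer]  # ascending total_signal
    is_se: np.ndarray  # bool per region, aligned with `regions`
    cutoff_signal: float
    cutoff_index: int

    @property
    def n_se(self) -> int:
        return int(self.is_se.sum())

    @property
    def n_typical(self) -> int:
        return len(self.regions) - self.n_se


def _tree_per_chrom(intervals: Iterable[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def define_enhancers(
    ep300: Sequence[Peak], h3k27ac: Sequence[GenomicInterval]
) -> List[Enhancer]:
    """Keep every Ep300 peak with >= 1 bp overlap with any H3K27ac region.

    The enhancer footprint is the Ep300 peak interval itself (the punctate
    regulatory element), not the intersection segment.
    """
    trees = _tree_per_chrom(h3k27ac)
    kept: List[Enhancer] = []
    ordered = sorted(
        ep300, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.name)
    )
    for peak in ordered:
        tree = trees.get(peak.interval.chrom)
        if tree is not None and tree.overlaps(peak.interval.start, peak.interval.end):
            kept.append(
                Enhancer(
                    interval=peak.interval,
                    id=f"enh_{len(kept):05d}",
                    source_peak_ids=(peak.name,),
                )
            )
    return kept


def exclude_tss_overlapping(
    enhancers: Sequence[Enhancer],
    tss_records: Sequence[TssRecord],
    window: int = 1000,
) -> List[Enhancer]:
    """Remove enhancers overlapping [pos - window, pos + window) of any TSS."""
    if window <= 0:
        raise ValueError("window must be > 0")
    trees: Dict[str, IntervalTree] = {}
    for tss in tss_records:
        trees.setdefault(tss.chrom, IntervalTree()).addi(
            max(0, tss.pos - window), tss.pos + window
        )
    return [
        e
        for e in enhancers
        if e.interval.chrom not in trees
        or not trees[e.interval.chrom].overlaps(e.interval.start, e.interval.end)
    ]


def stitch_enhancers(
    enhancers: Sequence[Enhancer], max_gap: int = 12500
) -> List[StitchedEnhancer]:
    """Merge enhancers whose inner gap (next.start - running end) <= max_gap.

    Transitive closure per chromosome; singletons pass through unchanged.
    """
    by_chrom: Dict[str, List[Enhancer]] = {}
    for e in enhancers:
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    out: List[StitchedEnhancer] = []
    for chrom in sorted(by_chrom):
        elems = sorted(by_chrom[chrom], key=lambda e: (e.interval.start, e.interval.end))
        cluster: List[Enhancer] = []
        cluster_end = -1
        for e in elems:
            if cluster and e.interval.start - cluster_end > max_gap:
                out.append(_make_stitched(chrom, cluster, cluster_end))
                cluster = []
                cluster_end = -1
            cluster.append(e)
            cluster_end = max(cluster_end, e.interval.end)
        if cluster:
            out.append(_make_stitched(chrom, cluster, cluster_end))
    return out


def _make_stitched(chrom: str, cluster: List[Enhancer], end: int) -> StitchedEnhancer:
    return StitchedEnhancer(
        interval=GenomicInterval(chrom, cluster[0].interval.start, end),
        constituent_ids=tuple(e.id for e in cluster),
    )


def quantify_region_signal(
    region: GenomicInterval,
    chip: SignalTrack,
    background: Optional[SignalTrack] = None,
) -> float:
    """Total ChIP signal (read-bases) over a region, optionally floored
    background-subtracted."""
    total = chip.region_sum(region.chrom, region.start, region.end)
    if background is not None:
        total = max(0.0, total - background.region_sum(region.chrom, region.start, region.end))
    return total


def call_se_cutoff(stitched: Sequence[StitchedEnhancer]) -> SECallResult:
    """Label stitched enhancers as super or typical via the hockey-stick cutoff.

    Regions are sorted by ascending total signal; rank is scaled to [0, 1] as
    i/(n-1) and signal to [0, 1] as (y - y_min)/(y_max - y_min). The cutoff is
    the tangent point of a slope-1 line with the scaled curve, located as the
    index minimizing y_scaled - x_scaled (ties resolved to the last index,
    i.e. the fewest SEs). Regions with signal strictly above the cutoff signal
    are SEs, so labels are invariant to rescaling all signals by a positive
    constant. If all signals are equal the curve is degenerate and no region
    is labelled SE.
    """
    if len(stitched) < 3:
        raise ValueError("need at least 3 stitched regions to place a cutoff")
    regions = sorted(
        stitched,
        key=lambda s: (s.total_signal, s.interval.chrom, s.interval.start, s.interval.end),
    )
    y = np.array([s.total_signal for s in regions], dtype=float)
    n = len(y)
    if y[0] == y[-1]:
        warnings.warn("all region signals equal; no super enhancers called")
        return SECallResult(regions, np.zeros(n, dtype=bool), float(y[-1]), n - 1)
    x_scaled = np.arange(n) / (n - 1)
    y_scaled = (y - y[0]) / (y[-1] - y[0])
    diff = y_scaled - x_scaled
    # last argmin: the most conservative tangent point
    cutoff_index = int(n - 1 - np.argmin(diff[::-1]))
    cutoff_signal = float(y[cutoff_index])
    is_se = y > cutoff_signal
    return SECallResult(regions, is_se, cutoff_signal, cutoff_index)


def hockey_curve(result: SECallResult) -> pd.DataFrame:
    """Rank/signal coordinates of the hockey-stick plot (ascending rank)."""
    n = len(result.regions)
    return pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "total_signal": [s.total_signal for s in result.regions],
            "is_se": result.is_se,
        }
    )


def se_table(result: SECallResult) -> pd.DataFrame:
    """Stitched regions with label, signal and descending-signal SE rank."""
    rows = []
    n = len(result.regions)
    for i, (region, se) in enumerate(zip(result.regions, result.is_se)):
        rows.append(
            {
                "chrom": region.interval.chrom,
                "start": region.interval.start,
                "end": region.interval.end,
                "n_constituents": len(region.constituent_ids),
                "constituents": ";".join(region.constituent_ids),
                "total_signal": region.total_signal,
                "rank_desc": n - i,
                "label": "SE" if se else "typical",
            }
        )
    return pd.DataFrame(rows)
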