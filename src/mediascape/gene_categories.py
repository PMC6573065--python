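"""Promoter breadth, enhancer-to-gene assignment and the gene-category partition.

Active genes (mean RPKM above threshold) are linked to enhancers as the
nearest active gene per region. Promoters whose H3K4me3 domain width falls in
the top fraction (default 5%) of genes with a domain are "broad". Crossing the
two axes partitions active genes into SE+Broad, SE-Broad (SE without broad
promoter), Broad-SE (broad promoter without SE) and Typical (nearest to a
typical enhancer only), plus Top-100 subsets per category.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, TssRecord

__all__ = [
    "PromoterDomainAssignment",
    "Top100Sets",
    "promoter_domain_width",
    "broad_promoter_set",
    "active_gene_set",
    "mean_rpkm",
    "nearest_active_gene",
    "nearest_gene_per_region",
    "assign_gene_categories",
    "top100_sets",
]

CATEGORY_NAMES = ("SE+Broad", "SE-Broad", "Broad-SE", "Typical")


@dataclass(frozen=True)
class PromoterDomainAssignment:
    gene_id: str
    h3k4me3_width: int  # 0 when no domain covers the TSS
    is_broad: bool = False


@dataclass(frozen=True)
class Top100Sets:
    top100_se_broad: Tuple[str, ...]
    top100_se_no_broad: Tuple[str, ...]
    top100_broad_no_se: Tuple[str, ...]


def promoter_domain_width(
    domains: Sequence[GenomicInterval], tss_records: Sequence[TssRecord]
) -> Dict[str, int]:
    """Width of the widest H3K4me3 domain covering each gene's TSS base (0 if none)."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for d in domains:
        by_chrom.setdefault(d.chrom, []).append(d)
    widths: Dict[str, int] = {}
    for tss in tss_records:
        best = 0
        for d in by_chrom.get(tss.chrom, ()):
            if d.start <= tss.pos < d.end and d.width > best:
                best = d.width
        widths[tss.gene_id] = best
    return widths


def broad_promoter_set(
    widths: Mapping[str, int], top_frac: float = 0.05
) -> Set[str]:
    """Genes in the top `top_frac` of H3K4me3 domain widths.

    Among the n genes with a nonzero domain, the threshold is the
    ceil(top_frac * n)-th largest width; ties at the threshold are all
    included.
    """
    if not (0 < top_frac < 1):
        raise ValueError("top_frac must be in (0, 1)")
    nonzero = {g: w for g, w in widths.items() if w > 0}
    if not nonzero:
        raise ValueError("no genes with a nonzero H3K4me3 domain width")
    k = math.ceil(top_frac * len(nonzero))
    threshold = sorted(nonzero.values(), reverse=True)[k - 1]
    return {g for g, w in nonzero.items() if w >= threshold}


def mean_rpkm(expression: pd.DataFrame) -> pd.Series:
    """Mean RPKM per gene over replicate columns; all-missing rows are dropped
    with a warning."""
    rep_cols = [c for c in expression.columns if c.startswith("rpkm_rep")]
    means = expression[rep_cols].mean(axis=1)
    empty = means.isna()
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} genes have no expression measurements; excluded"
        )
    out = pd.Series(means[~empty].values, index=expression.loc[~empty, "gene_id"])
    return out


def active_gene_set(expression: pd.DataFrame, min_rpkm: float = 0.5) -> Set[str]:
    """Genes with mean RPKM strictly above the activity threshold."""
    means = mean_rpkm(expression)
    return set(means.index[means > min_rpkm])


def nearest_active_gene(
    region: GenomicInterval, tss_records: Sequence[TssRecord]
) -> Tuple[Optional[str], Optional[int]]:
    """Nearest gene to a region, by edge-to-TSS distance on the same chromosome.

    Distance is 0 when the TSS lies inside the region, otherwise
    min(|tss - start|, |tss - (end-1)|). Ties go to the lexicographically
    smaller gene id; (None, None) when no gene shares the chromosome.
    """
    best: Tuple[int, str] | None = None
    for tss in tss_records:
        if tss.chrom != region.chrom:
            continue
        if region.start <= tss.pos < region.end:
            dist = 0
        else:
            dist = min(abs(tss.pos - region.start), abs(tss.pos - (region.end - 1)))
        cand = (dist, tss.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None, None
    return best[1], best[0]


def nearest_gene_per_region(
    regions: Sequence[GenomicInterval], tss_records: Sequence[TssRecord]
) -> List[Optional[str]]:
    """Vector of nearest-gene assignments, order-aligned with `regions`."""
    by_chrom: Dict[str, List[TssRecord]] = {}
    for t in tss_records:
        by_chrom.setdefault(t.chrom, []).append(t)
    return [
        nearest_active_gene(r, by_chrom.get(r.chrom, ()))[0] for r in regions
    ]


def assign_gene_categories(
    active_genes: Set[str],
    se_genes: Set[str],
    typical_genes: Set[str],
    broad_genes: Set[str],
) -> pd.DataFrame:
    """Partition active genes into SE+Broad / SE-Broad / Broad-SE / Typical.

    Genes nearest to an SE split by promoter breadth; broad genes without an
    SE form Broad-SE; typical-enhancer genes that are neither SE nor broad
    form Typical; remaining active genes get category 'none'.
    """
    for name, s in (("se", se_genes), ("typical", typical_genes), ("broad", broad_genes)):
        extra = s - active_genes
        if extra:
            raise ValueError(f"{name} gene set contains inactive genes: {sorted(extra)[:5]}")
    rows = []
    for gene in sorted(active_genes):
        se, broad, typ = gene in se_genes, gene in broad_genes, gene in typical_genes
        if se and broad:
            cat = "SE+Broad"
        elif se:
            cat = "SE-Broad"
        elif broad:
            cat = "Broad-SE"
        elif typ:
            cat = "Typical"
        else:
            cat = "none"
        rows.append(
            {
                "gene_id": gene,
                "is_active": True,
                "is_se_gene": se,
                "is_typical_gene": typ,
                "is_broad": broad,
                "category": cat,
            }
        )
    return pd.DataFrame(rows)


def top100_sets(
    se_ranked_genes: Sequence[Tuple[str, float, Optional[str]]],
    broad_genes: Set[str],
    widths: Mapping[str, int],
    categories: pd.DataFrame,
    n: int = 100,
) -> Top100Sets:
    """Top-n gene lists per category.

    `se_ranked_genes` carries (se_id, total_signal, nearest_gene) triples.
    SEs are walked in descending Mediator signal collecting one gene per SE —
    into the SE+Broad list when the gene has a broad promoter, otherwise the
    SE-Broad list — skipping duplicates, until each list has n genes or SEs
    run out. The Broad-SE list is the n widest-promoter genes among Broad-SE
    category genes.
    """
    ranked = sorted(se_ranked_genes, key=lambda t: (-t[1], t[0]))
    se_broad: List[str] = []
    se_no_broad: List[str] = []
    seen: Set[str] = set()
    for _se_id, _signal, gene in ranked:
        if gene is None or gene in seen:
            continue
        if gene in broad_genes:
            if len(se_broad) < n:
                se_broad.append(gene)
                seen.add(gene)
        else:
            if len(se_no_broad) < n:
                se_no_broad.append(gene)
                seen.add(gene)
        if len(se_broad) >= n and len(se_no_broad) >= n:
            break
    broad_no_se_genes = categories.loc[
        categories["category"] == "Broad-SE", "gene_id"
    ].tolist()
    broad_no_se = sorted(
        broad_no_se_genes, key=lambda g: (-widths.get(g, 0), g)
    )[:n]
    return Top100Sets(tuple(se_broad), tuple(se_no_broad), tuple(broad_no_se))
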