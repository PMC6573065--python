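"""Strand-aware TSS metaprofiles and per-category expression / knockdown stats.

The metaprofile averages tag-normalized ChIP coverage in fixed bins around a
set of TSSs (minus-strand windows are reversed before averaging, so "down-
stream" always means into the gene body). Category summaries compare mRNA
levels and knockdown responses (mean log2 fold change, fraction of
significantly downregulated genes) between gene categories, with pairwise
Student t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SignalTrack, TssRecord
from .gene_categories import mean_rpkm

__all__ = [
    "MetaProfile",
    "tss_metaprofile",
    "category_expression_summary",
    "pairwise_student_t",
    "kd_category_response",
]


@dataclass
class MetaProfile:
    """Binned mean ChIP density around a TSS set.

    `density` has 2*flank/bin_size entries in units of coverage per bp per
    region, scaled to a 10-million-tag library.
    """

    bin_size: int
    flank: int
    density: np.ndarray
    n_regions: int

    @property
    def bin_centers(self) -> np.ndarray:
        edges = np.arange(-self.flank, self.flank + 1, self.bin_size)
        return (edges[:-1] + edges[1:]) / 2.0


def tss_metaprofile(
    track: SignalTrack,
    tss_records: Sequence[TssRecord],
    bin_size: int = 10,
    flank: int = 12000,
) -> MetaProfile:
    """Mean tag-normalized coverage in `bin_size`-bp bins over ±`flank` bp
    around each TSS.

    Windows of minus-strand genes are reversed before averaging. Windows
    clipped at a chromosome edge contribute only their covered bins, each
    renormalized by the covered width, so edge genes are kept rather than
    dropped. Units: per bp per region, scaled by 1e7/total_tags.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    if not tss_records:
        raise ValueError("empty TSS set")
    n_bins = 2 * flank // bin_size
    bin_sum = np.zeros(n_bins)
    bin_n = np.zeros(n_bins)
    for tss in tss_records:
        arr = track.coverage[tss.chrom]
        lo, hi = tss.pos - flank, tss.pos + flank
        window = np.full(2 * flank, np.nan)
        src_lo, src_hi = max(lo, 0), min(hi, len(arr))
        if src_lo < src_hi:
            window[src_lo - lo : src_hi - lo] = arr[src_lo:src_hi]
        if tss.strand == "-":
            window = window[::-1]
        per_bin = window.reshape(n_bins, bin_size)
        covered = np.sum(~np.isnan(per_bin), axis=1)
        sums = np.nansum(per_bin, axis=1)
        has = covered > 0
        bin_sum[has] += sums[has] / covered[has]
        bin_n[has] += 1
    density = np.zeros(n_bins)
    nonzero = bin_n > 0
    density[nonzero] = bin_sum[nonzero] / bin_n[nonzero]
    density *= 1e7 / track.total_tags
    return MetaProfile(bin_size, flank, density, len(tss_records))


def category_expression_summary(
    categories: Mapping[str, str], expression: pd.DataFrame, log_transform: bool = False
) -> pd.DataFrame:
    """Per-category n, mean, median and quartiles of mean RPKM.

    With `log_transform`, statistics are computed on log2(RPKM + 1). Empty
    categories are reported with NaN statistics rather than dropped.
    """
    means = mean_rpkm(expression)
    values: Dict[str, List[float]] = {}
    for gene, cat in categories.items():
        if gene in means.index:
            values.setdefault(cat, []).append(float(means[gene]))
    rows = []
    for cat in sorted(set(categories.values())):
        v = np.asarray(values.get(cat, []), dtype=float)
        if log_transform:
            v = np.log2(v + 1.0)
        if len(v) == 0:
            rows.append({"category": cat, "n": 0, "mean": np.nan, "median": np.nan,
                         "q25": np.nan, "q75": np.nan})
        else:
            rows.append(
                {
                    "category": cat,
                    "n": len(v),
                    "mean": float(v.mean()),
                    "median": float(np.median(v)),
                    "q25": float(np.percentile(v, 25)),
                    "q75": float(np.percentile(v, 75)),
                }
            )
    return pd.DataFrame(rows).set_index("category")


def pairwise_student_t(
    groups: Mapping[str, Sequence[float]], welch: bool = False
) -> pd.DataFrame:
    """Two-sided unpaired t-test p-values for every pair of groups.

    Pooled-variance Student test by default; `welch=True` drops the
    equal-variance assumption. Diagonal is 1; two identical constant groups
    (t = 0/0) are reported as p = 1.
    """
    names = list(groups)
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            with warnings.catch_warnings():
                # near-constant groups trigger a precision warning inside the
                # test statistic; the t = 0/0 case is resolved explicitly below
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(groups[a], groups[b], equal_var=not welch)
            if np.isnan(p):  # zero pooled variance: equal means <=> t = 0
                p = 1.0 if np.mean(groups[a]) == np.mean(groups[b]) else 0.0
            mat.loc[a, b] = mat.loc[b, a] = float(p)
    return mat


def kd_category_response(
    de_table: pd.DataFrame, categories: Mapping[str, str]
) -> pd.DataFrame:
    """Knockdown response summary per gene category.

    For each category, over its genes present in the differential-expression
    table: n measured, n significant, mean log2FC and SEM over significant
    genes, and the fraction downregulated (significant with negative log2FC,
    over measured genes). Categories with no measured genes get NaN stats.
    """
    de = de_table.set_index("gene_id")
    rows = []
    for cat in sorted(set(categories.values())):
        genes = [g for g, c in categories.items() if c == cat and g in de.index]
        sub = de.loc[genes]
        n = len(sub)
        if n == 0:
            rows.append(
                {"category": cat, "n": 0, "n_significant": 0,
                 "mean_log2fc": np.nan, "sem_log2fc": np.nan, "frac_down": np.nan}
            )
            continue
        sig = sub[sub["significant"]]
        down = sig[sig["log2fc"] < 0]
        mean_fc = float(sig["log2fc"].mean()) if len(sig) else np.nan
        sem_fc = (
            float(sig["log2fc"].std(ddof=1) / np.sqrt(len(sig)))
            if len(sig) > 1
            else np.nan
        )
        rows.append(
            {
                "category": cat,
                "n": n,
                "n_significant": int(len(sig)),
                "mean_log2fc": mean_fc,
                "sem_log2fc": sem_fc,
                "frac_down": len(down) / n,
            }
        )
    return pd.DataFrame(rows).set_index("category")
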