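"""Readers and writers for the genomic and tabular formats used by the pipeline.

All genomic coordinates are 0-based, half-open (BED convention). A TSS is a
single 0-based base. These conventions are fixed here once; every other module
consumes the types defined in this file.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "Peak",
    "SignalTrack",
    "TssRecord",
    "read_chrom_sizes",
    "read_peaks_bed",
    "write_intervals_bed",
    "read_signal_bedgraph",
    "read_tss_table",
    "read_tabular",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A peak call: interval plus single-bp summit and significance score."""

    interval: GenomicInterval
    summit: int
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside {self.interval.chrom}:"
                f"{self.interval.start}-{self.interval.end}"
            )
        if self.score < 0:
            raise ValueError("score must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: gene id, chromosome, 0-based position, strand."""

    gene_id: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")
        if self.pos < 0:
            raise ValueError("TSS pos must be >= 0")


class SignalTrack:
    """Dense per-base read coverage, plus the total mapped tag count.

    ``coverage`` maps chromosome name to a float array of per-bp values;
    ``total_tags`` is the library size used for tag normalization.
    """

    def __init__(self, coverage: Mapping[str, np.ndarray], total_tags: float):
        if total_tags <= 0:
            raise ValueError("total_tags must be > 0")
        for chrom, arr in coverage.items():
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"coverage on {chrom} must be finite and >= 0")
        self.coverage: Dict[str, np.ndarray] = {
            c: np.asarray(a, dtype=float) for c, a in coverage.items()
        }
        self.total_tags = float(total_tags)

    def chrom_length(self, chrom: str) -> int:
        return len(self.coverage[chrom])

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of coverage over [start, end); raises if outside the track."""
        arr = self.coverage[chrom]
        if start < 0 or end > len(arr) or start >= end:
            raise ValueError(
                f"region {chrom}:{start}-{end} outside track bounds (len {len(arr)})"
            )
        return float(arr[start:end].sum())

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: a * factor for c, a in self.coverage.items()}, self.total_tags
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_chrom_sizes(path: Union[str, Path]) -> Dict[str, int]:
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_peaks_bed(
    path: Union[str, Path], summit_mode: str = "midpoint"
) -> List[Peak]:
    """Read BED / narrowPeak into Peak records.

    ``summit_mode='midpoint'`` sets the summit to floor((start+end)/2);
    ``'column_offset'`` uses narrowPeak column 10 (0-based offset from start;
    -1 means unknown and falls back to the midpoint).
    """
    if summit_mode not in {"midpoint", "column_offset"}:
        raise ValueError(f"unknown summit_mode {summit_mode!r}")
    peaks: List[Peak] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{ln}: invalid coordinates {chrom}:{start}-{end}"
                )
            name = parts[3] if len(parts) > 3 and parts[3] != "." else f"peak_{ln}"
            score = 0.0
            if len(parts) > 4 and parts[4] not in {".", ""}:
                score = float(parts[4])
                if score < 0:
                    raise ValueError(f"{path}:{ln}: negative score")
            strand = parts[5] if len(parts) > 5 and parts[5] in {"+", "-"} else "."
            summit = (start + end) // 2
            if summit_mode == "column_offset":
                if len(parts) < 10:
                    raise ValueError(
                        f"{path}:{ln}: column_offset mode needs >= 10 columns"
                    )
                offset = int(parts[9])
                if offset != -1:
                    summit = start + offset
            peaks.append(
                Peak(GenomicInterval(chrom, start, end, strand), summit, score, name)
            )
    return peaks


def write_intervals_bed(
    records: Iterable[Union[GenomicInterval, Peak]], path: Union[str, Path]
) -> None:
    """Write intervals or peaks as sorted BED (peaks: 5 columns with score).

    Output order is deterministic (chrom, start, end, name) and round-trips
    through :func:`read_peaks_bed`.
    """

    def key(rec):
        if isinstance(rec, Peak):
            return (rec.interval.chrom, rec.interval.start, rec.interval.end, rec.name)
        return (rec.chrom, rec.start, rec.end, "")

    with open(path, "w") as fh:
        for rec in sorted(records, key=key):
            if isinstance(rec, Peak):
                iv = rec.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t{rec.score!r}\n"
                )
            else:
                fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")


def read_signal_bedgraph(
    path: Union[str, Path],
    chrom_sizes: Mapping[str, int],
    total_tags: float,
) -> SignalTrack:
    """Read a bedGraph into a dense per-base SignalTrack.

    Uncovered bases are 0. Records beyond the chromosome bounds or
    overlapping each other are errors.
    """
    records: Dict[str, List[tuple]] = {c: [] for c in chrom_sizes}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}:{ln}: unknown chromosome {chrom!r}")
            if start < 0 or start >= end or end > chrom_sizes[chrom]:
                raise ValueError(
                    f"{path}:{ln}: interval {chrom}:{start}-{end} outside "
                    f"chromosome bounds [0, {chrom_sizes[chrom]})"
                )
            if value < 0:
                raise ValueError(f"{path}:{ln}: negative coverage value")
            records[chrom].append((start, end, value))
    coverage = {c: np.zeros(length, dtype=float) for c, length in chrom_sizes.items()}
    for chrom, recs in records.items():
        recs.sort()
        prev_end = -1
        for start, end, value in recs:
            if start < prev_end:
                raise ValueError(
                    f"{path}: overlapping bedGraph records on {chrom} at {start}"
                )
            coverage[chrom][start:end] = value
            prev_end = end
    return SignalTrack(coverage, total_tags)


def read_tss_table(path: Union[str, Path]) -> List[TssRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "pos", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSS columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene_id {dups[:5]}")
    return [
        TssRecord(row.gene_id, row.chrom, int(row.pos), row.strand)
        for row in df.itertuples(index=False)
    ]


_APMS_ROLES = (
    "untreated",
    "benzonase",
    "etbr",
    "benzonase_rep2",
    "control_exp1",
    "control_exp2",
)


def read_tabular(path: Union[str, Path], schema: str) -> pd.DataFrame:
    """Read a typed TSV. Schemas: 'apms', 'expression', 'de'.

    In AP-MS tables a blank numeric cell means "not detected" and is read as 0;
    in expression/DE tables missing values stay missing (NaN).
    """
    if schema == "apms":
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
        if "protein_id" not in df.columns:
            raise ValueError(f"{path}: apms table needs a protein_id column")
        score_cols = [
            f"{kind}_{role}" for kind in ("mascot", "empai") for role in _APMS_ROLES
        ]
        missing = [c for c in score_cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing apms columns {missing}")
        df[score_cols] = df[score_cols].fillna(0.0).astype(float)
        for flag in ("is_core_mediator", "is_cyto", "is_known_interactor"):
            if flag in df.columns:
                df[flag] = df[flag].fillna(0).astype(bool)
            else:
                df[flag] = False
        return df
    if schema == "expression":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        rep_cols = [c for c in df.columns if c.startswith("rpkm_rep")]
        if "gene_id" not in df.columns or not rep_cols:
            raise ValueError(
                f"{path}: expression table needs gene_id and rpkm_rep* columns"
            )
        df[rep_cols] = df[rep_cols].astype(float)
        return df
    if schema == "de":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        required = {"gene_id", "log2fc", "p_adj", "significant"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing de columns {sorted(missing)}")
        df["log2fc"] = df["log2fc"].astype(float)
        df["significant"] = df["significant"].astype(bool)
        return df
    raise ValueError(f"unknown schema {schema!r}")
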