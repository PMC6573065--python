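"""Seeded generators for AP-MS tables and a toy genome with known ground truth.

The AP-MS generator emulates the purification design: four bait purifications
(untreated, benzonase, EtBr, independent benzonase replicate) plus one control
per experiment. Planted classes: genuine chromatin-independent interactors and
core subunits (present in all four purifications, robust to treatment, absent
or strongly depleted in controls), chromatin-dependent binders (emPAI drops by
at least the configured factor under both treatments) and contaminants
(comparable abundance in controls, a subset annotated cytoskeletal).

The genome generator lays out gene loci on one toy chromosome: each active
gene gets a TSS, an H3K4me3 promoter domain (broad or typical width), a
promoter Mediator-signal block, and either a cluster of enhancers with high
Med1 intensity (a planted super-enhancer), a single typical enhancer, or
nothing. Enhancers are Ep300 peaks nested in H3K27ac regions; a fraction of
genes also carries a TSS-proximal element that the promoter-exclusion step
must remove. Loci are spaced further apart than the stitching gap so planted
clusters are exactly the stitching truth. Expression (three RPKM replicates)
is drawn per category with SE+Broad highest, and a knockdown table plants
per-category probabilities of significant downregulation.

Signal is modelled as piecewise-constant coverage intensity, not simulated
reads; summits get Gaussian jitter to exercise the summit-window overlap rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, Peak, TssRecord

__all__ = ["ApmsDataset", "GenomeFixture", "gen_apms_dataset", "gen_genome_fixture"]

_ROLES = ("untreated", "benzonase", "etbr", "benzonase_rep2", "control_exp1", "control_exp2")
_BAIT_ROLES = _ROLES[:4]
_TREATED = ("benzonase", "etbr", "benzonase_rep2")


def _fmt(x: float) -> str:
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# AP-MS generator


@dataclass
class ApmsDataset:
    table: pd.DataFrame
    truth: Dict[str, dict]  # protein_id -> {"class": ..., params...}
    core_ids: List[str]
    cyto_ids: List[str]
    seed: int

    def true_interactor_ids(self) -> List[str]:
        """Proteins the filter should call: genuine interactors plus core subunits."""
        return sorted(
            p for p, t in self.truth.items()
            if t["class"] in ("true_interactor", "core_subunit")
        )

    def to_dir(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "apms": out / "apms.tsv",
            "core_ids": out / "core_ids.txt",
            "cyto_ids": out / "cyto_ids.txt",
            "truth": out / "apms_truth.json",
        }
        df = self.table.copy()
        float_cols = [c for c in df.columns if c.startswith(("mascot_", "empai_"))]
        df[float_cols] = df[float_cols].map(_fmt)
        df.to_csv(paths["apms"], sep="\t", index=False)
        paths["core_ids"].write_text("".join(f"{p}\n" for p in self.core_ids))
        paths["cyto_ids"].write_text("".join(f"{p}\n" for p in self.cyto_ids))
        paths["truth"].write_text(
            json.dumps({"seed": self.seed, "proteins": self.truth}, indent=1, sort_keys=True)
        )
        return paths


def gen_apms_dataset(
    n_true: int = 50,
    n_chromdep: int = 10,
    n_contaminant: int = 40,
    n_core: int = 26,
    drop_factor: float = 3.0,
    control_detect_prob: float = 0.12,
    empai_sigma: float = 0.8,
    seed: int = 7,
    out_dir=None,
) -> ApmsDataset:
    """Generate an AP-MS table with planted interactor classes.

    Genuine interactors and core subunits keep their emPAI across treatments
    (within-sample jitter far below the two-fold rule); chromatin-dependent
    binders drop by at least `drop_factor` (>= the two-fold rule) in every
    treated purification; contaminants appear at comparable abundance in the
    controls. A `control_detect_prob` fraction of genuine interactors is also
    faintly detected in controls, below the enrichment cutoffs.
    """
    if min(n_true, n_chromdep, n_contaminant, n_core) < 0:
        raise ValueError("counts must be >= 0")
    if empai_sigma <= 0:
        raise ValueError("empai_sigma must be > 0")
    rng = np.random.default_rng(seed)
    rows: List[dict] = []
    truth: Dict[str, dict] = {}
    core_ids: List[str] = []
    cyto_ids: List[str] = []

    def zero_scores() -> dict:
        d = {}
        for role in _ROLES:
            d[f"mascot_{role}"] = 0.0
            d[f"empai_{role}"] = 0.0
        return d

    def mascot_of(empai: float) -> float:
        return 60.0 + 300.0 * empai * rng.lognormal(0.0, 0.2)

    def robust_protein(pid: str, base_loc: float) -> dict:
        """Present in all four bait purifications with a stable emPAI."""
        d = zero_scores()
        base = rng.lognormal(base_loc, empai_sigma)
        for role in _BAIT_ROLES:
            e = base * rng.lognormal(0.0, 0.05)
            d[f"empai_{role}"] = e
            d[f"mascot_{role}"] = mascot_of(e)
        if rng.uniform() < control_detect_prob:
            ctrl = rng.choice(["control_exp1", "control_exp2"])
            e = base / rng.uniform(8.0, 20.0)
            d[f"empai_{ctrl}"] = e
            d[f"mascot_{ctrl}"] = d[f"mascot_{'untreated'}"] / rng.uniform(5.0, 12.0)
        return d

    for i in range(n_true):
        pid = f"TRUE_{i:04d}"
        rows.append({"protein_id": pid, **robust_protein(pid, np.log(0.8)),
                     "is_core_mediator": False, "is_cyto": False,
                     "is_known_interactor": bool(rng.uniform() < 0.2)})
        truth[pid] = {"class": "true_interactor"}
    for i in range(n_core):
        pid = f"CORE_{i:04d}"
        rows.append({"protein_id": pid, **robust_protein(pid, np.log(2.0)),
                     "is_core_mediator": True, "is_cyto": False,
                     "is_known_interactor": True})
        truth[pid] = {"class": "core_subunit"}
        core_ids.append(pid)
    for i in range(n_chromdep):
        pid = f"CHRD_{i:04d}"
        d = zero_scores()
        base = rng.lognormal(np.log(0.8), empai_sigma)
        d["empai_untreated"] = base
        d["mascot_untreated"] = mascot_of(base)
        for role in _TREATED:
            e = base / rng.uniform(drop_factor, drop_factor + 2.0)
            d[f"empai_{role}"] = e
            d[f"mascot_{role}"] = mascot_of(e)
        rows.append({"protein_id": pid, **d, "is_core_mediator": False,
                     "is_cyto": False, "is_known_interactor": False})
        truth[pid] = {"class": "chromatin_dependent", "drop_factor": drop_factor}
    for i in range(n_contaminant):
        pid = f"CONT_{i:04d}"
        d = zero_scores()
        base = rng.lognormal(np.log(0.5), empai_sigma)
        for role in _BAIT_ROLES:
            if rng.uniform() < 0.75:
                e = base * rng.lognormal(0.0, 0.2)
                d[f"empai_{role}"] = e
                d[f"mascot_{role}"] = mascot_of(e)
        for role in ("control_exp1", "control_exp2"):
            e = base * rng.lognormal(0.0, 0.2)
            d[f"empai_{role}"] = e
            d[f"mascot_{role}"] = mascot_of(e)
        is_cyto = bool(rng.uniform() < 0.25)
        if is_cyto:
            cyto_ids.append(pid)
        rows.append({"protein_id": pid, **d, "is_core_mediator": False,
                     "is_cyto": is_cyto, "is_known_interactor": False})
        truth[pid] = {"class": "contaminant"}

    columns = (
        ["protein_id"]
        + [f"mascot_{r}" for r in _ROLES]
        + [f"empai_{r}" for r in _ROLES]
        + ["is_core_mediator", "is_cyto", "is_known_interactor"]
    )
    table = pd.DataFrame(rows, columns=columns)
    ds = ApmsDataset(table=table, truth=truth, core_ids=core_ids,
                     cyto_ids=cyto_ids, seed=seed)
    if out_dir is not None:
        ds.to_dir(out_dir)
    return ds


# ---------------------------------------------------------------------------
# genome fixture generator

CATEGORY_ORDER = ("SE+Broad", "SE-Broad", "Broad-SE", "Typical")

DEFAULT_EXPRESSION_MEDIANS = {
    "SE+Broad": 60.0,
    "SE-Broad": 15.0,
    "Broad-SE": 12.0,
    "Typical": 4.0,
}

DEFAULT_KD_DOWN_PROBS = {
    "SE+Broad": 0.65,
    "SE-Broad": 0.40,
    "Broad-SE": 0.20,
    "Typical": 0.20,
}

_PROMOTER_MED1 = {"SE+Broad": 6.0, "SE-Broad": 3.0, "Broad-SE": 3.0, "Typical": 1.0}


@dataclass
class GenomeFixture:
    chrom_sizes: Dict[str, int]
    tss_records: List[TssRecord]
    ep300_peaks: List[Peak]
    h3k27ac_regions: List[GenomicInterval]
    h3k4me3_domains: List[GenomicInterval]
    med1_bedgraph: List[Tuple[str, int, int, float]]  # sorted, non-overlapping
    factor_peaks: Dict[str, List[Peak]]
    expression: pd.DataFrame
    de_table: pd.DataFrame
    truth: dict
    total_tags: float

    def med1_track(self):
        from .io_formats import SignalTrack

        cov = {c: np.zeros(n) for c, n in self.chrom_sizes.items()}
        for chrom, start, end, value in self.med1_bedgraph:
            cov[chrom][start:end] = value
        return SignalTrack(cov, self.total_tags)

    def to_dir(self, out_dir) -> Dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: Dict[str, Path] = {}

        paths["chrom_sizes"] = out / "chrom.sizes"
        paths["chrom_sizes"].write_text(
            "".join(f"{c}\t{n}\n" for c, n in sorted(self.chrom_sizes.items()))
        )
        paths["tss"] = out / "tss.tsv"
        with open(paths["tss"], "w") as fh:
            fh.write("gene_id\tchrom\tpos\tstrand\n")
            for t in self.tss_records:
                fh.write(f"{t.gene_id}\t{t.chrom}\t{t.pos}\t{t.strand}\n")
        paths["ep300"] = out / "ep300_peaks.bed"
        with open(paths["ep300"], "w") as fh:
            for p in self.ep300_peaks:
                iv = p.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{_fmt(p.score)}\n")
        paths["h3k27ac"] = out / "h3k27ac_regions.bed"
        with open(paths["h3k27ac"], "w") as fh:
            for iv in self.h3k27ac_regions:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        paths["h3k4me3"] = out / "h3k4me3_domains.bed"
        with open(paths["h3k4me3"], "w") as fh:
            for iv in self.h3k4me3_domains:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        paths["med1"] = out / "med1.bedgraph"
        with open(paths["med1"], "w") as fh:
            for chrom, start, end, value in self.med1_bedgraph:
                fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")
        for factor, peaks in self.factor_peaks.items():
            key = f"peaks_{factor}"
            paths[key] = out / f"peaks_{factor}.narrowPeak"
            with open(paths[key], "w") as fh:
                for p in peaks:
                    iv = p.interval
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{_fmt(p.score)}"
                        f"\t.\t{_fmt(p.score)}\t-1\t-1\t{p.summit - iv.start}\n"
                    )
        paths["expression"] = out / "expression.tsv"
        expr = self.expression.copy()
        rep_cols = [c for c in expr.columns if c.startswith("rpkm_rep")]
        expr[rep_cols] = expr[rep_cols].map(_fmt)
        expr.to_csv(paths["expression"], sep="\t", index=False)
        paths["de"] = out / "de.tsv"
        de = self.de_table.copy()
        de["log2fc"] = de["log2fc"].map(_fmt)
        de["p_adj"] = de["p_adj"].map(_fmt)
        de.to_csv(paths["de"], sep="\t", index=False)
        paths["truth"] = out / "genome_truth.json"
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


def gen_genome_fixture(
    n_se_broad: int = 10,
    n_se_no_broad: int = 10,
    n_broad_no_se: int = 12,
    n_typical: int = 40,
    n_inactive: int = 8,
    n_decoy_ep300: int = 12,
    n_decoy_h3k27ac: int = 8,
    se_constituents: Tuple[int, int] = (2, 4),
    enhancer_width: Tuple[int, int] = (500, 800),
    constituent_gap: Tuple[int, int] = (1000, 3000),
    se_intensity_ratio: float = 10.0,
    typical_intensity: float = 1.0,
    intensity_sigma: float = 0.15,
    coloc_prob: float = 0.7,
    promoter_factor_prob: float = 0.3,
    tss_proximal_prob: float = 0.3,
    summit_jitter_sd: float = 20.0,
    expression_medians: Optional[Dict[str, float]] = None,
    expression_sigma: float = 0.4,
    kd_down_probs: Optional[Dict[str, float]] = None,
    kd_up_prob: float = 0.05,
    total_tags: float = 1e7,
    locus_spacing: int = 13500,
    seed: int = 11,
    out_dir=None,
) -> GenomeFixture:
    """Generate the toy-genome bundle with a consistent truth record.

    Planted SE clusters hold `se_constituents` enhancers with intensity
    `se_intensity_ratio` times the typical level; loci are separated by
    `locus_spacing` bp (beyond the 12.5 kb stitching gap) so each planted
    cluster is one stitched region. Deterministic under `seed`.
    """
    if expression_medians is None:
        expression_medians = dict(DEFAULT_EXPRESSION_MEDIANS)
    if kd_down_probs is None:
        kd_down_probs = dict(DEFAULT_KD_DOWN_PROBS)
    rng = np.random.default_rng(seed)
    chrom = "chr1"

    counts = {
        "SE+Broad": n_se_broad,
        "SE-Broad": n_se_no_broad,
        "Broad-SE": n_broad_no_se,
        "Typical": n_typical,
    }
    gene_plan: List[Optional[str]] = []
    for cat in CATEGORY_ORDER:
        gene_plan.extend([cat] * counts[cat])
    gene_plan.extend([None] * n_inactive)  # None = inactive gene
    order = rng.permutation(len(gene_plan))
    gene_plan = [gene_plan[i] for i in order]

    tss_records: List[TssRecord] = []
    ep300_peaks: List[Peak] = []
    h3k27ac_regions: List[GenomicInterval] = []
    h3k4me3_domains: List[GenomicInterval] = []
    med1_blocks: List[Tuple[str, int, int, float]] = []
    med1_sites: List[Tuple[int, int, float]] = []  # (start, end, intensity) for peaks
    tcf4_sites: List[Tuple[int, int]] = []
    truth_genes: List[dict] = []
    truth_enhancers: List[dict] = []
    truth_clusters: List[dict] = []

    cursor = 10000
    enh_counter = 0

    def add_enhancer(start: int, width: int, intensity: float, kind: str,
                     cluster_id: Optional[str], with_signal: bool = True) -> dict:
        nonlocal enh_counter
        end = start + width
        name = f"ep300_{enh_counter:05d}"
        enh_counter += 1
        score = float(50.0 * rng.lognormal(0.0, 0.4))
        ep300_peaks.append(
            Peak(GenomicInterval(chrom, start, end), (start + end) // 2, score, name)
        )
        h3k27ac_regions.append(GenomicInterval(chrom, start - 200, end + 200))
        if with_signal:
            med1_blocks.append((chrom, start, end, intensity))
            med1_sites.append((start, end, intensity))
            has_tcf4 = bool(rng.uniform() < coloc_prob)
            if has_tcf4:
                tcf4_sites.append((start, end))
        else:
            has_tcf4 = False
        rec = {
            "id": name, "start": start, "end": end, "kind": kind,
            "cluster_id": cluster_id, "intensity": intensity if with_signal else 0.0,
            "med1": with_signal, "tcf4": has_tcf4,
        }
        truth_enhancers.append(rec)
        return rec

    for idx, cat in enumerate(gene_plan):
        gene_id = f"g{idx:04d}"
        tss = cursor + 8000
        strand = "+" if rng.uniform() < 0.5 else "-"
        tss_records.append(TssRecord(gene_id, chrom, tss, strand))
        active = cat is not None
        width = 0
        if active:
            broad = cat in ("SE+Broad", "Broad-SE")
            width = int(rng.integers(4000, 8001) if broad else rng.integers(400, 1201))
            dom_start = max(0, tss - int(width * rng.uniform(0.2, 0.8)))
            h3k4me3_domains.append(GenomicInterval(chrom, dom_start, dom_start + width))
            med1_blocks.append(
                (chrom, tss - 500, tss + 1500,
                 float(_PROMOTER_MED1[cat] * rng.lognormal(0.0, 0.2)))
            )
            med1_sites.append((tss - 500, tss + 1500, _PROMOTER_MED1[cat]))
            if rng.uniform() < promoter_factor_prob:
                tcf4_sites.append((tss - 500, tss + 1500))
        feature_end = tss + 2000
        cluster_id = None
        tss_proximal = False
        if active and rng.uniform() < tss_proximal_prob:
            # promoter-proximal element; removed by the TSS-exclusion step
            add_enhancer(tss + 300, 400, 0.0, "tss_proximal", None, with_signal=False)
            tss_proximal = True
        if cat in ("SE+Broad", "SE-Broad"):
            cluster_id = f"se_{len(truth_clusters):04d}"
            k = int(rng.integers(se_constituents[0], se_constituents[1] + 1))
            pos = tss + int(rng.integers(2500, 3501))
            cluster_start = pos
            total = 0.0
            for _ in range(k):
                w = int(rng.integers(enhancer_width[0], enhancer_width[1] + 1))
                intensity = float(
                    se_intensity_ratio * typical_intensity * rng.lognormal(0.0, 0.25)
                )
                add_enhancer(pos, w, intensity, "se_constituent", cluster_id)
                total += w * intensity
                pos += w + int(rng.integers(constituent_gap[0], constituent_gap[1] + 1))
            cluster_end = truth_enhancers[-1]["end"]
            truth_clusters.append(
                {"cluster_id": cluster_id, "start": cluster_start,
                 "end": cluster_end, "gene_id": gene_id, "n_constituents": k,
                 "total_signal": total}
            )
            feature_end = cluster_end
        elif cat in ("Broad-SE", "Typical"):
            w = int(rng.integers(enhancer_width[0], enhancer_width[1] + 1))
            intensity = float(typical_intensity * rng.lognormal(0.0, intensity_sigma))
            start = tss + int(rng.integers(2500, 3501))
            add_enhancer(start, w, intensity, "typical", None)
            feature_end = start + w
        truth_genes.append(
            {"gene_id": gene_id, "tss": tss, "strand": strand, "active": active,
             "category": cat if active else "inactive",
             "broad": bool(active and cat in ("SE+Broad", "Broad-SE")),
             "h3k4me3_width": width, "cluster_id": cluster_id,
             "tss_proximal_element": tss_proximal}
        )
        cursor = feature_end + locus_spacing

    # decoy zone: Ep300 without H3K27ac support, and H3K27ac without Ep300
    for i in range(n_decoy_ep300):
        start = cursor
        w = int(rng.integers(enhancer_width[0], enhancer_width[1] + 1))
        name = f"decoy_ep300_{i:03d}"
        ep300_peaks.append(
            Peak(GenomicInterval(chrom, start, start + w), start + w // 2,
                 float(50.0 * rng.lognormal(0.0, 0.4)), name)
        )
        truth_enhancers.append(
            {"id": name, "start": start, "end": start + w, "kind": "decoy_ep300",
             "cluster_id": None, "intensity": 0.0, "med1": False, "tcf4": False}
        )
        cursor = start + w + 14000
    for i in range(n_decoy_h3k27ac):
        start = cursor
        w = int(rng.integers(800, 2001))
        h3k27ac_regions.append(GenomicInterval(chrom, start, start + w))
        cursor = start + w + 14000

    chrom_len = cursor + 20000
    chrom_sizes = {chrom: chrom_len}

    # factor peak calls with jittered summits
    def make_peaks(sites, factor: str, score_scale: float) -> List[Peak]:
        peaks = []
        for j, site in enumerate(sites):
            start, end = site[0], site[1]
            pad = 150
            iv = GenomicInterval(chrom, max(0, start - pad), end + pad)
            center = (start + end) // 2
            summit = int(np.clip(round(center + rng.normal(0.0, summit_jitter_sd)),
                                 iv.start, iv.end - 1))
            base = site[2] if len(site) > 2 else 1.0
            score = float(score_scale * base * rng.lognormal(0.0, 0.3))
            peaks.append(Peak(iv, summit, score, f"{factor}_{j:05d}"))
        return peaks

    factor_peaks = {
        "med1": make_peaks(med1_sites, "med1", 40.0),
        "tcf4": make_peaks(tcf4_sites, "tcf4", 30.0),
    }

    # expression: three RPKM replicates, category-ordered means
    expr_rows = []
    for g in truth_genes:
        if g["active"]:
            mean = max(1.0, expression_medians[g["category"]]
                       * rng.lognormal(0.0, expression_sigma))
        else:
            mean = min(0.4, 0.1 * rng.lognormal(0.0, 0.3))
        reps = mean * rng.lognormal(0.0, 0.1 if g["active"] else 0.05, size=3)
        if not g["active"]:
            reps = np.minimum(reps, 0.45)
        g["mean_rpkm"] = float(np.mean(reps))
        expr_rows.append({"gene_id": g["gene_id"], "rpkm_rep1": reps[0],
                          "rpkm_rep2": reps[1], "rpkm_rep3": reps[2]})
    expression = pd.DataFrame(expr_rows)

    # knockdown differential expression: per category, plant exactly
    # floor(p_down * n + 0.5) significant-down genes (and a small sig-up set)
    # on randomly chosen genes, so the planted fraction is the dataset's truth
    status: Dict[str, str] = {}
    for cat in CATEGORY_ORDER:
        members = [g["gene_id"] for g in truth_genes if g["category"] == cat]
        if not members:
            continue
        perm = [members[i] for i in rng.permutation(len(members))]
        n_down = int(kd_down_probs[cat] * len(members) + 0.5)
        n_up = int(kd_up_prob * len(members) + 0.5)
        for gid in perm[:n_down]:
            status[gid] = "down"
        for gid in perm[n_down : n_down + n_up]:
            status[gid] = "up"
    de_rows = []
    for g in truth_genes:
        st = status.get(g["gene_id"], "none")
        if st == "down":
            lfc = min(-0.1, rng.normal(-1.2, 0.3))
            p_adj = rng.uniform(1e-4, 0.01)
            sig = True
        elif st == "up":
            lfc = max(0.1, rng.normal(0.8, 0.3))
            p_adj = rng.uniform(1e-4, 0.01)
            sig = True
        elif g["active"]:
            lfc = rng.normal(0.0, 0.15)
            p_adj = rng.uniform(0.2, 0.9)
            sig = False
        else:
            lfc = rng.normal(0.0, 0.1)
            p_adj = rng.uniform(0.5, 0.95)
            sig = False
        g["kd_significant"] = bool(sig)
        g["kd_down"] = st == "down"
        de_rows.append({"gene_id": g["gene_id"], "log2fc": float(lfc),
                        "p_adj": float(p_adj), "significant": bool(sig)})
    de_table = pd.DataFrame(de_rows)

    broad_true = sum(1 for g in truth_genes if g["broad"])
    with_domain = sum(1 for g in truth_genes if g["h3k4me3_width"] > 0)
    truth = {
        "seed": seed,
        "chrom_sizes": chrom_sizes,
        "genes": truth_genes,
        "enhancers": truth_enhancers,
        "se_clusters": truth_clusters,
        "params": {
            "counts": counts, "n_inactive": n_inactive,
            "se_intensity_ratio": se_intensity_ratio,
            "typical_intensity": typical_intensity,
            "coloc_prob": coloc_prob,
            "kd_down_probs": kd_down_probs,
            "kd_up_prob": kd_up_prob,
            "expression_medians": expression_medians,
            "broad_frac_true": (broad_true / with_domain) if with_domain else 0.0,
            "total_tags": total_tags,
            "locus_spacing": locus_spacing,
        },
    }
    fixture = GenomeFixture(
        chrom_sizes=chrom_sizes,
        tss_records=tss_records,
        ep300_peaks=ep300_peaks,
        h3k27ac_regions=h3k27ac_regions,
        h3k4me3_domains=h3k4me3_domains,
        med1_bedgraph=sorted(med1_blocks, key=lambda b: (b[0], b[1])),
        factor_peaks=factor_peaks,
        expression=expression,
        de_table=de_table,
        truth=truth,
        total_tags=total_tags,
    )
    if out_dir is not None:
        fixture.to_dir(out_dir)
    return fixture
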