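"""Configuration, orchestration and manifest reporting for full runs.

A run is described by a small mapping (usually a YAML file) with three
sections: ``inputs`` (paths per data type), ``params`` (the tunable
thresholds, all defaulted to the analysis' standard values) and
``output_dir``. Unknown keys are rejected before any computation. Every run
writes a ``manifest.json`` echoing parameters, input checksums and stage
counts, so two runs over identical inputs are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    GenomicInterval,
    read_chrom_sizes,
    read_peaks_bed,
    read_signal_bedgraph,
    read_tabular,
    read_tss_table,
)
from .interactome import (
    FilterConfig,
    calls_to_table,
    call_interactors,
    edge_list,
    rows_from_table,
    subtract_core_subunits,
)
from .enhancer_se import (
    call_se_cutoff,
    define_enhancers,
    exclude_tss_overlapping,
    hockey_curve,
    quantify_region_signal,
    se_table,
    stitch_enhancers,
)
from .gene_categories import (
    active_gene_set,
    assign_gene_categories,
    broad_promoter_set,
    nearest_gene_per_region,
    promoter_domain_width,
    top100_sets,
)
from .profiles_response import kd_category_response

logger = logging.getLogger("mediascape")

PARAM_DEFAULTS: Dict[str, float] = {
    "stitch": 12500,
    "tss_window": 1000,
    "top_n": 5000,
    "summit_window": 200,
    "promoter_halfwidth": 1500,
    "rpkm_min": 0.5,
    "broad_frac": 0.05,
    "bin": 10,
    "flank": 12000,
    "mascot_min": 50.0,
    "empai_fold_min": 5.0,
    "mascot_fold_min": 3.0,
    "treatment_drop_fold": 2.0,
    "total_tags": 1e7,
    "top_k": 100,
}

INPUT_KEYS = {
    "apms",
    "core_ids",
    "ep300",
    "h3k27ac",
    "h3k4me3",
    "tss",
    "med1_bedgraph",
    "background_bedgraph",
    "chrom_sizes",
    "expression",
    "de",
}

TOP_KEYS = {"inputs", "params", "output_dir", "log_level", "seed"}


class ConfigError(ValueError):
    pass


def load_config(source) -> dict:
    """Load and validate a pipeline config from a path or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(source)
    unknown = set(cfg) - TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    inputs = cfg.get("inputs") or {}
    unknown = set(inputs) - INPUT_KEYS
    if unknown:
        raise ConfigError(f"unknown input keys: {sorted(unknown)}")
    params = dict(PARAM_DEFAULTS)
    user_params = cfg.get("params") or {}
    unknown = set(user_params) - set(PARAM_DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
    params.update(user_params)
    if "output_dir" not in cfg:
        raise ConfigError("config needs an output_dir")
    for key, path in inputs.items():
        if not Path(path).exists():
            raise ConfigError(f"input {key!r}: no such file {path}")
    return {"inputs": inputs, "params": params, "output_dir": cfg["output_dir"],
            "log_level": cfg.get("log_level", "INFO")}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config) -> dict:
    """Run the configured stages and return the manifest (also written to disk)."""
    cfg = load_config(config)
    inputs, params = cfg["inputs"], cfg["params"]
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), 20))
    counts: Dict[str, int] = {}
    outputs: List[str] = []

    if "apms" in inputs:
        logger.info("stage: interactome")
        try:
            table = read_tabular(inputs["apms"], "apms")
            fc = FilterConfig(
                mascot_min=params["mascot_min"],
                empai_fold_min=params["empai_fold_min"],
                mascot_fold_min=params["mascot_fold_min"],
                treatment_drop_fold=params["treatment_drop_fold"],
            )
            calls = call_interactors(rows_from_table(table), fc)
            passing = [c for c in calls if c.passed]
            counts["apms_proteins"] = len(calls)
            counts["interactors_passing"] = len(passing)
            if "core_ids" in inputs:
                core = set(Path(inputs["core_ids"]).read_text().split())
                minus_core = subtract_core_subunits(passing, core)
                counts["core_matches"] = len(passing) - len(minus_core)
                counts["interactors_after_core"] = len(minus_core)
            calls_to_table(calls).to_csv(out / "interactors.tsv", sep="\t", index=False)
            edge_list(calls).to_csv(out / "edges.tsv", sep="\t", index=False)
            outputs += ["interactors.tsv", "edges.tsv"]
        except Exception as exc:
            raise RuntimeError(f"stage interactome failed: {exc}") from exc

    genomic_needed = {"ep300", "h3k27ac", "tss", "med1_bedgraph", "chrom_sizes"}
    categories_df = None
    if genomic_needed <= set(inputs):
        logger.info("stage: enhancers/SE")
        try:
            ep300 = read_peaks_bed(inputs["ep300"])
            h3k27ac = [p.interval for p in read_peaks_bed(inputs["h3k27ac"])]
            tss = read_tss_table(inputs["tss"])
            sizes = read_chrom_sizes(inputs["chrom_sizes"])
            track = read_signal_bedgraph(
                inputs["med1_bedgraph"], sizes, params["total_tags"]
            )
            background = None
            if "background_bedgraph" in inputs:
                background = read_signal_bedgraph(
                    inputs["background_bedgraph"], sizes, params["total_tags"]
                )
            enhancers = define_enhancers(ep300, h3k27ac)
            counts["enhancers"] = len(enhancers)
            kept = exclude_tss_overlapping(enhancers, tss, int(params["tss_window"]))
            counts["enhancers_outside_tss"] = len(kept)
            stitched = stitch_enhancers(kept, int(params["stitch"]))
            stitched = [
                s.with_signal(quantify_region_signal(s.interval, track, background))
                for s in stitched
            ]
            counts["stitched_regions"] = len(stitched)
            result = call_se_cutoff(stitched)
            counts["super_enhancers"] = result.n_se
            counts["typical_enhancers"] = result.n_typical
            se_table(result).to_csv(out / "stitched_regions.tsv", sep="\t", index=False)
            hockey_curve(result).to_csv(out / "hockey_curve.tsv", sep="\t", index=False)
            outputs += ["stitched_regions.tsv", "hockey_curve.tsv"]

            if {"expression", "h3k4me3"} <= set(inputs):
                logger.info("stage: gene categories")
                expression = read_tabular(inputs["expression"], "expression")
                active = active_gene_set(expression, params["rpkm_min"])
                active_tss = [t for t in tss if t.gene_id in active]
                domains = [p.interval for p in read_peaks_bed(inputs["h3k4me3"])]
                widths = promoter_domain_width(domains, tss)
                broad = broad_promoter_set(widths, params["broad_frac"]) & active
                ordered = sorted(
                    zip(result.regions, result.is_se),
                    key=lambda t: -t[0].total_signal,
                )
                se_regions = [r.interval for r, se in ordered if se]
                te_regions = [r.interval for r, se in ordered if not se]
                se_nearest = nearest_gene_per_region(se_regions, active_tss)
                te_nearest = nearest_gene_per_region(te_regions, active_tss)
                se_genes = {g for g in se_nearest if g}
                typical_genes = {g for g in te_nearest if g} - se_genes
                categories_df = assign_gene_categories(
                    active, se_genes, typical_genes, broad
                )
                for cat, n in categories_df["category"].value_counts().items():
                    counts[f"genes_{cat}"] = int(n)
                ranked = [
                    (f"se_{i:04d}", r.total_signal, g)
                    for i, ((r, _), g) in enumerate(
                        zip([t for t in ordered if t[1]], se_nearest)
                    )
                ]
                tops = top100_sets(
                    ranked, broad, widths, categories_df, int(params["top_k"])
                )
                categories_df.to_csv(out / "gene_categories.tsv", sep="\t", index=False)
                pd.DataFrame(
                    {
                        "list": (["top_se_broad"] * len(tops.top100_se_broad)
                                 + ["top_se_no_broad"] * len(tops.top100_se_no_broad)
                                 + ["top_broad_no_se"] * len(tops.top100_broad_no_se)),
                        "gene_id": (list(tops.top100_se_broad)
                                    + list(tops.top100_se_no_broad)
                                    + list(tops.top100_broad_no_se)),
                    }
                ).to_csv(out / "top_gene_lists.tsv", sep="\t", index=False)
                outputs += ["gene_categories.tsv", "top_gene_lists.tsv"]

                if "de" in inputs:
                    logger.info("stage: knockdown response")
                    de = read_tabular(inputs["de"], "de")
                    cat_map = dict(
                        zip(categories_df["gene_id"], categories_df["category"])
                    )
                    cat_map = {g: c for g, c in cat_map.items() if c != "none"}
                    response = kd_category_response(de, cat_map)
                    response.to_csv(out / "kd_response.tsv", sep="\t")
                    outputs.append("kd_response.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage genomic failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "parameters": params,
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "counts": counts,
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
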