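"""End-to-end orchestration: data in, classified categories, nulls,
score statistics, ECS calls and a machine-readable report out.

A :class:`PipelineConfig` names either input files (site table, PWMs,
annotation lists, abundance table) or a simulation block; exactly one of
the two. Stages whose inputs are absent are skipped with a logged notice.
All randomness flows from the single config seed, so a report is
re-creatable byte-identically from config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    stc_fraction_by_abundance_bins,
    annotation_proportion_test,
    summarize_categories,
    summarize_poly_clusters,
)
from .core_io import OrthologAlignment, read_pwms, read_site_table, write_site_table
from .ecs_detection import DEFAULT_L_VALUES, detect_ecs_dataset
from .kinase_scoring import (
    compare_score_sets,
    divergence_excess_from_scores,
    fraction_phosphorylated_by_score_bin,
    kinase_overlap_test,
    score_alignment_sites,
    score_correlation,
)
from .null_models import (
    null_category_distribution,
    null_poly_cluster_distribution,
    null_report,
)
from .synthetic_data import SimulationConfig, apply_detection_noise, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run."""

    # exactly one of the two input modes
    site_table: str | None = None
    simulation: SimulationConfig | None = None

    pwms: str | None = None
    abundance: str | None = None  # TSV: protein_id <tab> abundance
    annotations: dict[str, str] = field(default_factory=dict)  # label -> path

    n_iterations_category: int = 100
    n_iterations_poly: int = 1000
    n_iterations_ecs: int = 1000
    n_iterations_overlap_best1: int = 10_000
    n_iterations_overlap_top3: int = 100
    alpha: float = 0.05
    L_values: tuple[int, ...] = DEFAULT_L_VALUES
    abundance_bins: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.site_table is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of site_table / simulation must be given")


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    cfg = PipelineConfig(
        simulation=SimulationConfig(**sim) if sim is not None else None,
        **{k: (tuple(v) if k == "L_values" else v) for k, v in raw.items()},
    )
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return str(obj)
    blob = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _read_abundance(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["protein_id", "abundance"], comment="#")
    return dict(zip(df.protein_id, df.abundance.astype(float)))


def _read_labels(path) -> set[str]:
    with open(path) as fh:
        return {ln.strip() for ln in fh
                if ln.strip() and not ln.startswith("#")}


def _load_alignments(cfg: PipelineConfig) -> list[OrthologAlignment]:
    if cfg.site_table is not None:
        return read_site_table(cfg.site_table)
    truth, _events = simulate_dataset(cfg.simulation)
    return apply_detection_noise(truth, cfg.simulation)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute every stage the configuration enables and write the report.

    Returns the report dictionary; files written under ``outdir``:
    ``report.json``, ``site_table.tsv`` (for simulated inputs),
    ``ecs_pairs.tsv`` and ``scored_sites.tsv`` when produced.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
        },
    }
    t0 = time.monotonic()
    alignments = _load_alignments(cfg)
    logger.info("loaded %d ortholog alignments (%.1fs)",
                len(alignments), time.monotonic() - t0)
    if cfg.simulation is not None:
        write_site_table(alignments, out / "site_table.tsv")

    # -- categories and their nulls -------------------------------------
    summary = summarize_categories(alignments)
    report["categories"] = {
        "counts": summary.counts,
        "union_total": summary.union_total,
        "fractions": summary.fractions,
        "disorder_strata": summary.disorder_strata,
    }
    nulls = null_category_distribution(
        alignments, "b", cfg.n_iterations_category,
        np.random.SeedSequence((cfg.seed, 1)))
    report["category_nulls"] = null_report(nulls)

    poly = summarize_poly_clusters(alignments)
    report["poly_clusters"] = {"counts": poly}
    if cfg.n_iterations_poly > 0:
        poly_nulls = null_poly_cluster_distribution(
            alignments, "b", cfg.n_iterations_poly,
            np.random.SeedSequence((cfg.seed, 2)))
        report["poly_cluster_nulls"] = null_report(poly_nulls)

    # -- abundance and annotations --------------------------------------
    if cfg.abundance is not None:
        bins, dropped = stc_fraction_by_abundance_bins(
            summary.per_protein, _read_abundance(cfg.abundance),
            cfg.abundance_bins)
        report["abundance_bins"] = {
            "table": bins.to_dict(orient="records"),
            "n_dropped": len(dropped),
        }
    else:
        logger.info("no abundance table; skipping abundance bins")

    if cfg.annotations:
        per_protein = summary.per_protein
        stc_sites = [p for p, c in per_protein.items()
                     for _ in range(c.get("StC", 0))]
        std_sites = [p for p, c in per_protein.items()
                     for _ in range(c.get("StD", 0))]
        ann = {}
        for label, path in sorted(cfg.annotations.items()):
            res = annotation_proportion_test(
                stc_sites, std_sites, _read_labels(path))
            ann[label] = {
                "stc_proportion": res.proportion_1,
                "std_proportion": res.proportion_2,
                "p_value": res.p_value,
            }
        report["annotation_tests"] = ann

    # -- kinase scoring ---------------------------------------------------
    scored = None
    if cfg.pwms is not None:
        pwms = read_pwms(cfg.pwms)
        scored = score_alignment_sites(alignments, pwms)
        scored.to_csv(out / "scored_sites.tsv", sep="\t", index=False)
        section: dict = {"n_scored_columns": int(len(scored))}
        stc = scored[scored.category == "StC"]
        if len(stc) >= 2:
            m1, m2, p = compare_score_sets(stc.score_a, stc.score_b)
            rho, rho_p = score_correlation(
                list(zip(stc.score_a, stc.score_b)))
            section["stc"] = {"median_a": m1, "median_b": m2,
                              "ranksum_p": p, "spearman_rho": rho,
                              "spearman_p": rho_p}
        std = scored[scored.category == "StD"]
        if len(std) >= 2:
            phos = np.where(std.phospho_in == "a", std.score_a, std.score_b)
            non = np.where(std.phospho_in == "a", std.score_b, std.score_a)
            m1, m2, p = compare_score_sets(phos, non)
            section["std_phospho_vs_non"] = {
                "median_phospho": m1, "median_non": m2, "ranksum_p": p}
        section["divergence_excess"] = divergence_excess_from_scores(scored)
        flags = ((scored.phospho_in == "both") | (scored.phospho_in == "a"))
        section["fraction_phospho_by_score_bin"] = (
            fraction_phosphorylated_by_score_bin(
                scored.score_a.to_numpy(), flags.to_numpy())
            .to_dict(orient="records"))
        report["scores"] = section
    else:
        logger.info("no PWMs configured; skipping scoring stages")

    # -- evolutionary clustered sites ------------------------------------
    ecs_table, flagged = detect_ecs_dataset(
        alignments, cfg.L_values, cfg.n_iterations_ecs, cfg.alpha,
        np.random.SeedSequence((cfg.seed, 3)),
    )
    ecs_table.to_csv(out / "ecs_pairs.tsv", sep="\t", index=False)
    report["ecs"] = {
        "n_pairs": int(len(ecs_table)),
        "n_proteins": int(ecs_table.pair_id.nunique()) if len(ecs_table) else 0,
        "flagged_large_clusters": flagged,
    }

    # -- shared-kinase tests ----------------------------------------------
    if scored is not None and len(scored):
        overlap: dict = {}
        for cat in ("StC", "StD"):
            sub = scored[scored.category == cat]
            pairs = [(a, b) for a, b in zip(sub.top3_a, sub.top3_b)]
            if len(pairs) >= 2:
                overlap[cat] = {
                    mode: _null_summary(kinase_overlap_test(
                        pairs, mode,
                        cfg.n_iterations_overlap_best1 if mode == "best1"
                        else cfg.n_iterations_overlap_top3,
                        np.random.SeedSequence((cfg.seed, 4))))
                    for mode in ("best1", "top3")
                }
        report["kinase_overlap"] = overlap

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True,
                                      default=_json_default) + "\n")
    logger.info("pipeline complete in %.1fs -> %s",
                time.monotonic() - t0, report_path)
    return report


def _null_summary(nd) -> dict:
    return {
        "observed": nd.observed,
        "null_mean": float(np.mean(nd.replicates)),
        "fold": nd.fold,
        "empirical_p": nd.empirical_p,
        "n_iterations": nd.n_iterations,
    }


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
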