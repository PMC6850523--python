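"""End-to-end orchestration: diagnose, correct, re-test, and report.

``run_pipeline`` executes the recommended workflow on one dataset: filter
expressed genes, scan replicate pairs for length-FC bias, correct with the
covariate normalizer when flagged, re-diagnose, run pre-ranked GSEA on the
strongest replicate-pair ranking before and after correction, run the
VIF-adjusted set test, and write a machine-readable summary plus a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    align_to_annotation,
    filter_expressed,
    log2_fold_change,
    read_annotation,
    read_counts,
    read_gmt,
)
from .diagnostics import FLAG_P, replicate_pair_scan
from .norm import covariate_normalize, normalize_counts
from .sets import gsea_preranked, ranked_from_scores, vif_adjusted_set_test
from .synth import SynthConfig, generate_dataset, write_dataset

logger = logging.getLogger("lenbias")

__all__ = ["PipelineConfig", "run_pipeline", "make_synth"]


@dataclass
class PipelineConfig:
    counts: str
    design: str
    annotation: str
    gmt: str
    outdir: str
    normalizer: str = "rpkm"
    covariates: tuple[str, ...] = ("length",)
    n_knots: int = 5
    cpm_threshold: float = 1.0
    flag_p: float = FLAG_P
    removal_rho: float = 0.05
    gsea_nperm: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    fdr_threshold: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config fields: {sorted(unknown)}")
        if "covariates" in raw and isinstance(raw["covariates"], list):
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        return d


def _report_rows(reports) -> list[dict]:
    return [r.to_row() for r in reports]


def _gsea_rows(results) -> list[dict]:
    return [
        {
            "set_name": r.set_name,
            "es": r.es,
            "nes": r.nes,
            "p_nominal": r.p_nominal,
            "fdr_q": r.fdr_q,
            "direction": r.direction,
            "n_members": r.n_members_in_universe,
        }
        for r in results
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full inspect-correct-retest workflow; returns the summary dict
    (also written to ``<outdir>/summary.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    stage = "setup"
    timings: dict[str, float] = {}
    try:
        t0 = time.perf_counter()
        logger.info("lenbias %s starting; config=%s", __version__, config.resolved())

        stage = "load"
        cm = read_counts(config.counts, config.design)
        ann = read_annotation(config.annotation)
        sets = read_gmt(config.gmt)
        cm, n_dropped = align_to_annotation(cm, ann)
        cm = filter_expressed(cm, config.cpm_threshold)
        timings[stage] = time.perf_counter() - t0

        stage = "diagnose"
        t0 = time.perf_counter()
        pre_reports = replicate_pair_scan(
            cm, ann, config.normalizer, flag_p=config.flag_p
        )
        strongest = pre_reports[0]
        flagged = any(r.flagged for r in pre_reports)
        timings[stage] = time.perf_counter() - t0

        post_reports = None
        corrected_expr = None
        if flagged:
            stage = "correct"
            t0 = time.perf_counter()
            corrected_expr, _fit = covariate_normalize(
                cm, ann, config.covariates, config.n_knots
            )
            post_reports = replicate_pair_scan(
                cm,
                ann,
                "covariate",
                covariates=config.covariates,
                n_knots=config.n_knots,
                flag_p=config.flag_p,
            )
            timings[stage] = time.perf_counter() - t0

        stage = "gsea"
        t0 = time.perf_counter()
        # rank genes by the strongest replicate pair's fold change
        _, pair = strongest.comparison_label.split(":", 1)
        sample_a, sample_b = pair.split("_vs_")
        expr_pre = normalize_counts(cm, ann, config.normalizer)
        fc_pre = log2_fold_change(expr_pre, [sample_a], [sample_b])
        gsea_pre = gsea_preranked(
            ranked_from_scores(fc_pre.log2_fc),
            sets,
            n_perm=config.gsea_nperm,
            min_size=config.gsea_min_size,
            max_size=config.gsea_max_size,
            seed=config.seed,
        )
        gsea_post = None
        if corrected_expr is not None:
            diff = corrected_expr.values[sample_a] - corrected_expr.values[sample_b]
            gsea_post = gsea_preranked(
                ranked_from_scores(diff),
                sets,
                n_perm=config.gsea_nperm,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
                seed=config.seed,
            )
        timings[stage] = time.perf_counter() - t0

        stage = "settest"
        t0 = time.perf_counter()
        settest_rows = []
        conditions = cm.conditions()
        if len(conditions) >= 2 and all(
            len(cm.samples_of(c)) >= 2 for c in conditions[:2]
        ):
            log2_expr = corrected_expr
            if log2_expr is None:
                vals = np.log2(expr_pre.values + 0.5)
                from .data import ExpressionMatrix

                log2_expr = ExpressionMatrix(vals, "log2")
            res = vif_adjusted_set_test(
                log2_expr,
                cm.samples_of(conditions[1]),
                cm.samples_of(conditions[0]),
                sets,
            )
            settest_rows = [
                {
                    "set_name": r.set_name,
                    "mean_rho": r.mean_rho,
                    "vif": r.vif,
                    "statistic": r.statistic,
                    "p_two_sided": r.p_two_sided,
                    "n_members": r.n_members,
                }
                for r in res
            ]
        timings[stage] = time.perf_counter() - t0

        stage = "summarize"
        called_pre = {
            r["set_name"]
            for r in _gsea_rows(gsea_pre)
            if r["fdr_q"] < config.fdr_threshold
        }
        called_post = (
            {
                r["set_name"]
                for r in _gsea_rows(gsea_post)
                if r["fdr_q"] < config.fdr_threshold
            }
            if gsea_post is not None
            else None
        )
        changed = (
            sorted(called_pre ^ called_post) if called_post is not None else []
        )
        summary = {
            "config": config.resolved(),
            "version": __version__,
            "n_genes_analyzed": int(len(cm.gene_ids)),
            "n_genes_dropped_no_annotation": int(n_dropped),
            "flagged_pre_correction": bool(flagged),
            "strongest_pair": strongest.to_row(),
            "replicate_pairs_pre": _report_rows(pre_reports),
            "replicate_pairs_post": (
                _report_rows(post_reports) if post_reports is not None else None
            ),
            "flagged_post_correction": (
                any(r.flagged for r in post_reports)
                if post_reports is not None
                else None
            ),
            "removal_criterion_met": (
                bool(abs(post_reports[0].rho_length) < config.removal_rho)
                if post_reports is not None
                else None
            ),
            "gsea_pre": _gsea_rows(gsea_pre),
            "gsea_post": _gsea_rows(gsea_post) if gsea_post is not None else None,
            "sets_called_pre": sorted(called_pre),
            "sets_called_post": sorted(called_post) if called_post is not None else None,
            "changed_calls": changed,
            "settest": settest_rows,
        }
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        logger.info("stage timings: %s", {k: round(v, 3) for k, v in timings.items()})
        return summary
    except Exception as exc:  # noqa: BLE001 - stage context matters to callers
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def make_synth(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a synthetic dataset and write it in the pipeline's input
    formats (counts/design/annotation TSV, GMT, ground-truth JSON)."""
    cm, ann, sets, truth = generate_dataset(config)
    return write_dataset(cm, ann, sets, truth, outdir)
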