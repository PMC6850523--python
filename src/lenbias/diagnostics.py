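"""Detection of sample-specific length (and GC) bias in fold changes.

A dataset is screened by correlating per-gene log2 fold change with gene
length (Spearman, two-sided p from the t approximation) for the comparison
of interest and for every within-condition replicate pair; replicate pairs
measure purely technical effects, so any length–FC coupling there is bias.
A comparison is flagged when p < 1e-8. Length-bin profiles summarize how
the effect bends expression along the length axis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    CountMatrix,
    ExpressionMatrix,
    FoldChangeTable,
    GeneAnnotation,
    log2_fold_change,
)
from .norm import covariate_normalize, normalize_counts

logger = logging.getLogger("lenbias")

FLAG_P = 1e-8  # significance threshold for declaring length-FC coupling

__all__ = [
    "BiasReport",
    "spearman_with_p",
    "length_fc_bias",
    "replicate_pair_scan",
    "length_bin_profile",
    "FLAG_P",
]


@dataclass
class BiasReport:
    comparison_label: str
    rho_length: float
    p_length: float
    n_genes: int
    rho_gc: float | None = None
    p_gc: float | None = None
    flagged: bool = False
    bin_summaries: pd.DataFrame | None = None

    def to_row(self) -> dict:
        return {
            "comparison": self.comparison_label,
            "rho_length": self.rho_length,
            "p_length": self.p_length,
            "rho_gc": self.rho_gc,
            "p_gc": self.p_gc,
            "n_genes": self.n_genes,
            "flagged": self.flagged,
        }


def spearman_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (average ranks) with a two-sided t-approximation p-value.

    t = rho * sqrt((n-2) / (1-rho^2)) on n-2 degrees of freedom; |rho| = 1
    reports the smallest positive float rather than p = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 5:
        raise ValueError("need n >= 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-12:  # identical rank orders up to rounding
        return float(np.sign(rho)), float(np.finfo(float).tiny)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, max(p, float(np.finfo(float).tiny))


def length_fc_bias(
    fc: FoldChangeTable,
    ann: GeneAnnotation,
    covariate: str = "length",
    flag_p: float = FLAG_P,
) -> BiasReport:
    """Correlate log2 fold change with gene length (or GC) and flag bias.

    Length enters on the log10 scale for reporting; the rank statistic is
    unaffected by monotone transforms. Fewer than 100 genes triggers a
    warning but still produces a report.
    """
    genes = fc.gene_ids
    missing = [g for g in genes if g not in ann.table.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} has no annotation")
    if len(genes) < 100:
        warnings.warn("fewer than 100 genes; bias estimate is unstable")
    if covariate == "length":
        x = np.log10(ann.lengths(genes).to_numpy(float))
    elif covariate == "gc":
        gc = ann.gc(genes)
        if gc.isna().any():
            raise ValueError("gc covariate requested but gc_fraction missing")
        x = gc.to_numpy(float)
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    rho, p = spearman_with_p(x, fc.log2_fc.to_numpy(float))
    report = BiasReport(
        comparison_label=fc.comparison_label,
        rho_length=rho if covariate == "length" else np.nan,
        p_length=p if covariate == "length" else np.nan,
        n_genes=len(genes),
        flagged=bool(p < flag_p),
    )
    if covariate == "gc":
        report.rho_gc, report.p_gc = rho, p
    return report


def _pair_fold_changes(
    cm: CountMatrix,
    ann: GeneAnnotation | None,
    normalizer: str,
    covariates: Sequence[str],
    n_knots: int,
) -> list[tuple[str, FoldChangeTable]]:
    """Single-sample-vs-single-sample FCs for all within-condition pairs."""
    pairs: list[tuple[str, str, str]] = []
    for cond in cm.conditions():
        samples = sorted(cm.samples_of(cond))
        for a, b in combinations(samples, 2):
            pairs.append((cond, a, b))
    if not pairs:
        raise ValueError("no condition has >= 2 replicates")

    out: list[tuple[str, FoldChangeTable]] = []
    if normalizer == "covariate":
        if ann is None:
            raise ValueError("covariate normalizer requires an annotation")
        expr, _ = covariate_normalize(cm, ann, covariates, n_knots)
        for cond, a, b in pairs:
            diff = expr.values[a] - expr.values[b]
            mean_ab = (2.0 ** expr.values[a] + 2.0 ** expr.values[b]) / 2.0
            fc = FoldChangeTable(
                pd.DataFrame({"log2_fc": diff, "mean_abundance": mean_ab}),
                f"{cond}:{a}_vs_{b}",
            )
            out.append((cond, fc))
    else:
        expr = normalize_counts(cm, ann, normalizer)
        for cond, a, b in pairs:
            fc = log2_fold_change(
                expr, [a], [b], comparison_label=f"{cond}:{a}_vs_{b}"
            )
            out.append((cond, fc))
    return out


def replicate_pair_scan(
    cm: CountMatrix,
    ann: GeneAnnotation,
    normalizer: str = "rpkm",
    covariates: Sequence[str] = ("length",),
    n_knots: int = 5,
    flag_p: float = FLAG_P,
    with_gc: bool = False,
) -> list[BiasReport]:
    """Length–FC bias reports for every within-condition replicate pair.

    Fold changes are single sample vs single sample (no averaging), so each
    report isolates the technical difference between two replicates. The
    list is sorted by |rho_length| descending (ties by label), so the first
    entry is the strongest pair.
    """
    reports: list[BiasReport] = []
    for _, fc in _pair_fold_changes(cm, ann, normalizer, covariates, n_knots):
        rep = length_fc_bias(fc, ann, "length", flag_p)
        if with_gc and ann.has_gc():
            gc_rep = length_fc_bias(fc, ann, "gc", flag_p)
            rep.rho_gc, rep.p_gc = gc_rep.rho_gc, gc_rep.p_gc
        reports.append(rep)
    reports.sort(key=lambda r: (-abs(r.rho_length), r.comparison_label))
    return reports


def length_bin_profile(
    expr: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    ann: GeneAnnotation,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Quartile summaries of expression in equal-size gene-length bins.

    Genes are sorted by annotated length (ties by gene id) and partitioned
    into ``n_bins`` contiguous bins whose sizes differ by at most one. For
    each bin the mean length and the quartiles of expression in each sample
    and of their difference (a - b) are reported.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    genes = expr.gene_ids
    if n_bins > len(genes):
        raise ValueError("more bins than genes")
    for s in (sample_a, sample_b):
        if s not in expr.sample_ids:
            raise ValueError(f"unknown sample id: {s!r}")
    lengths = ann.lengths(genes)
    order = sorted(genes, key=lambda g: (lengths[g], g))
    rows = []
    for i, chunk in enumerate(np.array_split(np.array(order), n_bins), start=1):
        a = expr.values.loc[chunk, sample_a].to_numpy(float)
        b = expr.values.loc[chunk, sample_b].to_numpy(float)
        diff = a - b
        row = {"bin": i, "n_genes": len(chunk), "mean_length": float(lengths[chunk].mean())}
        for tag, vec in (("a", a), ("b", b), ("diff", diff)):
            q1, q2, q3 = np.percentile(vec, [25, 50, 75])
            row[f"{tag}_q25"], row[f"{tag}_median"], row[f"{tag}_q75"] = (
                float(q1),
                float(q2),
                float(q3),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("bin")


def lowess_trend(
    fc: FoldChangeTable, ann: GeneAnnotation, frac: float = 0.3
) -> pd.DataFrame:
    """Lowess smooth of log2 FC against log10 length, for report plots only."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    x = np.log10(ann.lengths(fc.gene_ids).to_numpy(float))
    y = fc.log2_fc.to_numpy(float)
    smoothed = lowess(y, x, frac=frac, return_sorted=True)
    return pd.DataFrame(smoothed, columns=["log10_length", "log2_fc_trend"])
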