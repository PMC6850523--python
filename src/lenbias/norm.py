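"""Between-sample normalization schemes and the covariate-aware corrector.

Implements the six classic scale/quantile normalizations (cpm, RPKM,
RPKM+quantile, TMM, RLE, RLE+RPKM, UQ+RPKM) plus a covariate corrector that
removes sample-specific systematic effects of gene length (and, optionally,
GC content) by per-sample median spline regression followed by full quantile
normalization. Scale factors follow the convention that the geometric mean
of the factors over samples equals one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountMatrix, ExpressionMatrix, GeneAnnotation, cpm_values

logger = logging.getLogger("lenbias")

__all__ = [
    "ScaleFactors",
    "CovariateFit",
    "cpm",
    "rpkm",
    "quantile_normalize",
    "tmm_factors",
    "rle_factors",
    "uq_factors",
    "apply_factors",
    "covariate_normalize",
    "normalize_counts",
    "NORMALIZERS",
]


@dataclass
class ScaleFactors:
    """Per-sample multiplicative size factors, geometric mean 1."""

    factors: pd.Series
    method: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("scale factors must be positive")


def _rescale_geomean(f: pd.Series) -> pd.Series:
    return f / np.exp(np.log(f).mean())


# ---------------------------------------------------------------------------
# simple per-library normalizations


def cpm(cm: CountMatrix) -> ExpressionMatrix:
    """Counts per million: count * 1e6 / N_s."""
    return ExpressionMatrix(cpm_values(cm), "linear")


def rpkm(cm: CountMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Reads per kilobase per million: count * 1e9 / (N_s * L_g)."""
    missing = [g for g in cm.gene_ids if g not in ann.table.index]
    if missing:
        raise ValueError(f"gene {missing[0]!r} has no length annotation")
    libs = cm.library_sizes
    if (libs == 0).any():
        raise ValueError("zero library size")
    lengths = ann.lengths(cm.gene_ids)
    vals = cm.counts * 1e9
    vals = vals.div(libs, axis=1).div(lengths, axis=0)
    return ExpressionMatrix(vals, "linear")


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Full quantile normalization.

    Each column's sorted values are replaced by the row-wise mean over the
    sorted columns; tied values within a column receive the mean of the
    reference values their rank span covers, so within-column order is
    preserved.
    """
    vals = expr.values.to_numpy(float)
    n, s = vals.shape
    if s < 2:
        raise ValueError("quantile normalization requires >= 2 samples")
    order = np.argsort(vals, axis=0, kind="stable")
    ref = np.take_along_axis(vals, order, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(s):
        assigned = np.empty(n)
        assigned[order[:, j]] = ref
        # average the assigned reference values over ties
        uniq, inverse = np.unique(vals[:, j], return_inverse=True)
        sums = np.bincount(inverse, weights=assigned, minlength=len(uniq))
        counts = np.bincount(inverse, minlength=len(uniq))
        out[:, j] = (sums / counts)[inverse]
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.gene_ids, columns=expr.sample_ids),
        expr.scale,
    )


# ---------------------------------------------------------------------------
# scale-factor methods


def tmm_factors(
    cm: CountMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    min_genes: int = 10,
) -> ScaleFactors:
    """Trimmed mean of M-values size factors.

    The reference sample is the column whose upper quartile of cpm is closest
    to the mean upper quartile. For each sample k against the reference r,
    over genes with positive counts in both, M_g = log2((y_gk/N_k)/(y_gr/N_r))
    and A_g = 0.5*log2((y_gk/N_k)*(y_gr/N_r)); genes in the top/bottom
    ``trim_m`` fraction by M-rank and ``trim_a`` fraction by A-rank are
    dropped (rank bounds floor(n*trim)+1 .. n-floor(n*trim), average ranks),
    and the factor is 2 to the precision-weighted mean of the remaining M_g
    with weights 1/var, var = (N_k-y_gk)/(N_k*y_gk) + (N_r-y_gr)/(N_r*y_gr).
    Factors are rescaled to geometric mean 1.
    """
    if len(cm.sample_ids) < 2:
        raise ValueError("TMM requires >= 2 samples")
    counts = cm.counts.to_numpy(float)
    libs = cm.library_sizes.to_numpy(float)
    cpm_mat = counts * 1e6 / libs
    uq = np.quantile(cpm_mat, 0.75, axis=0)
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(len(cm.sample_ids))
    for j in range(len(cm.sample_ids)):
        if j == ref_j:
            continue
        mask = (counts[:, j] > 0) & (counts[:, ref_j] > 0)
        yk, yr = counts[mask, j], counts[mask, ref_j]
        nk, nr = libs[j], libs[ref_j]
        m = np.log2((yk / nk) / (yr / nr))
        a = 0.5 * np.log2((yk / nk) * (yr / nr))
        n = len(m)
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        keep = (
            (rank_m >= lo_m)
            & (rank_m <= n + 1 - lo_m)
            & (rank_a >= lo_a)
            & (rank_a <= n + 1 - lo_a)
        )
        if keep.sum() < min_genes:
            raise ValueError(
                f"only {int(keep.sum())} genes remain after TMM trimming; "
                "use smaller trim fractions"
            )
        w = 1.0 / ((nk - yk) / (nk * yk) + (nr - yr) / (nr * yr))
        factors[j] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    return ScaleFactors(
        _rescale_geomean(pd.Series(factors, index=cm.sample_ids)), "tmm"
    )


def rle_factors(cm: CountMatrix) -> ScaleFactors:
    """Relative log expression size factors (median ratio to the per-gene
    geometric mean), over genes positive in all samples."""
    counts = cm.counts.to_numpy(float)
    mask = (counts > 0).all(axis=1)
    if not mask.any():
        raise ValueError("RLE requires at least one gene positive in all samples")
    pos = counts[mask]
    geo = np.exp(np.log(pos).mean(axis=1))
    factors = np.median(pos / geo[:, None], axis=0)
    return ScaleFactors(
        _rescale_geomean(pd.Series(factors, index=cm.sample_ids)), "rle"
    )


def uq_factors(cm: CountMatrix) -> ScaleFactors:
    """Upper-quartile size factors: the 75th percentile of each sample's
    nonzero counts divided by its library size, rescaled to geometric mean 1.
    Percentiles interpolate linearly between order statistics."""
    libs = cm.library_sizes.to_numpy(float)
    factors = np.empty(len(cm.sample_ids))
    for j, s in enumerate(cm.sample_ids):
        nz = cm.counts[s].to_numpy(float)
        nz = nz[nz > 0]
        if len(nz) < 4:
            raise ValueError(f"sample {s!r} has fewer than 4 nonzero counts")
        factors[j] = np.quantile(nz, 0.75) / libs[j]
    return ScaleFactors(
        _rescale_geomean(pd.Series(factors, index=cm.sample_ids)), "uq"
    )


def apply_factors(
    cm: CountMatrix,
    factors: ScaleFactors,
    ann: GeneAnnotation | None = None,
) -> ExpressionMatrix:
    """cpm (or RPKM when an annotation is given) computed with effective
    library sizes N_s' = N_s * factor_s."""
    for s in cm.sample_ids:
        if s not in factors.factors.index:
            raise ValueError(f"no scale factor for sample {s!r}")
    eff = cm.library_sizes * factors.factors.loc[cm.sample_ids]
    if ann is None:
        vals = cm.counts * 1e6 / eff
    else:
        missing = [g for g in cm.gene_ids if g not in ann.table.index]
        if missing:
            raise ValueError(f"gene {missing[0]!r} has no length annotation")
        vals = (cm.counts * 1e9).div(eff, axis=1).div(ann.lengths(cm.gene_ids), axis=0)
    return ExpressionMatrix(vals, "linear")


# ---------------------------------------------------------------------------
# covariate-aware correction


@dataclass
class CovariateFit:
    """Per-sample spline fits of log2 expression on gene covariates.

    Attributes
    ----------
    covariates : tuple of covariate names used ("length" -> log10 bp).
    knots : dict covariate -> knot locations (quantiles of the covariate).
    coefficients : DataFrame, samples x regression parameters.
    fitted : DataFrame, genes x samples systematic component h_s(g).
    residual_mad : Series, per-sample median absolute residual.
    """

    covariates: tuple[str, ...]
    knots: dict[str, np.ndarray]
    coefficients: pd.DataFrame
    fitted: pd.DataFrame
    residual_mad: pd.Series


def _natural_cubic_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (no intercept): x plus K-2 curvature terms."""
    last = knots[-1]

    def d(k: float) -> np.ndarray:
        return (
            np.clip(x - k, 0, None) ** 3 - np.clip(x - last, 0, None) ** 3
        ) / (last - k)

    cols = [x]
    for k in knots[:-2]:
        cols.append(d(k) - d(knots[-2]))
    return np.column_stack(cols)


def _covariate_design(
    ann: GeneAnnotation,
    gene_ids: pd.Index,
    covariates: Sequence[str],
    n_knots: int,
) -> tuple[np.ndarray, dict[str, np.ndarray], list[str]]:
    columns = [np.ones(len(gene_ids))]
    names = ["intercept"]
    knots_of: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "length":
            x = np.log10(ann.lengths(gene_ids).to_numpy(float))
        elif cov == "gc":
            gc = ann.gc(gene_ids)
            if gc.isna().any():
                raise ValueError("gc covariate requested but gc_fraction missing")
            x = gc.to_numpy(float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")
        if np.ptp(x) == 0:
            raise ValueError(f"covariate {cov!r} is constant")
        levels = np.arange(1, n_knots + 1) / (n_knots + 1)
        knots = np.unique(np.quantile(x, levels))
        if len(knots) < 3:
            raise ValueError(f"covariate {cov!r} too degenerate for a spline")
        knots_of[cov] = knots
        basis = _natural_cubic_basis(x, knots)
        columns.append(basis)
        names.extend(f"{cov}_s{i}" for i in range(basis.shape[1]))
    return np.column_stack(columns), knots_of, names


def covariate_normalize(
    cm: CountMatrix,
    ann: GeneAnnotation,
    covariates: Sequence[str] = ("length",),
    n_knots: int = 5,
) -> tuple[ExpressionMatrix, CovariateFit]:
    """Remove sample-specific covariate effects from log2 counts.

    Per sample, a median (0.5-quantile) regression on a natural cubic spline
    basis of the selected covariates (log10 length and/or GC fraction; knots
    at equally spaced quantiles) estimates the sample-specific systematic
    deviation h_s(g) - hbar(g), where hbar is the across-sample mean curve.
    The regression is fit to gene-centered values, log2(count_gs + 0.5)
    minus the gene's across-sample mean: centering removes the (large,
    sample-shared) between-gene baseline spread from the residuals, so the
    per-sample curve estimate tracks only the sample-specific trend. Values
    are corrected to log2(count + 0.5) - (h_s(g) - hbar(g)) and then fully
    quantile-normalized across samples.
    """
    from statsmodels.regression.quantile_regression import QuantReg

    covariates = tuple(covariates)
    if not covariates:
        raise ValueError("at least one covariate required")
    X, knots_of, names = _covariate_design(ann, cm.gene_ids, covariates, n_knots)
    y = np.log2(cm.counts.to_numpy(float) + 0.5)
    centered = y - y.mean(axis=1, keepdims=True)
    fitted = np.empty_like(y)
    coefs = np.empty((len(cm.sample_ids), X.shape[1]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j in range(y.shape[1]):
            res = QuantReg(centered[:, j], X).fit(q=0.5, max_iter=2000)
            coefs[j] = res.params
            fitted[:, j] = X @ res.params
    if not np.all(np.isfinite(fitted)):
        raise ValueError("covariate fit produced non-finite values")
    corrected = y - (fitted - fitted.mean(axis=1, keepdims=True))
    expr = ExpressionMatrix(
        pd.DataFrame(corrected, index=cm.gene_ids, columns=cm.sample_ids), "log2"
    )
    expr = quantile_normalize(expr)
    fit = CovariateFit(
        covariates=covariates,
        knots=knots_of,
        coefficients=pd.DataFrame(coefs, index=cm.sample_ids, columns=names),
        fitted=pd.DataFrame(fitted, index=cm.gene_ids, columns=cm.sample_ids),
        residual_mad=pd.Series(
            np.median(np.abs(y - fitted), axis=0), index=cm.sample_ids
        ),
    )
    return expr, fit


# ---------------------------------------------------------------------------
# dispatcher used by diagnostics and the CLI

NORMALIZERS = (
    "cpm",
    "rpkm",
    "rpkm-qnorm",
    "tmm",
    "rle",
    "rle-rpkm",
    "uq-rpkm",
)


def normalize_counts(
    cm: CountMatrix,
    ann: GeneAnnotation | None,
    method: str,
) -> ExpressionMatrix:
    """Linear-scale normalized expression under one of the named schemes."""
    needs_ann = method in ("rpkm", "rpkm-qnorm", "rle-rpkm", "uq-rpkm")
    if needs_ann and ann is None:
        raise ValueError(f"normalizer {method!r} requires a gene annotation")
    if method == "cpm":
        return cpm(cm)
    if method == "rpkm":
        return rpkm(cm, ann)
    if method == "rpkm-qnorm":
        return quantile_normalize(rpkm(cm, ann))
    if method == "tmm":
        return apply_factors(cm, tmm_factors(cm))
    if method == "rle":
        return apply_factors(cm, rle_factors(cm))
    if method == "rle-rpkm":
        return apply_factors(cm, rle_factors(cm), ann)
    if method == "uq-rpkm":
        return apply_factors(cm, uq_factors(cm), ann)
    raise ValueError(f"unknown normalizer {method!r}")
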