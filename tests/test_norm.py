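"""Normalization schemes against hand examples and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lenbias import (
    ExpressionMatrix,
    SynthConfig,
    apply_factors,
    covariate_normalize,
    cpm,
    generate_dataset,
    quantile_normalize,
    rle_factors,
    rpkm,
    tmm_factors,
    uq_factors,
)
from lenbias.diagnostics import replicate_pair_scan

from conftest import make_annotation, make_counts


def expr_of(values):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"g{i+1}" for i in range(values.shape[0])],
            columns=[f"s{j+1}" for j in range(values.shape[1])],
        ),
        "linear",
    )


# ---------------------------------------------------------------------------
# cpm / rpkm


def test_cpm_direct_value():
    mat = np.zeros((2, 1), dtype=int)
    mat[0, 0] = 10
    mat[1, 0] = 1_000_000 - 10
    cm = make_counts(mat)
    assert cpm(cm).values.iloc[0, 0] == pytest.approx(10.0)


def test_rpkm_direct_value():
    mat = np.array([[100], [1_000_000 - 100]])
    cm = make_counts(mat)
    ann = make_annotation([2000, 1000])
    out = rpkm(cm, ann)
    assert out.values.iloc[0, 0] == pytest.approx(100 * 1e9 / (1e6 * 2000))  # 50
    assert out.values.iloc[1, 0] > 0


def test_rpkm_zero_count_and_scale_invariance():
    mat = np.array([[0, 4], [10, 20], [90, 176]])
    cm = make_counts(mat)
    ann = make_annotation([500, 1000, 1500])
    out1 = rpkm(cm, ann).values
    out2 = rpkm(make_counts(mat * 2), ann).values
    assert out1.iloc[0, 0] == 0
    assert np.allclose(out1, out2)


def test_rpkm_missing_length_names_gene():
    cm = make_counts([[1], [1]])
    ann = make_annotation([100], gene_ids=["g1"])
    with pytest.raises(ValueError, match="g2"):
        rpkm(cm, ann)


# ---------------------------------------------------------------------------
# quantile normalization


def test_qnorm_hand_example():
    out = quantile_normalize(expr_of([[1, 6], [3, 2]])).values.to_numpy()
    assert np.allclose(out, [[1.5, 4.5], [4.5, 1.5]])


def test_qnorm_identical_columns_unchanged():
    vals = [[3, 3], [1, 1], [9, 9]]
    out = quantile_normalize(expr_of(vals)).values.to_numpy()
    assert np.allclose(out, vals)


def test_qnorm_columns_share_sorted_values():
    rng = np.random.default_rng(3)
    vals = rng.gamma(2, 10, (40, 4))
    out = quantile_normalize(expr_of(vals)).values.to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(1, 4):
        assert np.allclose(np.sort(out[:, j]), ref)


def test_qnorm_ties_get_mean_of_spanned_references():
    # column 1 has a tie spanning reference ranks 1-2
    out = quantile_normalize(expr_of([[2, 1], [2, 3], [5, 9]])).values.to_numpy()
    ref = [(1 + 2) / 2, (2 + 3) / 2, (5 + 9) / 2]  # [1.5, 2.5, 7.0]
    assert np.allclose(out[:, 1], ref)
    assert out[0, 0] == pytest.approx((1.5 + 2.5) / 2)
    assert out[1, 0] == pytest.approx((1.5 + 2.5) / 2)
    assert out[2, 0] == pytest.approx(7.0)


def test_qnorm_monotone_within_columns():
    rng = np.random.default_rng(4)
    vals = rng.normal(0, 1, (30, 3))
    out = quantile_normalize(
        ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(30)], columns=list("abc")),
            "log2",
        )
    ).values.to_numpy()
    for j in range(3):
        order = np.argsort(vals[:, j], kind="stable")
        assert (np.diff(out[order, j]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# TMM


def tmm_bruteforce(counts, trim_m=0.3, trim_a=0.05):
    """Independent enumeration of the trimmed weighted mean for 2 samples,
    column 2 vs reference column 1."""
    counts = np.asarray(counts, float)
    nk, nr = counts[:, 1].sum(), counts[:, 0].sum()
    rows = [(yk, yr) for yk, yr in zip(counts[:, 1], counts[:, 0]) if yk > 0 and yr > 0]
    m_vals = [np.log2((yk / nk) / (yr / nr)) for yk, yr in rows]
    a_vals = [0.5 * np.log2((yk / nk) * (yr / nr)) for yk, yr in rows]
    n = len(rows)
    lo_m = int(np.floor(n * trim_m)) + 1
    lo_a = int(np.floor(n * trim_a)) + 1
    rank_m = stats.rankdata(m_vals)
    rank_a = stats.rankdata(a_vals)
    keep = [
        i
        for i in range(n)
        if lo_m <= rank_m[i] <= n + 1 - lo_m and lo_a <= rank_a[i] <= n + 1 - lo_a
    ]
    num = den = 0.0
    for i in keep:
        yk, yr = rows[i]
        w = 1.0 / ((nk - yk) / (nk * yk) + (nr - yr) / (nr * yr))
        num += w * m_vals[i]
        den += w
    return 2 ** (num / den)


def test_tmm_identical_columns_unity():
    vals = np.tile(np.arange(1, 13)[:, None], (1, 3)) * 10
    f = tmm_factors(make_counts(vals), min_genes=1).factors
    assert np.allclose(f, 1.0)


def test_tmm_depth_only_difference_unity():
    rng = np.random.default_rng(5)
    col = rng.integers(5, 500, 40)
    vals = np.column_stack([col, 2 * col])
    f = tmm_factors(make_counts(vals), min_genes=1).factors
    assert np.allclose(f, 1.0)


def test_tmm_matches_bruteforce_oracle():
    vals = np.array(
        [
            [120, 60],
            [35, 150],
            [500, 480],
            [88, 90],
            [12, 44],
            [260, 210],
            [75, 300],
            [44, 18],
        ]
    )
    cm = make_counts(vals)
    got = tmm_factors(cm, min_genes=1).factors
    raw = tmm_bruteforce(vals)
    # implementation rescales to geometric mean 1: factors (1, raw)/sqrt(raw)
    expected = np.array([1.0, raw]) / np.sqrt(raw)
    # reference choice: sample with upper quartile of cpm closest to mean
    uq = np.quantile(vals * 1e6 / vals.sum(0), 0.75, axis=0)
    assert np.argmin(np.abs(uq - uq.mean())) == 0
    assert np.allclose(got.to_numpy(), expected, atol=1e-12)


def test_tmm_row_order_invariance():
    rng = np.random.default_rng(6)
    vals = rng.integers(1, 400, (30, 3))
    cm1 = make_counts(vals)
    perm = rng.permutation(30)
    cm2 = make_counts(vals[perm], gene_ids=[f"p{i}" for i in range(30)])
    f1 = tmm_factors(cm1, min_genes=1).factors.to_numpy()
    f2 = tmm_factors(cm2, min_genes=1).factors.to_numpy()
    assert np.allclose(f1, f2)


def test_tmm_too_few_genes_errors():
    cm = make_counts([[5, 6], [7, 8], [9, 10]])
    with pytest.raises(ValueError, match="trim"):
        tmm_factors(cm, min_genes=10)


# ---------------------------------------------------------------------------
# RLE / UQ


def test_rle_hand_example():
    f = rle_factors(make_counts([[2, 8], [4, 16], [1, 4]])).factors
    assert np.allclose(f.to_numpy(), [0.5, 2.0])


def test_rle_identical_columns_unity():
    f = rle_factors(make_counts([[3, 3], [8, 8]])).factors
    assert np.allclose(f, 1.0)


def test_rle_column_scaling_equivariance():
    base = np.array([[20, 20], [50, 50], [7, 7]])
    scaled = base.copy()
    scaled[:, 1] *= 6
    f = rle_factors(make_counts(scaled)).factors
    assert f["s2"] / f["s1"] == pytest.approx(6.0)


def test_rle_requires_all_positive_gene():
    with pytest.raises(ValueError, match="positive"):
        rle_factors(make_counts([[0, 5], [5, 0]]))


def test_uq_identical_columns_unity_and_percentile_convention():
    col = np.concatenate([np.arange(1, 101), [0, 0]])
    f = uq_factors(make_counts(np.column_stack([col, col]))).factors
    assert np.allclose(f, 1.0)
    # frozen interpolation convention for the 75th percentile of 1..100
    assert np.quantile(np.arange(1, 101), 0.75) == pytest.approx(75.25)


def test_uq_rejects_sparse_sample():
    with pytest.raises(ValueError, match="nonzero"):
        uq_factors(make_counts([[1, 1], [0, 1], [0, 1], [0, 1], [0, 2]]))


# ---------------------------------------------------------------------------
# apply_factors


def test_apply_unit_factors_equals_cpm_rpkm():
    vals = np.array([[10, 40], [90, 60]])
    cm = make_counts(vals)
    ann = make_annotation([1000, 4000])
    from lenbias.norm import ScaleFactors

    unit = ScaleFactors(pd.Series([1.0, 1.0], index=cm.sample_ids), "unit")
    assert np.allclose(apply_factors(cm, unit).values, cpm(cm).values)
    assert np.allclose(apply_factors(cm, unit, ann).values, rpkm(cm, ann).values)


def test_apply_factor_two_halves_values():
    cm = make_counts([[10, 10], [30, 30]])
    from lenbias.norm import ScaleFactors

    f = ScaleFactors(pd.Series([1.0, 2.0], index=cm.sample_ids), "x")
    out = apply_factors(cm, f).values
    ref = cpm(cm).values
    assert np.allclose(out["s1"], ref["s1"])
    assert np.allclose(out["s2"], ref["s2"] / 2.0)


def test_rle_then_rpkm_composes_hand_examples():
    cm = make_counts([[2, 8], [4, 16], [1, 4]])
    ann = make_annotation([1000, 2000, 500])
    out = apply_factors(cm, rle_factors(cm), ann).values
    plain = rpkm(cm, ann).values
    assert np.allclose(out["s1"], plain["s1"] * 2.0)  # factor 0.5 doubles
    assert np.allclose(out["s2"], plain["s2"] / 2.0)  # factor 2 halves


# ---------------------------------------------------------------------------
# covariate corrector


def small_config(**kw):
    defaults = dict(n_genes=3000, seed=11)
    defaults.update(kw)
    return SynthConfig(**defaults)


def test_covariate_normalize_no_bias_is_neutral():
    # with no injected bias, correction should match plain quantile-normalized
    # log2 data up to fitting noise; full-scale universe for the +/-0.02 band
    from itertools import combinations

    from lenbias.diagnostics import spearman_with_p

    cm, ann, _, _ = generate_dataset(small_config(n_genes=12100, bias_sd=0.0))
    log2_qn = quantile_normalize(
        ExpressionMatrix(np.log2(cpm(cm).values + 0.5), "log2")
    )
    corrected, _ = covariate_normalize(cm, ann, ("length",))
    logl = np.log10(ann.lengths(cm.gene_ids).to_numpy(float))
    deltas = []
    for cond in cm.conditions():
        for a, b in combinations(sorted(cm.samples_of(cond)), 2):
            rho_plain, _ = spearman_with_p(
                logl, (log2_qn.values[a] - log2_qn.values[b]).to_numpy()
            )
            rho_corr, _ = spearman_with_p(
                logl, (corrected.values[a] - corrected.values[b]).to_numpy()
            )
            # stays well below the 0.05 removal threshold for every pair
            assert abs(rho_corr) < 0.05
            deltas.append(abs(rho_corr - rho_plain))
    # typical pair agrees with plain quantile-normalized data to ~fit noise
    assert np.median(deltas) < 0.02


def test_covariate_normalize_removes_length_bias():
    cm, ann, _, _ = generate_dataset(small_config(bias_sd=0.25, seed=3))
    pre = replicate_pair_scan(cm, ann, "rpkm")
    post = replicate_pair_scan(cm, ann, "covariate", covariates=("length",))
    assert abs(pre[0].rho_length) > 0.2
    assert abs(post[0].rho_length) < 0.05


def test_gc_only_correction_leaves_length_bias():
    cm, ann, _, _ = generate_dataset(small_config(bias_sd=0.25, seed=3))
    pre = replicate_pair_scan(cm, ann, "rpkm")
    post_gc = replicate_pair_scan(cm, ann, "covariate", covariates=("gc",))
    assert abs(post_gc[0].rho_length) > 0.5 * abs(pre[0].rho_length)


def test_covariate_normalize_errors():
    cm, ann, _, _ = generate_dataset(small_config())
    with pytest.raises(ValueError, match="unknown covariate"):
        covariate_normalize(cm, ann, ("phase",))
    ann_const = make_annotation(
        [1000] * len(cm.gene_ids), gene_ids=list(cm.gene_ids)
    )
    with pytest.raises(ValueError, match="constant"):
        covariate_normalize(cm, ann_const, ("length",))


def test_covariate_fit_reports_finite_curves():
    cm, ann, _, _ = generate_dataset(small_config())
    _, fit = covariate_normalize(cm, ann, ("length", "gc"))
    assert np.isfinite(fit.fitted.to_numpy()).all()
    assert set(fit.knots) == {"length", "gc"}
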