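"""Differential-expression engine: CPM, TMM, NB exact test, selection."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpair.de import (cpm, de_analysis, estimate_common_dispersion,
                        filter_low_expression, nb_exact_test, select_de,
                        tmm_factors, _exact_nb_pvalue)
from tests.conftest import make_count_matrix, nb_counts


# ---------------------------------------------------------------------- CPM

def test_cpm_direct_arithmetic():
    cm = make_count_matrix([[1], [1]], ["control"])
    assert cpm(cm).iloc[:, 0].tolist() == [5e5, 5e5]
    cm = make_count_matrix([[3], [7]], ["tumour"])
    assert cpm(cm).iloc[:, 0].tolist() == [3e5, 7e5]
    cm = make_count_matrix([[0], [10]], ["tumour"])
    assert cpm(cm).iloc[0, 0] == 0.0


def test_cpm_columns_sum_to_million():
    rng = np.random.default_rng(0)
    cm = make_count_matrix(rng.poisson(30, (50, 6)),
                           ["control"] * 3 + ["tumour"] * 3)
    assert cpm(cm).sum(axis=0).to_numpy() == pytest.approx([1e6] * 6)


def test_cpm_zero_library_names_sample():
    cm = make_count_matrix([[0, 5], [0, 5]], ["control", "tumour"])
    with pytest.raises(ValueError, match="s0"):
        cpm(cm)


# ------------------------------------------------------------------- filter

def test_filter_removes_all_zero_and_keeps_boundary():
    # library 1e6 so count == CPM; feature at exactly CPM 1 is kept
    values = np.zeros((3, 2), dtype=int)
    values[1] = [1, 1]
    values[2] = [999_999, 999_999]
    cm = make_count_matrix(values, ["control", "tumour"])
    kept = filter_low_expression(cm, cpm_threshold=1.0, min_samples=2)
    assert list(kept.feature_ids) == ["g1", "g2"]


def test_filter_count_by_direct_cpm():
    rng = np.random.default_rng(1)
    values = rng.poisson(40, (10, 4))
    values[[2, 5, 7]] = 0  # below threshold everywhere
    cm = make_count_matrix(values, ["control"] * 2 + ["tumour"] * 2)
    kept = filter_low_expression(cm, 1.0, min_samples=2)
    assert kept.counts.shape[0] == 7
    assert list(kept.feature_ids) == [f"g{i}" for i in range(10) if i not in (2, 5, 7)]


# ---------------------------------------------------------------------- TMM

def test_tmm_identical_columns_unit_factors():
    col = np.arange(1, 101)
    cm = make_count_matrix(np.c_[col, col], ["control", "tumour"])
    assert tmm_factors(cm).to_numpy() == pytest.approx([1.0, 1.0], abs=1e-12)


def test_tmm_pure_depth_scaling_cancels():
    rng = np.random.default_rng(2)
    col = rng.poisson(100, 300) + 1
    cm = make_count_matrix(np.c_[col, 3 * col], ["control", "tumour"])
    assert tmm_factors(cm).to_numpy() == pytest.approx([1.0, 1.0], abs=1e-9)


def tmm_oracle(df, ref, trim_m=0.30, trim_a=0.05):
    """Literal-formula reimplementation (per-sample loops, no vectorising)."""
    lib = df.sum(axis=0).astype(float)
    factors = {}
    for sample in df.columns:
        if sample == ref:
            factors[sample] = 1.0
            continue
        m_vals, a_vals, w_vals = [], [], []
        for g in df.index:
            yk, yr = df.loc[g, sample], df.loc[g, ref]
            if yk > 0 and yr > 0:
                pk, pr = yk / lib[sample], yr / lib[ref]
                m_vals.append(math.log2(pk / pr))
                a_vals.append(0.5 * math.log2(pk * pr))
                w_vals.append((lib[sample] - yk) / (lib[sample] * yk)
                              + (lib[ref] - yr) / (lib[ref] * yr))
        n = len(m_vals)
        rank_m = stats.rankdata(m_vals)
        rank_a = stats.rankdata(a_vals)
        lo_m, lo_a = math.floor(n * trim_m) + 1, math.floor(n * trim_a) + 1
        num = den = 0.0
        for i in range(n):
            if (lo_m <= rank_m[i] <= n + 1 - lo_m
                    and lo_a <= rank_a[i] <= n + 1 - lo_a):
                num += w_vals[i] * m_vals[i]
                den += w_vals[i]
        factors[sample] = 2.0 ** (num / den)
    f = pd.Series(factors).reindex(df.columns)
    return f / np.exp(np.log(f).mean())


def test_tmm_matches_literal_oracle():
    rng = np.random.default_rng(3)
    values = nb_counts(rng, rng.lognormal(4, 1, 200)[:, None], 0.2, (200, 4))
    cm = make_count_matrix(values, ["control"] * 2 + ["tumour"] * 2)
    got = tmm_factors(cm, ref_sample="s0")
    want = tmm_oracle(cm.counts, "s0")
    assert got.to_numpy() == pytest.approx(want.to_numpy(), abs=1e-8)


def test_tmm_geometric_mean_is_one():
    rng = np.random.default_rng(4)
    values = nb_counts(rng, 50.0, 0.3, (100, 5))
    cm = make_count_matrix(values, ["control"] * 2 + ["tumour"] * 3)
    f = tmm_factors(cm)
    assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-9)


# ------------------------------------------------------------ NB exact test

def binomial_exact_oracle(s1, s2, n1, n2):
    """Exhaustive conditional binomial two-sided p (the phi = 0 limit)."""
    total = s1 + s2
    p1 = Fraction(n1, n1 + n2)
    probs = [Fraction(math.comb(total, k)) * p1 ** k * (1 - p1) ** (total - k)
             for k in range(total + 1)]
    obs = probs[s1]
    return float(sum(p for p in probs if p <= obs))


@pytest.mark.parametrize("s1,s2,n1,n2", [
    (10, 10, 3, 3), (0, 12, 4, 4), (25, 25, 5, 5), (7, 30, 2, 6),
    (18, 3, 4, 2), (50, 0, 3, 3),
])
def test_exact_test_phi_zero_is_conditional_binomial(s1, s2, n1, n2):
    got = _exact_nb_pvalue(s1, s2, n1, n2, disp=0.0)
    assert got == pytest.approx(binomial_exact_oracle(s1, s2, n1, n2), abs=1e-10)


def test_exact_test_no_signal_p_near_one():
    # identical per-group normalised means, tiny dispersion
    assert _exact_nb_pvalue(500, 500, 5, 5, disp=1e-13) >= 0.9
    assert _exact_nb_pvalue(0, 0, 5, 5, disp=0.1) == 1.0


def test_exact_test_group_label_symmetry_and_order_invariance():
    rng = np.random.default_rng(5)
    values = nb_counts(rng, 80.0, 0.1, (40, 8))
    groups = ["control"] * 4 + ["tumour"] * 4
    cm = make_count_matrix(values, groups)
    res = nb_exact_test(cm, dispersion=0.1)
    # swap group labels: two-sided p unchanged, log2fc negated
    swapped = make_count_matrix(values, ["tumour"] * 4 + ["control"] * 4)
    res_sw = nb_exact_test(swapped, dispersion=0.1)
    assert res_sw["pvalue"].to_numpy() == pytest.approx(res["pvalue"].to_numpy())
    assert res_sw["log2fc"].to_numpy() == pytest.approx(-res["log2fc"].to_numpy())
    # permute feature order
    perm = rng.permutation(40)
    cm_perm = make_count_matrix(values[perm], groups,
                                features=[f"g{i}" for i in perm])
    res_perm = nb_exact_test(cm_perm, dispersion=0.1)
    assert res_perm.loc[res.index, "pvalue"].to_numpy() == pytest.approx(
        res["pvalue"].to_numpy())


def test_exact_test_requires_both_groups():
    cm = make_count_matrix([[5, 5]], ["control", "control"])
    with pytest.raises(ValueError):
        nb_exact_test(cm, dispersion=0.1)


def test_zero_total_group_is_an_error():
    values = np.array([[0, 0, 5, 6], [0, 0, 7, 8]])
    cm = make_count_matrix(values, ["control"] * 2 + ["tumour"] * 2)
    with pytest.raises(ValueError, match="control"):
        nb_exact_test(cm, dispersion=0.1)


def test_dispersion_estimate_recovers_truth():
    rng = np.random.default_rng(6)
    values = nb_counts(rng, rng.lognormal(4.5, 0.8, 800)[:, None], 0.15, (800, 12))
    cm = make_count_matrix(values, ["control"] * 6 + ["tumour"] * 6)
    est = estimate_common_dispersion(cm)
    assert est == pytest.approx(0.15, rel=0.25)


# ---------------------------------------------------------------- selection

def test_select_de_thresholds_are_strict():
    res = pd.DataFrame({
        "log2fc": [2.0, 1.0, -2.0, 1.5],
        "avg_log2cpm": 5.0,
        "pvalue": [1e-4] * 4,
        "fdr": [0.05, 0.01, 0.01, 0.049],
    }, index=["at_fdr", "at_lfc", "ok_down", "ok_up"])
    sel = select_de(res, fdr_max=0.05, lfc_min=1.0)
    assert list(sel.index) == ["ok_down", "ok_up"]
    assert sel["direction"].tolist() == ["down", "up"]


def test_select_de_needs_fdr_column():
    with pytest.raises(ValueError):
        select_de(pd.DataFrame({"log2fc": [1.0], "pvalue": [0.1]}))


def test_de_analysis_fdr_dominates_p_and_directions_match_sign():
    rng = np.random.default_rng(7)
    values = nb_counts(rng, 60.0, 0.1, (100, 10))
    cm = make_count_matrix(values, ["control"] * 5 + ["tumour"] * 5)
    res = de_analysis(cm)
    assert np.all(res["fdr"].to_numpy() >= res["pvalue"].to_numpy() - 1e-15)
    assert np.all((res["log2fc"] > 0) == (res["direction"] == "up"))
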