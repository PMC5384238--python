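"""Covariate-adjusted pair models: RPKM, M-values, Type-III correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpair.regression import (JOINT, adjust_pair_pvalues, beta_to_m,
                                fit_joint_model, fit_pair_model,
                                log_expression, results_frame, rpkm,
                                select_significant_negative)
from tests.conftest import make_count_matrix


# ------------------------------------------------------------------ scaling

def test_rpkm_direct_arithmetic():
    cm = make_count_matrix([[10], [999_990]], ["tumour"])
    lengths = pd.Series({"g0": 1000, "g1": 1000})
    out = rpkm(cm, lengths)
    assert out.iloc[0, 0] == pytest.approx(10.0)
    zero = make_count_matrix([[0], [100]], ["tumour"])
    assert rpkm(zero, lengths).iloc[0, 0] == 0.0


def test_rpkm_halves_when_library_doubles():
    lengths = pd.Series({"g0": 500, "g1": 500})
    a = rpkm(make_count_matrix([[50], [50]], ["tumour"]), lengths)
    b = rpkm(make_count_matrix([[50], [150]], ["tumour"]), lengths)
    assert b.iloc[0, 0] == pytest.approx(a.iloc[0, 0] / 2)


def test_rpkm_missing_length_names_feature():
    cm = make_count_matrix([[5], [5]], ["tumour"])
    with pytest.raises(ValueError, match="g1"):
        rpkm(cm, pd.Series({"g0": 100}))


def test_beta_to_m_closed_forms():
    assert beta_to_m(0.5) == 0.0
    assert beta_to_m(0.8) == pytest.approx(2.0)
    for b in (0.01, 0.2, 0.5, 0.73, 0.999):
        assert beta_to_m(b) + beta_to_m(1 - b) == pytest.approx(0.0, abs=1e-9)
    with pytest.warns(UserWarning):
        out = beta_to_m(np.array([0.5, np.nan]))
    assert np.isnan(out[1])


# ---------------------------------------------------------------- per-type

def frame(rng, n=80, slope=-0.5, cna_effect=0.0, met_effect=0.0, noise=0.5):
    mir = rng.normal(8, 1, n)
    cna = rng.choice([-2, -1, 0, 1, 2], n, p=[0.05, 0.1, 0.7, 0.1, 0.05])
    met = rng.normal(0, 1.5, n)
    gene = (10 + slope * mir + cna_effect * cna + met_effect * met
            + rng.normal(0, noise, n))
    return pd.DataFrame({"gene_expr": gene, "mir_expr": mir, "cna": cna,
                         "met_cg1": met},
                        index=[f"s{i}" for i in range(n)])


def test_simple_regression_correlation_is_pearson_r():
    rng = np.random.default_rng(0)
    d = frame(rng)[["gene_expr", "mir_expr"]]
    res = fit_pair_model(d, "m", "g", "TT")
    r, _ = stats.pearsonr(d["mir_expr"], d["gene_expr"])
    assert res.correlation == pytest.approx(r, abs=1e-10)
    assert res.status == "fit"


def test_cna_only_signal_leaves_mirna_null():
    rng = np.random.default_rng(1)
    pvals, corrs = [], []
    for _ in range(200):
        d = frame(rng, n=60, slope=0.0, cna_effect=0.8, noise=0.4)
        res = fit_pair_model(d, "m", "g", "TT")
        pvals.append(res.pvalue)
        corrs.append(res.correlation)
    # p approximately uniform, adjusted correlation small
    assert 0.02 < np.mean(np.array(pvals) < 0.05) < 0.1
    assert np.median(np.abs(corrs)) < 0.2


def test_confounded_slope_recovered_with_negative_correlation():
    rng = np.random.default_rng(2)
    hits = 0
    for _ in range(20):
        d = frame(rng, slope=-0.5, cna_effect=0.6, met_effect=-0.3)
        res = fit_pair_model(d, "m", "g", "TT")
        if res.correlation < 0 and res.pvalue < 0.01:
            hits += 1
    assert hits >= 18


def test_too_few_samples_is_nonexistent():
    rng = np.random.default_rng(3)
    d = frame(rng, n=4)
    res = fit_pair_model(d, "m", "g", "TT")
    assert res.status == "nonexistent" and res.correlation == 0.0


def test_constant_met_probe_dropped_silently():
    rng = np.random.default_rng(4)
    d = frame(rng)
    d["met_cg2"] = 1.234  # zero variance
    res = fit_pair_model(d, "m", "g", "TT")
    assert res.status == "fit"


# -------------------------------------------------------------------- joint

def test_joint_matches_pooled_r_with_identical_slopes():
    rng = np.random.default_rng(5)
    frames = []
    for t in ("A", "B", "C"):
        d = frame(rng, n=100, slope=-0.6, noise=0.4)[["gene_expr", "mir_expr"]]
        frames.append(d.assign(cancer_type=t))
    data = pd.concat(frames, ignore_index=True)
    res = fit_joint_model(data, "m", "g")
    r, _ = stats.pearsonr(data["mir_expr"], data["gene_expr"])
    # same slope + same intercept in all types: joint ~ pooled within-type r
    assert res.correlation == pytest.approx(r, abs=0.05)
    assert res.correlation < -0.5


def test_joint_opposite_slopes_cancel_in_main_effect():
    rng = np.random.default_rng(6)
    mir = rng.normal(0, 1, 200)
    up = pd.DataFrame({"gene_expr": 5 + 0.8 * mir, "mir_expr": mir,
                       "cancer_type": "A"})
    dn = pd.DataFrame({"gene_expr": 5 - 0.8 * mir, "mir_expr": mir,
                       "cancer_type": "B"})
    res = fit_joint_model(pd.concat([up, dn], ignore_index=True), "m", "g")
    assert abs(res.correlation) < 0.05  # balanced cancellation


def test_joint_single_type_instructs_per_type_model():
    rng = np.random.default_rng(7)
    d = frame(rng).assign(cancer_type="A")
    with pytest.raises(ValueError, match="fit_pair_model"):
        fit_joint_model(d, "m", "g")


def test_correlation_invariant_to_covariate_order():
    """Type-III attribution does not depend on where terms sit in the design."""
    rng = np.random.default_rng(9)
    d = frame(rng, cna_effect=0.5, met_effect=-0.3)
    d["met_cg2"] = rng.normal(0, 1, len(d))
    base = fit_pair_model(d, "m", "g", "TT")
    shuffled = d[["met_cg2", "gene_expr", "met_cg1", "mir_expr", "cna"]]
    other = fit_pair_model(shuffled, "m", "g", "TT")
    assert other.correlation == pytest.approx(base.correlation, abs=1e-12)
    assert other.pvalue == pytest.approx(base.pvalue, abs=1e-12)


# ------------------------------------------------------- FDR and selection

def test_bh_family_excludes_nonexistent_and_spans_16_datasets():
    rng = np.random.default_rng(8)
    results = []
    for i in range(16):
        d = frame(rng, slope=0.0)
        results.append(fit_pair_model(d, "m", "g", f"T{i:02d}"))
    from mirpair.regression import PairModelResult
    results.append(PairModelResult.nonexistent("m", "g", "T99"))
    adj = adjust_pair_pvalues(results)
    fit_rows = adj[adj["status"] == "fit"]
    assert len(fit_rows) == 16
    assert adj.loc[adj["status"] == "nonexistent", "fdr"].isna().all()
    assert np.all(fit_rows["fdr"].to_numpy() >= fit_rows["pvalue"].to_numpy() - 1e-12)


def test_select_significant_negative_rules():
    rows = pd.DataFrame({
        "mirna_id": ["m1", "m2", "m3"],
        "gene_id": ["g1", "g2", "g3"],
        "dataset": [JOINT] * 3,
        "correlation": [0.4, -0.3, -0.5],
        "t_stat": [5.0, -3.0, -1.0],
        "pvalue": [1e-8, 1e-3, 0.2],
        "fdr": [1e-6, 0.04, 0.3],
        "n_samples": [100] * 3,
        "status": ["fit"] * 3,
    })
    sel = select_significant_negative(rows)
    # positive correlation excluded no matter how significant
    assert sel["mirna_id"].tolist() == ["m2"]
    with pytest.raises(ValueError):
        select_significant_negative(rows[rows["dataset"] != JOINT])


def test_per_pair_fdr_family_option():
    rng = np.random.default_rng(10)
    results = []
    for pair in ("p1", "p2"):
        for t in range(4):
            d = frame(rng, slope=0.0)
            results.append(fit_pair_model(d, f"m_{pair}", f"g_{pair}", f"T{t}"))
    adj = adjust_pair_pvalues(results, per_pair=True)
    for _, grp in adj.groupby(["mirna_id", "gene_id"]):
        from mirpair._stats import bh_adjust as bh
        assert grp["fdr"].to_numpy() == pytest.approx(
            bh(grp["pvalue"].to_numpy()))


def test_log_expression_default_scale():
    assert log_expression(pd.DataFrame({"s": [0.0, 3.0]})).iloc[1, 0] == 2.0
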