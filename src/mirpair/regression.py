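"""Covariate-adjusted linear models of gene on miRNA expression.

For every candidate pair, gene log2(RPKM+1) is regressed on miRNA
log2(RPKM+1) adjusting for copy-number level (5-level categorical factor)
and for every methylation probe mapping to the gene (M-values). A per-type
model is fitted in each tumour type, plus one joint model over all types
that adds cancer type (sum-to-zero contrasts) and its interaction with
miRNA expression.

The reported pair correlation is the signed square root of the fraction of
gene-expression variance attributed to the miRNA term by Type-III ANOVA --
for the 1-df miRNA term this equals ``sign(beta) * sqrt(t^2 * s^2 / SS_total)``
-- so in a model with no covariates it reduces exactly to the Pearson r.
P-values are BH-adjusted across the full (pair x dataset) family and the
final call keeps pairs with a negative joint correlation at fdr < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._stats import bh_adjust
from .matrix import CountMatrix

__all__ = [
    "PairModelResult",
    "rpkm",
    "log_expression",
    "beta_to_m",
    "fit_pair_model",
    "fit_joint_model",
    "adjust_pair_pvalues",
    "select_significant_negative",
    "analyse_pairs",
    "JOINT",
]

JOINT = "joint"

#: minimum variance for a methylation probe (or any covariate) to be kept
_MIN_VAR = 1e-12


@dataclass
class PairModelResult:
    mirna_id: str
    gene_id: str
    dataset: str  # tumour type, or "joint"
    correlation: float
    t_stat: float
    pvalue: float
    fdr: float
    n_samples: int
    status: str  # "fit" or "nonexistent"

    @staticmethod
    def nonexistent(mirna_id, gene_id, dataset) -> "PairModelResult":
        return PairModelResult(mirna_id, gene_id, dataset, 0.0, np.nan,
                               np.nan, np.nan, 0, "nonexistent")


def rpkm(counts, lengths: pd.Series) -> pd.DataFrame:
    """Reads per kilobase per million: count * 1e9 / (library * length_bp)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    lengths = pd.Series(lengths)
    missing = df.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing feature length(s): {list(missing[:10])}")
    lengths = lengths.reindex(df.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    lib = df.sum(axis=0).astype(float)
    return df * 1e9 / lib / lengths.to_numpy()[:, None]


def log_expression(values, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount); the expression scale used by all models."""
    return np.log2(values + pseudocount)


def beta_to_m(beta, eps: float = 1e-6):
    """Methylation beta -> M-value: log2(beta / (1 - beta)), beta clamped.

    NaN inputs propagate (with a warning) so incomplete-case handling stays
    with the caller.
    """
    arr = np.asarray(beta, dtype=float)
    if np.isnan(arr).any():
        warnings.warn("NaN beta-value(s) propagate to NaN M-values")
    clamped = np.clip(arr, eps, 1 - eps)
    m = np.log2(clamped / (1 - clamped))
    m = np.where(np.isnan(arr), np.nan, m)
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(m)
    if isinstance(beta, (pd.Series, pd.DataFrame)):
        return type(beta)(m, index=beta.index, **(
            {"columns": beta.columns} if isinstance(beta, pd.DataFrame) else {}))
    return m


def _dummy_columns(levels: pd.Series, prefix: str) -> pd.DataFrame:
    """Treatment dummies over the observed levels, first level as reference."""
    cats = sorted(pd.unique(levels))
    return pd.DataFrame(
        {f"{prefix}{c}": (levels == c).astype(float) for c in cats[1:]},
        index=levels.index)


def _sum_contrasts(levels: pd.Series, prefix: str) -> pd.DataFrame:
    """Sum-to-zero contrast columns; the last sorted level is the negative pole."""
    cats = sorted(pd.unique(levels))
    cols = {}
    for c in cats[:-1]:
        col = (levels == c).astype(float) - (levels == cats[-1]).astype(float)
        cols[f"{prefix}{c}"] = col
    return pd.DataFrame(cols, index=levels.index)


def _drop_aliased(X: pd.DataFrame, protected: int) -> pd.DataFrame:
    """Drop constant then collinear columns (never the first ``protected``)."""
    keep = list(X.columns[:protected])
    for col in X.columns[protected:]:
        if X[col].var() > _MIN_VAR:
            keep.append(col)
    X = X[keep]
    while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1] and X.shape[1] > protected:
        # drop the trailing column most explained by the others
        dropped = False
        for col in reversed(X.columns[protected:]):
            rest = X.drop(columns=[col])
            if np.linalg.matrix_rank(rest.to_numpy()) == np.linalg.matrix_rank(X.to_numpy()):
                warnings.warn(f"dropping aliased model column {col!r}")
                X = rest
                dropped = True
                break
        if not dropped:
            break
    return X


def _fit(y: pd.Series, X: pd.DataFrame, mirna_id, gene_id, dataset) -> PairModelResult:
    n = len(y)
    if n < X.shape[1] + 2:
        return PairModelResult.nonexistent(mirna_id, gene_id, dataset)
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    j = list(X.columns).index("mir")
    beta = fit.params[j]
    t = fit.tvalues[j]
    p = fit.pvalues[j]
    ss_total = float(((y - y.mean()) ** 2).sum())
    if ss_total <= 0 or not np.isfinite(t):
        return PairModelResult.nonexistent(mirna_id, gene_id, dataset)
    ss_mir = t ** 2 * fit.mse_resid  # Type-III SS of a 1-df term
    corr = float(np.sign(beta) * np.sqrt(min(ss_mir / ss_total, 1.0)))
    return PairModelResult(mirna_id, gene_id, dataset, corr, float(t), float(p),
                           np.nan, n, "fit")


def _design_base(data: pd.DataFrame):
    """Complete cases + shared covariate columns (miRNA, CNA, MET)."""
    met_cols = [c for c in data.columns if c.startswith("met_")]
    cols = ["gene_expr", "mir_expr"] + (["cna"] if "cna" in data.columns else []) + met_cols
    if "cancer_type" in data.columns:
        cols.append("cancer_type")
    d = data[cols].dropna()
    X = pd.DataFrame({"const": 1.0, "mir": d["mir_expr"]}, index=d.index)
    if "cna" in d.columns:
        X = pd.concat([X, _dummy_columns(d["cna"], "cna_")], axis=1)
    for c in met_cols:
        X[c] = d[c]
    return d, X


def fit_pair_model(data: pd.DataFrame, mirna_id: str, gene_id: str,
                   dataset: str) -> PairModelResult:
    """Per-tumour-type OLS of gene on miRNA expression + CNA + MET probes.

    ``data`` columns: ``gene_expr``, ``mir_expr``, optional ``cna``
    (integer level) and any number of ``met_<probe>`` M-value columns.
    Incomplete cases are dropped; too few samples or a degenerate design
    yields status ``nonexistent`` (correlation treated as 0 downstream).
    """
    d, X = _design_base(data)
    if len(d) == 0 or d["mir_expr"].var() <= _MIN_VAR:
        return PairModelResult.nonexistent(mirna_id, gene_id, dataset)
    X = _drop_aliased(X, protected=2)
    return _fit(d["gene_expr"], X, mirna_id, gene_id, dataset)


def fit_joint_model(data: pd.DataFrame, mirna_id: str, gene_id: str) -> PairModelResult:
    """Joint OLS over all tumour types with type and type x miRNA terms.

    ``data`` additionally carries a ``cancer_type`` column; the type factor
    uses sum-to-zero contrasts so the miRNA main effect is the average
    within-type slope and its Type-III SS is interpretable under the
    interaction.
    """
    if "cancer_type" not in data.columns:
        raise ValueError("joint model needs a 'cancer_type' column")
    d, X = _design_base(data)
    if len(d) == 0 or d["mir_expr"].var() <= _MIN_VAR:
        return PairModelResult.nonexistent(mirna_id, gene_id, JOINT)
    if d["cancer_type"].nunique() < 2:
        raise ValueError("joint model needs >= 2 cancer types; use fit_pair_model")
    contrasts = _sum_contrasts(d["cancer_type"], "ct_")
    inter = contrasts.mul(d["mir_expr"], axis=0)
    inter.columns = [c.replace("ct_", "mir_x_ct_") for c in contrasts.columns]
    X = pd.concat([X, contrasts, inter], axis=1)
    X = _drop_aliased(X, protected=2)
    return _fit(d["gene_expr"], X, mirna_id, gene_id, JOINT)


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def adjust_pair_pvalues(results, per_pair: bool = False) -> pd.DataFrame:
    """BH across every fitted (pair x dataset) test; nonexistent rows excluded.

    With ``per_pair=True`` the family is instead the (up to 16) datasets of
    each pair separately.
    """
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    df = df.copy()
    fit = df["status"] == "fit"
    if per_pair:
        for _, idx in df[fit].groupby(["mirna_id", "gene_id"]).groups.items():
            df.loc[idx, "fdr"] = bh_adjust(df.loc[idx, "pvalue"].to_numpy())
    else:
        df.loc[fit, "fdr"] = bh_adjust(df.loc[fit, "pvalue"].to_numpy())
    return df


def select_significant_negative(results: pd.DataFrame,
                                fdr_max: float = 0.05) -> pd.DataFrame:
    """Pairs with joint correlation < 0 and joint fdr < ``fdr_max``."""
    joint = results[(results["dataset"] == JOINT) & (results["status"] == "fit")]
    if joint.empty:
        raise ValueError("no joint results present; fit the joint model first")
    keep = joint[(joint["correlation"] < 0) & (joint["fdr"] < fdr_max)]
    return keep[["mirna_id", "gene_id", "correlation", "t_stat", "pvalue", "fdr"]]


def analyse_pairs(bundles: dict, joint: bool = True) -> pd.DataFrame:
    """Fit all per-type and joint models and BH-adjust the whole family.

    ``bundles`` maps (mirna, gene) -> {tumour_type: per-type DataFrame}; a
    missing tumour type (member undetected there) is recorded as a
    nonexistent dataset so downstream treats its correlation as 0.
    """
    results = []
    for (mirna, gene), per_type in bundles.items():
        frames = []
        for ttype, d in per_type.items():
            if d is None:
                results.append(PairModelResult.nonexistent(mirna, gene, ttype))
                continue
            results.append(fit_pair_model(d, mirna, gene, ttype))
            frames.append(d.assign(cancer_type=ttype))
        if joint:
            if len([f for f in frames if len(f)]) >= 2:
                joint_df = pd.concat(frames, ignore_index=True)
                results.append(fit_joint_model(joint_df, mirna, gene))
            else:
                results.append(PairModelResult.nonexistent(mirna, gene, JOINT))
    return adjust_pair_pvalues(results)
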