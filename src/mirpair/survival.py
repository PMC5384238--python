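"""Stage-adjusted Cox proportional-hazards association with expression.

Tumour stage is collapsed to a binary prognosis factor (stages I-II good;
III, IV and X bad; for the prostate-like type Gleason 6-7 good, >= 8 bad)
and entered next to log2-transformed expression in a Cox model with Efron
tie handling, fitted separately per tumour type. The expression Wald p is
therefore the stage-independent association. P-values are BH-adjusted over
the whole (feature x tumour type) family and combined with the regression
results into per-(pair, type) support calls.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from ._stats import bh_adjust

__all__ = [
    "encode_prognosis",
    "cox_fit",
    "survival_scan",
    "combine_correlation_survival",
    "SurvivalResult",
]

_LN2 = np.log(2.0)
_STAGE_RE = re.compile(r"stage\s*([ivx]+)\s*[a-c]?\s*$", re.IGNORECASE)
_GLEASON_RE = re.compile(r"(?:gleason\s*)?(\d+)\s*$", re.IGNORECASE)

GOOD, BAD = "good", "bad"


@dataclass
class SurvivalResult:
    feature_id: str
    tumour_type: str
    log2_hr: float  # per unit log2-expression
    log_hr: float   # natural-log scale
    pvalue: float
    fdr: float
    n: int
    n_events: int
    status: str  # "fit", "failed", "degenerate"


def encode_prognosis(stage_raw: str, gleason: bool = False) -> str:
    """Binary prognosis from a raw stage (or Gleason) annotation.

    Stages I/II (with sub-letters) -> good; III/IV/X -> bad. With
    ``gleason=True`` a score of 6-7 is good and >= 8 bad.

    Raises ValueError on unparseable input, so callers can exclude the
    record with a warning.
    """
    if not str(stage_raw).strip():
        raise ValueError("empty stage annotation")
    text = str(stage_raw).strip()
    if gleason:
        m = _GLEASON_RE.search(text)
        if not m:
            raise ValueError(f"unparseable Gleason score: {stage_raw!r}")
        return GOOD if int(m.group(1)) <= 7 else BAD
    m = _STAGE_RE.search(text)
    if not m:
        raise ValueError(f"unparseable tumour stage: {stage_raw!r}")
    numeral = m.group(1).upper()
    if numeral in {"I", "II"}:
        return GOOD
    if numeral in {"III", "IV", "X"}:
        return BAD
    raise ValueError(f"unparseable tumour stage: {stage_raw!r}")


def cox_fit(records: pd.DataFrame, expr: pd.Series, feature_id: str = "",
            tumour_type: str = "") -> SurvivalResult:
    """Cox PH of survival on prognosis + log2-expression (Efron ties).

    ``records`` needs columns ``time``, ``event`` and ``prognosis``
    (good/bad), indexed by sample; ``expr`` is the per-sample log2
    expression covariate. If prognosis has a single level it is dropped
    with a warning; constant expression or a failed fit yields a flagged
    result excluded from the FDR family.
    """
    df = records.join(expr.rename("expr"), how="inner").dropna(
        subset=["time", "event", "expr", "prognosis"])
    n, n_events = len(df), int(df["event"].sum())
    if n_events < 2:
        return SurvivalResult(feature_id, tumour_type, np.nan, np.nan, np.nan,
                              np.nan, n, n_events, "degenerate")
    if df["expr"].var() <= 1e-12:
        return SurvivalResult(feature_id, tumour_type, np.nan, np.nan, np.nan,
                              np.nan, n, n_events, "degenerate")
    model = df[["time", "event", "expr"]].copy()
    if df["prognosis"].nunique() > 1:
        model["bad_stage"] = (df["prognosis"] == BAD).astype(float)
    else:
        warnings.warn(
            f"single prognosis level in {tumour_type or 'cohort'}; stage covariate dropped")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(model, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-14, "max_steps": 100})
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return SurvivalResult(feature_id, tumour_type, np.nan, np.nan, np.nan,
                              np.nan, n, n_events, "failed")
    coef = float(cph.params_["expr"])
    p = float(cph.summary.loc["expr", "p"])
    if not np.isfinite(coef) or not np.isfinite(p):
        return SurvivalResult(feature_id, tumour_type, np.nan, np.nan, np.nan,
                              np.nan, n, n_events, "failed")
    return SurvivalResult(feature_id, tumour_type, coef / _LN2, coef, p,
                          np.nan, n, n_events, "fit")


def survival_scan(clinical_by_type: dict, expr_by_type: dict,
                  features) -> pd.DataFrame:
    """Fit every (feature, tumour type) Cox model and BH-adjust the family.

    ``clinical_by_type`` maps tumour type -> clinical frame (time, event,
    prognosis; indexed by sample); ``expr_by_type`` maps tumour type ->
    log2-expression frame (features x samples).
    """
    results = []
    for ttype, clin in clinical_by_type.items():
        expr = expr_by_type.get(ttype)
        if expr is None:
            continue
        for feat in features:
            if feat not in expr.index:
                continue
            results.append(cox_fit(clin, expr.loc[feat], feat, ttype))
    df = pd.DataFrame([vars(r) for r in results])
    if df.empty:
        return df
    fit = df["status"] == "fit"
    df.loc[fit, "fdr"] = bh_adjust(df.loc[fit, "pvalue"].to_numpy())
    return df


def combine_correlation_survival(pair_results: pd.DataFrame,
                                 surv: pd.DataFrame,
                                 fdr_max: float = 0.05) -> pd.DataFrame:
    """Per (pair, tumour type) support matrix combining both analyses.

    A cell is ``supported`` iff the pair's per-type correlation fdr and the
    gene's survival fdr in that type are both below ``fdr_max``. The output
    mirrors the summary-figure layout: correlation (sign/strength), log2
    hazard ratio, per-analysis significance flags and the combined call.
    """
    per_type = pair_results[(pair_results["dataset"] != "joint")
                            & (pair_results["status"] == "fit")]
    surv_idx = surv.set_index(["feature_id", "tumour_type"]) if len(surv) else None
    rows = []
    for _, r in per_type.iterrows():
        key = (r["gene_id"], r["dataset"])
        if surv_idx is not None and key in surv_idx.index:
            s = surv_idx.loc[key]
            log2_hr, s_fdr = s["log2_hr"], s["fdr"]
        else:
            log2_hr, s_fdr = np.nan, np.nan
        corr_sig = bool(r["fdr"] < fdr_max)
        surv_sig = bool(s_fdr < fdr_max) if np.isfinite(s_fdr) else False
        rows.append({
            "mirna": r["mirna_id"], "gene": r["gene_id"],
            "tumour_type": r["dataset"], "correlation": r["correlation"],
            "correlation_fdr": r["fdr"], "log2_hr": log2_hr,
            "survival_fdr": s_fdr, "correlation_significant": corr_sig,
            "survival_significant": surv_sig,
            "supported": corr_sig and surv_sig,
        })
    return pd.DataFrame(rows)


def multi_type_supported(combined: pd.DataFrame, min_types: int = 2) -> pd.DataFrame:
    """Pairs supported in at least ``min_types`` distinct tumour types."""
    if combined.empty:
        return combined
    sup = combined[combined["supported"]]
    counts = sup.groupby(["mirna", "gene"])["tumour_type"].nunique()
    keep = counts[counts >= min_types]
    return keep.rename("n_supported_types").reset_index()
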