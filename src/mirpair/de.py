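"""Two-group differential expression for count matrices.

The engine follows the classic count-based workflow: weakly expressed
features are removed by a CPM cut-off, libraries are normalised by the
trimmed mean of M-values (TMM), a single negative-binomial dispersion is
estimated by conditional maximum likelihood on library-equalised
pseudo-counts, and each feature is tested with the conditional NB exact
test. P-values are Benjamini-Hochberg adjusted and features are selected at
FDR < 0.05 with |log2FC| > 1 (both strict).

The variance model is ``var = mu + phi * mu**2`` throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import minimize_scalar

from ._stats import bh_adjust
from .matrix import CONTROL, TUMOUR, CountMatrix

__all__ = [
    "cpm",
    "filter_low_expression",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "select_de",
    "de_analysis",
]

#: prior count added to each group mean when forming log2 fold changes
LFC_PRIOR = 0.125

#: conditional totals above this size use the beta tail approximation
EXACT_TOTAL_LIMIT = 10_000


def _counts_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def cpm(counts) -> pd.DataFrame:
    """Counts per million: ``count * 1e6 / column library size``."""
    df = _counts_frame(counts)
    lib = df.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return df * 1e6 / lib


def filter_low_expression(counts: CountMatrix, cpm_threshold: float = 1.0,
                          min_samples: int | None = None) -> CountMatrix:
    """Keep features with CPM >= ``cpm_threshold`` in >= ``min_samples`` samples.

    ``min_samples`` defaults to the smaller group size. Feature order is
    preserved; the result may be empty.
    """
    if min_samples is None:
        sizes = counts.groups.value_counts()
        min_samples = int(sizes.min()) if len(sizes) else 1
    ok = (cpm(counts) >= cpm_threshold).sum(axis=1) >= min_samples
    return counts.subset_features(counts.feature_ids[ok])


def _choose_reference(df: pd.DataFrame) -> str:
    """TMM reference column: upper quartile of CPM closest to the mean UQ."""
    uq = cpm(df).quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def tmm_factors(counts, ref_sample: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors, geometric mean 1.

    For sample ``k`` against the reference ``r``, over features positive in
    both, M = log2 ratio of library-scaled proportions and A = the average
    log2 abundance; features are doubly trimmed (30% on M, 5% on A) and the
    factor is 2 to the weighted mean of the surviving M-values, with
    inverse asymptotic-variance weights.
    """
    df = _counts_frame(counts)
    if df.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = df.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every library size must be positive")
    if ref_sample is None:
        ref_sample = _choose_reference(df)
    yr = df[ref_sample].to_numpy(dtype=float)
    nr = lib[ref_sample]
    factors = {}
    for sample in df.columns:
        if sample == ref_sample:
            factors[sample] = 1.0
            continue
        yk = df[sample].to_numpy(dtype=float)
        nk = lib[sample]
        pos = (yk > 0) & (yr > 0)
        if pos.sum() < 1:
            warnings.warn(f"no shared positive features for {sample}; TMM factor set to 1")
            factors[sample] = 1.0
            continue
        pk, pr = yk[pos] / nk, yr[pos] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (nk - yk[pos]) / (nk * yk[pos]) + (nr - yr[pos]) / (nr * yr[pos])
        n = m.size
        rank_m = stats.rankdata(m)
        rank_a = stats.rankdata(a)
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        keep = ((rank_m >= lo_m) & (rank_m <= n + 1 - lo_m)
                & (rank_a >= lo_a) & (rank_a <= n + 1 - lo_a))
        if keep.sum() < 1 or w[keep].sum() == 0:
            warnings.warn(f"trimming removed all features for {sample}; TMM factor set to 1")
            factors[sample] = 1.0
            continue
        factors[sample] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    f = pd.Series(factors).reindex(df.columns)
    return f / np.exp(np.log(f).mean())


def _nb_logpmf(k: np.ndarray, mean: float, disp: float) -> np.ndarray:
    """log NB pmf with var = mean + disp*mean^2; Poisson at disp ~ 0."""
    k = np.asarray(k, dtype=float)
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if disp < 1e-12:
        return k * np.log(mean) - mean - special.gammaln(k + 1)
    r = 1.0 / disp
    return (special.gammaln(k + r) - special.gammaln(r) - special.gammaln(k + 1)
            + r * np.log(r / (r + mean)) + k * np.log(mean / (r + mean)))


def _q2qnbinom(x: np.ndarray, input_mean: np.ndarray, output_mean: np.ndarray,
               disp: float) -> np.ndarray:
    """Quantile-map counts between NB distributions of different means.

    Average of a variance-matched linear (normal) map and a gamma
    quantile-quantile map; used to equalise library sizes before the
    conditional-likelihood steps.
    """
    eps = 1e-14
    input_mean = np.maximum(input_mean, eps)
    output_mean = np.maximum(output_mean, eps)
    ri = 1.0 + disp * input_mean
    ro = 1.0 + disp * output_mean
    q1 = output_mean + np.sqrt((output_mean * ro) / (input_mean * ri)) * (x - input_mean)
    p = stats.gamma.cdf(x, a=input_mean / ri, scale=ri)
    q2 = stats.gamma.ppf(np.clip(p, 1e-300, 1 - 1e-16), a=output_mean / ro, scale=ro)
    return np.maximum((q1 + q2) / 2.0, 0.0)


def _pseudo_counts(values: np.ndarray, eff_lib: np.ndarray, disp: float):
    """Equalise effective libraries to their geometric mean.

    Returns (pseudo counts, common library size).
    """
    common = float(np.exp(np.mean(np.log(eff_lib))))
    lam = values.sum(axis=1) / eff_lib.sum()  # per-feature abundance
    input_mean = np.outer(lam, eff_lib)
    output_mean = np.outer(lam, np.full_like(eff_lib, common))
    return _q2qnbinom(values, input_mean, output_mean, disp), common


def _cond_log_lik(pseudo: np.ndarray, group_masks, disp: float) -> float:
    """Common conditional NB log-likelihood of pseudo-counts, both groups."""
    r = 1.0 / max(disp, 1e-10)
    total = 0.0
    for mask in group_masks:
        y = pseudo[:, mask]
        n = mask.sum()
        z = y.sum(axis=1)
        total += float(np.sum(special.gammaln(y + r).sum(axis=1)
                              + special.gammaln(n * r)
                              - special.gammaln(z + n * r)
                              - n * special.gammaln(r)))
    return total


def _moments_dispersion(values: np.ndarray, eff_lib: np.ndarray) -> float:
    """Method-of-moments fallback on CPM-scale means/variances."""
    scaled = values / eff_lib * np.mean(eff_lib)
    mu = scaled.mean(axis=1)
    var = scaled.var(axis=1, ddof=1)
    ok = mu > 0
    if not ok.any():
        return 0.0
    phi = (var[ok] - mu[ok]) / mu[ok] ** 2
    return float(np.clip(np.median(phi), 0.0, 20.0))


def estimate_common_dispersion(counts: CountMatrix, factors: pd.Series | None = None,
                               n_iter: int = 2) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Alternates library equalisation (pseudo-counts at the current
    dispersion) with a 1-D maximisation of the conditional log-likelihood
    over ``delta = phi / (1 + phi)``. Falls back to a method-of-moments
    estimate if the optimisation fails.
    """
    values = counts.counts.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    if factors is None:
        factors = tmm_factors(counts)
    eff_lib = lib * factors.reindex(counts.sample_ids).to_numpy()
    masks = [np.asarray(counts.groups.to_numpy() == g) for g in (CONTROL, TUMOUR)]
    if not all(m.any() for m in masks):
        raise ValueError("both a control and a tumour group are required")
    keep = values.sum(axis=1) > 0
    values = values[keep]
    if values.shape[0] == 0:
        return 0.0
    disp = 0.01
    try:
        for _ in range(n_iter):
            pseudo, _ = _pseudo_counts(values, eff_lib, disp)
            res = minimize_scalar(
                lambda delta: -_cond_log_lik(pseudo, masks, delta / (1 - delta)),
                bounds=(1e-6, 0.995), method="bounded",
                options={"xatol": 1e-6},
            )
            if not res.success or not np.isfinite(res.fun):
                raise RuntimeError("conditional-likelihood optimisation failed")
            disp = float(res.x / (1 - res.x))
        return disp
    except Exception:
        warnings.warn("dispersion CML optimisation failed; using method-of-moments estimate")
        return _moments_dispersion(values, eff_lib)


def _exact_nb_pvalue(s1: int, s2: int, n1: int, n2: int, disp: float) -> float:
    """Two-sided conditional exact NB p-value for group sums (s1, s2).

    Conditions on the total ``S = s1 + s2`` assuming equalised libraries:
    group sums are NB with means proportional to group sizes and
    dispersions ``disp / n_group``. The p-value is the conditional
    probability of splits at most as probable as the one observed.
    Totals above ``EXACT_TOTAL_LIMIT`` use a beta tail approximation
    (the large-total limit of the conditional split distribution) with
    tail doubling.
    """
    total = s1 + s2
    if total == 0:
        return 1.0
    frac1 = n1 / (n1 + n2)
    if total > EXACT_TOTAL_LIMIT:
        if disp < 1e-12:
            return stats.binomtest(s1, total, frac1).pvalue
        r1, r2 = n1 / disp, n2 / disp
        left = special.betainc(r1, r2, (s1 + 0.5) / (total + 1))
        right = 1.0 - special.betainc(r1, r2, max((s1 - 0.5) / (total + 1), 0.0))
        return float(min(1.0, 2.0 * min(left, right)))
    k = np.arange(total + 1)
    lp = (_nb_logpmf(k, total * frac1, disp / n1)
          + _nb_logpmf(total - k, total * (1 - frac1), disp / n2))
    obs = lp[s1]
    norm = special.logsumexp(lp)
    keep = lp <= obs + 1e-10
    return float(min(1.0, np.exp(special.logsumexp(lp[keep]) - norm)))


def nb_exact_test(counts: CountMatrix, factors: pd.Series | None = None,
                  dispersion: float | None = None) -> pd.DataFrame:
    """Conditional NB exact test, tumour vs control, per feature.

    Returns a DataFrame indexed by feature with columns ``log2fc`` (tumour
    vs control, prior count 0.125 on each group mean), ``avg_log2cpm`` and
    ``pvalue``. FDR adjustment is left to :func:`bh_adjust`/:func:`de_analysis`.
    """
    ctrl = counts.samples_in_group(CONTROL)
    tum = counts.samples_in_group(TUMOUR)
    if not ctrl or not tum:
        raise ValueError("nb_exact_test needs samples in both groups")
    values = counts.counts.to_numpy(dtype=float)
    if values.shape[0] == 0:
        return pd.DataFrame(columns=["log2fc", "avg_log2cpm", "pvalue"])
    lib = values.sum(axis=0)
    for g, names in ((CONTROL, ctrl), (TUMOUR, tum)):
        if counts.counts[names].to_numpy().sum() == 0:
            raise ValueError(f"group '{g}' has zero total count")
    if factors is None:
        factors = tmm_factors(counts)
    eff_lib = lib * factors.reindex(counts.sample_ids).to_numpy()
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, factors)
    pseudo, common_lib = _pseudo_counts(values, eff_lib, dispersion)
    mask_c = np.asarray(counts.groups.to_numpy() == CONTROL)
    mask_t = ~mask_c
    n1, n2 = int(mask_c.sum()), int(mask_t.sum())
    sums_c = np.rint(pseudo[:, mask_c].sum(axis=1)).astype(np.int64)
    sums_t = np.rint(pseudo[:, mask_t].sum(axis=1)).astype(np.int64)
    pvals = np.array([
        _exact_nb_pvalue(int(sc), int(st), n1, n2, dispersion)
        for sc, st in zip(sums_c, sums_t)
    ])
    mean_c = sums_c / n1
    mean_t = sums_t / n2
    log2fc = np.log2((mean_t + LFC_PRIOR) / (mean_c + LFC_PRIOR))
    avg = np.log2(((sums_c + sums_t) / (n1 + n2) + 0.25) / common_lib * 1e6)
    return pd.DataFrame(
        {"log2fc": log2fc, "avg_log2cpm": avg, "pvalue": pvals},
        index=counts.feature_ids,
    )


def select_de(results: pd.DataFrame, fdr_max: float = 0.05,
              lfc_min: float = 1.0) -> pd.DataFrame:
    """Differentially expressed features: fdr < ``fdr_max`` AND |log2fc| > ``lfc_min``.

    Both comparisons are strict. Adds a ``direction`` column (``up``/``down``).
    """
    if "fdr" not in results.columns:
        raise ValueError("results must carry an 'fdr' column; run bh_adjust first")
    keep = (results["fdr"] < fdr_max) & (results["log2fc"].abs() > lfc_min)
    out = results.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def de_analysis(counts: CountMatrix, cpm_threshold: float = 1.0,
                min_samples: int | None = None,
                dispersion: float | None = None) -> pd.DataFrame:
    """Full per-tumour DE table: filter, TMM, exact test, BH, direction."""
    filtered = filter_low_expression(counts, cpm_threshold, min_samples)
    if filtered.counts.shape[0] == 0:
        return pd.DataFrame(columns=["log2fc", "avg_log2cpm", "pvalue", "fdr", "direction"])
    factors = tmm_factors(filtered)
    res = nb_exact_test(filtered, factors, dispersion)
    res["fdr"] = bh_adjust(res["pvalue"].to_numpy())
    res["direction"] = np.where(res["log2fc"] > 0, "up", "down")
    return res
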