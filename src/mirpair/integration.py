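"""Cross-tumour recurrence of DE features and threshold optimisation.

A feature's recurrence is the number of distinct tumour types in which it
is differentially expressed (in either direction; a gene may be up in some
types and down in others). The recurrence cut-off is not fixed a priori:
candidate thresholds (by default 5..10 tumour types) are scanned and the
one maximising the odds ratio of enrichment in a list of known cancer
genes/miRNAs -- subject to a significant right-tailed Fisher FDR -- is
chosen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_2x2, haldane_odds_ratio, odds_ratio

__all__ = [
    "recurrence_table",
    "optimize_threshold",
    "select_recurrent",
    "NoEnrichableThreshold",
]


class NoEnrichableThreshold(ValueError):
    """Raised when no scanned threshold is significantly enriched."""


def recurrence_table(per_tumour_de: dict) -> dict:
    """Map feature -> set of (tumour_type, direction) where it is DE.

    ``per_tumour_de`` maps tumour type -> {feature: direction}. Features DE
    nowhere are absent from the result.
    """
    if len(set(per_tumour_de)) != len(per_tumour_de):
        raise ValueError("tumour types must be distinct")
    table: dict = {}
    for ttype, de in per_tumour_de.items():
        for feature, direction in de.items():
            table.setdefault(feature, set()).add((ttype, direction))
    return table


def recurrence_counts(table: dict) -> pd.Series:
    """Number of distinct tumour types per feature."""
    return pd.Series({f: len({t for t, _ in hits}) for f, hits in table.items()},
                     dtype=int)


def optimize_threshold(table: dict, known, universe,
                       t_range=range(5, 11), fdr_max: float = 0.05):
    """Choose the recurrence cut-off by enrichment in a known-feature list.

    For each candidate T, features with recurrence >= T are crossed with
    membership in ``known`` over ``universe`` in a 2x2 table tested with a
    right-tailed Fisher test; p-values are BH-adjusted across the scanned
    thresholds. The chosen T maximises the odds ratio among thresholds
    with fdr < ``fdr_max`` (ties break toward the smaller T; zero-cell
    tables are ranked by the Haldane-corrected OR; empty selections are
    reported with OR = NaN and excluded).

    Returns ``(chosen_T, scan)`` where ``scan`` is a DataFrame with one row
    per threshold.
    """
    known, universe = set(known), set(universe)
    if not known <= universe:
        raise ValueError("known features must be contained in the universe")
    counts = recurrence_counts(table)
    rows = []
    for t in t_range:
        selected = set(counts.index[counts >= t]) & universe
        a = len(selected & known)
        b = len(selected - known)
        c = len(known - selected)
        d = len(universe) - a - b - c
        if len(selected) == 0:
            rows.append({"threshold": t, "n_selected": 0, "a": a, "b": b, "c": c,
                         "d": d, "odds_ratio": np.nan, "rank_or": np.nan,
                         "pvalue": np.nan})
            continue
        _, p_right, _ = fisher_2x2(((a, b), (c, d)))
        or_ = odds_ratio(a, b, c, d)
        rank_or = or_ if np.isfinite(or_) else haldane_odds_ratio(a, b, c, d)
        rows.append({"threshold": t, "n_selected": len(selected), "a": a, "b": b,
                     "c": c, "d": d, "odds_ratio": or_, "rank_or": rank_or,
                     "pvalue": p_right})
    scan = pd.DataFrame(rows)
    tested = scan["pvalue"].notna()
    scan["fdr"] = np.nan
    if tested.any():
        scan.loc[tested, "fdr"] = bh_adjust(scan.loc[tested, "pvalue"].to_numpy())
    eligible = scan[(scan["fdr"] < fdr_max) & scan["rank_or"].notna()]
    if eligible.empty:
        raise NoEnrichableThreshold(
            "no enrichable threshold: no scanned cut-off reaches "
            f"fdr < {fdr_max} against the known list"
        )
    best = eligible["rank_or"].max()
    chosen = int(eligible.loc[eligible["rank_or"] == best, "threshold"].min())
    return chosen, scan.drop(columns=["rank_or"])


def select_recurrent(table: dict, threshold: int) -> dict:
    """Features with recurrence >= ``threshold``; the direction map is kept."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return {f: hits for f, hits in table.items()
            if len({t for t, _ in hits}) >= threshold}
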