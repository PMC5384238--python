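"""Directional pathway enrichment of DE genes by 2x2 Fisher tests.

Each curated pathway (the seven cancer hallmarks used throughout the
pipeline: apoptosis, necrosis, senescence, DDR, cell cycle, DNA
replication, telomere elongation) is tested for over/under-representation
of differentially expressed genes against the universe of genes expressed
in that tumour type. An odds ratio > 1 marks a pathway enriched in altered
genes; < 1 marks a pathway depleted (behaving like healthy tissue).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, fisher_2x2, haldane_odds_ratio

__all__ = ["EnrichmentResult", "enrich_pathways", "random_control", "is_nonrandom"]


@dataclass
class EnrichmentResult:
    pathway: str
    table: tuple  # ((a, b), (c, d)) over the expressed-gene universe
    odds_ratio: float
    odds_ratio_reported: float  # Haldane-corrected when a cell is zero
    pvalue: float
    fdr: float
    direction: str  # enriched iff odds_ratio > 1


def _contingency(de_genes: set, expressed: set, pathway_genes: set):
    p = pathway_genes & expressed
    a = len(de_genes & p)
    b = len(de_genes - p)
    c = len(p - de_genes)
    d = len(expressed) - a - b - c
    return (a, b), (c, d)


def enrich_pathways(de_genes, expressed_genes, catalog: dict) -> list[EnrichmentResult]:
    """Two-sided Fisher enrichment of ``de_genes`` in each pathway.

    ``catalog`` maps pathway name -> gene set (a GMT read by
    :func:`mirpair.io.read_gmt`). ``de_genes`` must be a subset of
    ``expressed_genes``; table margins always sum to the universe size.
    """
    de_genes, expressed_genes = set(de_genes), set(expressed_genes)
    stray = de_genes - expressed_genes
    if stray:
        raise ValueError(f"DE genes outside the expressed universe: {sorted(stray)[:10]}")
    rows = []
    for name, genes in catalog.items():
        table = _contingency(de_genes, expressed_genes, set(genes))
        or_, _, p_two = fisher_2x2(table)
        (a, b), (c, d) = table
        reported = or_ if np.isfinite(or_) else haldane_odds_ratio(a, b, c, d)
        rows.append((name, table, or_, reported, p_two))
    fdr = bh_adjust([r[4] for r in rows]) if rows else []
    return [
        EnrichmentResult(name, table, or_, rep, p, q,
                         "enriched" if or_ > 1 else "depleted")
        for (name, table, or_, rep, p), q in zip(rows, fdr)
    ]


def random_control(de_genes, expressed_genes, pathway_size: int,
                   n_reps: int, seed: int) -> pd.DataFrame:
    """Null odds-ratio distribution from random size-matched gene sets.

    Draws ``n_reps`` random sets of ``pathway_size`` genes from the
    expressed universe and computes the DE-enrichment OR and p of each,
    for comparison with the real pathway's statistics.
    """
    de_genes, expressed_genes = set(de_genes), set(expressed_genes)
    universe = sorted(expressed_genes)
    if pathway_size > len(universe):
        raise ValueError("pathway_size exceeds the expressed-gene universe")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        fake = set(rng.choice(universe, size=pathway_size, replace=False))
        table = _contingency(de_genes, expressed_genes, fake)
        or_, _, p_two = fisher_2x2(table)
        (a, b), (c, d) = table
        rows.append({
            "odds_ratio": or_ if np.isfinite(or_) else haldane_odds_ratio(a, b, c, d),
            "pvalue": p_two,
        })
    return pd.DataFrame(rows, columns=["odds_ratio", "pvalue"])


def is_nonrandom(real_odds_ratio: float, control: pd.DataFrame,
                 lo: float = 0.025, hi: float = 0.975) -> bool:
    """True when the real OR falls outside the control ORs' central interval."""
    if len(control) == 0:
        return False
    q_lo, q_hi = control["odds_ratio"].quantile([lo, hi])
    return bool(real_odds_ratio < q_lo or real_odds_ratio > q_hi)
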