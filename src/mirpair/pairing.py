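"""Inverse-expression miRNA-mRNA pairing under the genomic-agreement filter.

Candidate interactions come from a predicted-target catalogue in which each
(miRNA, gene) edge carries a "genomic agreement": the number of distinct
prediction methods supporting the same 3'UTR position. Only edges with
agreement >= 2 are trusted. A pair instance is emitted for every tumour
type in which the miRNA and the gene are differentially expressed in
opposite directions (miRNA up / gene down, or the reverse), with genes
restricted to the curated pathway universe.

Downstream views: pairs conserved across recurrently DE partners, pairs
exclusive to one tumour type (or one named type group), a right-tailed
Fisher "specificity" statistic rewarding pairs that recur across tumours
while both partners have few co-interactors, and novelty flags against a
validated-pair list.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from ._stats import bh_adjust, fisher_2x2, odds_ratio

__all__ = [
    "PairInstance",
    "normalize_mirna",
    "candidate_pairs",
    "conserved_pairs",
    "exclusive_pairs",
    "group_exclusive_pairs",
    "specificity_test",
    "flag_novel",
]


@dataclass(frozen=True)
class PairInstance:
    mirna_id: str
    gene_id: str
    tumour_type: str
    orientation: str  # "miR-up/gene-down" or "miR-down/gene-up"


def normalize_mirna(name: str) -> str:
    """Lower-case and strip the 'hsa-' prefix (catalogues mix conventions)."""
    name = str(name).strip().lower()
    return name.removeprefix("hsa-")


def candidate_pairs(per_tumour_de_genes: dict, per_tumour_de_mirnas: dict,
                    catalog: pd.DataFrame, min_agreement: int = 2,
                    pathway_universe=None) -> list[PairInstance]:
    """Emit one instance per (tumour type, catalogue edge) inversely DE there.

    ``per_tumour_de_genes`` / ``per_tumour_de_mirnas`` map tumour type ->
    {feature: direction}; ``catalog`` has columns mirna, gene, agreement.
    Genes are restricted to ``pathway_universe`` when given.
    """
    edges = catalog[catalog["agreement"] >= min_agreement]
    universe = set(pathway_universe) if pathway_universe is not None else None
    instances = []
    for ttype, de_genes in per_tumour_de_genes.items():
        de_mirnas = {normalize_mirna(m): d
                     for m, d in per_tumour_de_mirnas.get(ttype, {}).items()}
        for mirna, gene in zip(edges["mirna"], edges["gene"]):
            mkey = normalize_mirna(mirna)
            if mkey not in de_mirnas or gene not in de_genes:
                continue
            if universe is not None and gene not in universe:
                continue
            dm, dg = de_mirnas[mkey], de_genes[gene]
            if dm == dg:
                continue  # not an inverse profile
            orientation = "miR-up/gene-down" if dm == "up" else "miR-down/gene-up"
            instances.append(PairInstance(mkey, gene, ttype, orientation))
    return instances


def conserved_pairs(instances, recurrent_genes, recurrent_mirnas) -> pd.DataFrame:
    """Pairs whose both members passed the recurrence cut-off.

    Returns one row per pair with the list of tumour types supporting it
    and the orientation pattern observed.
    """
    recurrent_genes = set(recurrent_genes)
    recurrent_mirnas = {normalize_mirna(m) for m in recurrent_mirnas}
    by_pair: dict = defaultdict(list)
    for inst in instances:
        if inst.gene_id in recurrent_genes and inst.mirna_id in recurrent_mirnas:
            by_pair[(inst.mirna_id, inst.gene_id)].append(inst)
    rows = [{
        "mirna": m, "gene": g,
        "n_tumours": len({i.tumour_type for i in group}),
        "tumour_types": sorted({i.tumour_type for i in group}),
        "orientations": sorted({i.orientation for i in group}),
    } for (m, g), group in sorted(by_pair.items())]
    return pd.DataFrame(rows, columns=["mirna", "gene", "n_tumours",
                                       "tumour_types", "orientations"])


def _pair_types(instances) -> dict:
    types: dict = defaultdict(set)
    for inst in instances:
        types[(inst.mirna_id, inst.gene_id)].add(inst.tumour_type)
    return types


def exclusive_pairs(instances) -> dict:
    """Map tumour type -> pairs occurring in that type and no other."""
    types = _pair_types(instances)
    out: dict = defaultdict(set)
    for pair, tt in types.items():
        if len(tt) == 1:
            out[next(iter(tt))].add(pair)
    return dict(out)


def group_exclusive_pairs(instances, group) -> set:
    """Pairs whose full tumour-type support is contained in ``group``.

    Pairs seen in a single member of the group are excluded: a
    group-exclusive pair must involve more than one of the named types
    (e.g. pairs shared by, and only by, LUAD and LUSC).
    """
    group = set(group)
    return {pair for pair, tt in _pair_types(instances).items()
            if 1 < len(tt) and tt <= group}


def specificity_test(instances) -> pd.DataFrame:
    """Right-tailed Fisher promiscuity test over all pair instances.

    For each distinct pair (m, g) the instance multiset is crossed as
    [[#(m,g), #(m, not g)], [#(not m, g), #(not m, not g)]]; a small p
    means the pair recurs across tumours while both partners have few
    co-interactors. BH adjustment is over all tested pairs.
    """
    instances = list(instances)
    if not instances:
        raise ValueError("specificity_test needs at least one pair instance")
    n = len(instances)
    pair_n = Counter((i.mirna_id, i.gene_id) for i in instances)
    mir_n = Counter(i.mirna_id for i in instances)
    gene_n = Counter(i.gene_id for i in instances)
    rows = []
    for (m, g), a in sorted(pair_n.items()):
        b = mir_n[m] - a
        c = gene_n[g] - a
        d = n - a - b - c
        _, p_right, _ = fisher_2x2(((a, b), (c, d)))
        rows.append({"mirna": m, "gene": g, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": odds_ratio(a, b, c, d), "pvalue": p_right})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def flag_novel(pairs: pd.DataFrame, known_pairs) -> pd.DataFrame:
    """Mark each (mirna, gene) row validated/novel against a known-pair list."""
    known = {(normalize_mirna(m), g) for m, g in known_pairs}
    out = pairs.copy()
    out["status"] = [
        "validated" if (normalize_mirna(m), g) in known else "novel"
        for m, g in zip(out["mirna"], out["gene"])
    ]
    return out
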