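"""End-to-end orchestration: validate -> DE -> enrichment -> recurrence ->
pairing -> covariate regression -> survival.

Every stage writes a self-describing TSV (header comment lines carry the
parameter snapshot) under the output directory, and a structured log line
records each filter's in/out counts so the discovery funnel (expressed ->
DE -> recurrent -> paired -> regression-significant -> survival-supported)
can be reconstructed from the logs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import enrichment as enr_mod
from . import integration as int_mod
from . import pairing as pair_mod
from . import regression as reg_mod
from . import survival as surv_mod
from .io import read_cohort, validate_cohort
from .matrix import TUMOUR
from .pairing import normalize_mirna
from .simulate import SyntheticCohort

log = logging.getLogger("mirpair.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "build_pair_bundles"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds, defaulting to the published analysis values."""

    cohort_dir: str = ""
    out_dir: str = "results"
    fdr: float = 0.05
    lfc: float = 1.0
    cpm: float = 1.0
    agreement: int = 2
    scan_min: int = 5
    scan_max: int = 10
    min_controls: int = 10
    min_control_fraction: float = 0.05
    recurrence_threshold: int | None = None  # None -> optimise by enrichment
    joint: bool = True
    exclusive_group: list | None = None      # e.g. ["LUAD", "LUSC"]
    enrichment_control_reps: int = 0
    seed: int = 0
    resume: bool = False

    def validate(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.lfc < 0 or self.cpm < 0:
            raise ValueError("lfc and cpm thresholds must be non-negative")
        if self.agreement < 1:
            raise ValueError("agreement must be >= 1")
        if self.scan_min < 1 or self.scan_max < self.scan_min:
            raise ValueError("scan range must satisfy 1 <= scan_min <= scan_max")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _snapshot(config: PipelineConfig) -> str:
    items = ", ".join(f"{k}={v}" for k, v in sorted(vars(config).items()))
    return f"# mirpair parameters: {items}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_snapshot(config))
        df.to_csv(fh, sep="\t", index=index)


def _log_filter(stage: str, n_in: int, n_out: int) -> None:
    log.info("filter stage=%s in=%d out=%d", stage, n_in, n_out)


def build_pair_bundles(cohort: SyntheticCohort, pairs) -> dict:
    """Per-(pair, tumour type) regression frames over tumour samples.

    ``pairs`` is an iterable of (mirna, gene); miRNA ids are matched
    through name normalisation. A tumour type where a member is undetected
    maps to ``None`` (recorded as a nonexistent dataset downstream).
    """
    per_type_expr = {}
    for ttype, data in cohort.types.items():
        tum = data.genes.samples_in_group(TUMOUR)
        gene_log = reg_mod.log_expression(
            reg_mod.rpkm(data.genes, cohort.gene_lengths))[tum]
        mir_log = reg_mod.log_expression(
            reg_mod.rpkm(data.mirnas, cohort.mirna_lengths))[tum]
        mir_map = {normalize_mirna(m): m for m in mir_log.index}
        met_m = (reg_mod.beta_to_m(data.met[ [c for c in tum if c in data.met.columns] ])
                 if data.met is not None else None)
        per_type_expr[ttype] = (gene_log, mir_log, mir_map, data.cna, met_m)
    probe_lookup = cohort.probe_map.groupby("gene")["probe"].apply(list).to_dict()

    bundles: dict = {}
    for mirna, gene in pairs:
        mkey = normalize_mirna(mirna)
        per_type: dict = {}
        for ttype, (gene_log, mir_log, mir_map, cna, met_m) in per_type_expr.items():
            if gene not in gene_log.index or mkey not in mir_map:
                per_type[ttype] = None
                continue
            d = pd.DataFrame({
                "gene_expr": gene_log.loc[gene],
                "mir_expr": mir_log.loc[mir_map[mkey]],
            })
            if gene in cna.index:
                d["cna"] = cna.loc[gene].reindex(d.index)
            if met_m is not None:
                for probe in probe_lookup.get(gene, []):
                    if probe in met_m.index:
                        d[f"met_{probe}"] = met_m.loc[probe].reindex(d.index)
            per_type[ttype] = d
        bundles[(mkey, gene)] = per_type
    return bundles


def _clinical_with_prognosis(cohort: SyntheticCohort) -> dict:
    out = {}
    for ttype, data in cohort.types.items():
        clin = data.clinical.copy()
        gleason = ttype == cohort.gleason_type
        prognosis = []
        for raw in clin["stage_or_gleason"]:
            try:
                prognosis.append(surv_mod.encode_prognosis(raw, gleason=gleason))
            except ValueError as exc:
                warnings.warn(f"{ttype}: excluding record ({exc})")
                prognosis.append(None)
        clin["prognosis"] = prognosis
        out[ttype] = clin.dropna(subset=["prognosis"])
    return out


def run_pipeline(config: PipelineConfig,
                 cohort: SyntheticCohort | None = None) -> dict:
    """Execute the full integrative analysis; returns all stage outputs.

    Stage order mirrors the analysis: cohort validation, per-tumour DE for
    genes and miRNAs, pathway enrichment, cross-tumour recurrence with
    threshold optimisation, pairing (conserved / exclusive / specificity /
    novelty), covariate-adjusted regression with the negative-correlation
    selection, and stage-adjusted survival with the combined support calls.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        cohort = read_cohort(config.cohort_dir)

    # ---- validation -------------------------------------------------------
    sheets = {
        ttype: pd.DataFrame({"sample_id": d.genes.sample_ids,
                             "group": d.genes.groups.to_numpy()})
        for ttype, d in cohort.types.items()
    }
    accepted, report = validate_cohort(sheets, config.min_controls,
                                       config.min_control_fraction)
    _log_filter("validate_cohort", len(sheets), len(accepted))
    _write_tsv(report, out_dir / "cohort_report.tsv", config)

    # ---- per-tumour differential expression -------------------------------
    de_genes_tables, de_mirna_tables = {}, {}
    de_genes, de_mirnas = {}, {}
    universes = {}
    for ttype in accepted:
        data = cohort.types[ttype]
        for label, cm, store, table_store in (
                ("genes", data.genes, de_genes, de_genes_tables),
                ("mirnas", data.mirnas, de_mirnas, de_mirna_tables)):
            path = out_dir / "de" / f"{ttype}.{label}.tsv"
            if config.resume and path.exists():
                res = pd.read_csv(path, sep="\t", comment="#", index_col=0)
            else:
                res = de_mod.de_analysis(cm, cpm_threshold=config.cpm)
                _write_tsv(res, path, config, index=True)
            table_store[ttype] = res
            sel = de_mod.select_de(res, config.fdr, config.lfc)
            store[ttype] = dict(zip(sel.index, sel["direction"]))
            _log_filter(f"de.{label}.{ttype}", len(res), len(sel))
        universes[ttype] = set(de_genes_tables[ttype].index)

    # ---- pathway enrichment ----------------------------------------------
    enr_rows = []
    for ttype in accepted:
        results = enr_mod.enrich_pathways(
            set(de_genes[ttype]) & universes[ttype], universes[ttype],
            cohort.pathways)
        for r in results:
            (a, b), (c, d) = r.table
            enr_rows.append({"tumour_type": ttype, "pathway": r.pathway,
                             "a": a, "b": b, "c": c, "d": d,
                             "odds_ratio": r.odds_ratio_reported,
                             "pvalue": r.pvalue, "fdr": r.fdr,
                             "direction": r.direction})
    enrichment = pd.DataFrame(enr_rows)
    _write_tsv(enrichment, out_dir / "pathway_enrichment.tsv", config)

    # ---- recurrence and threshold choice ----------------------------------
    scan_range = range(config.scan_min, config.scan_max + 1)
    gene_table = int_mod.recurrence_table(de_genes)
    mir_table = int_mod.recurrence_table(de_mirnas)
    thresholds, scans = {}, {}
    for label, table, known, universe in (
            ("genes", gene_table, cohort.known_genes,
             set().union(*universes.values()) if universes else set()),
            ("mirnas", mir_table, cohort.known_mirnas,
             set().union(*(set(t.index) for t in de_mirna_tables.values()))
             if de_mirna_tables else set())):
        if config.recurrence_threshold is not None:
            thresholds[label] = config.recurrence_threshold
            scans[label] = pd.DataFrame()
            continue
        try:
            chosen, scan = int_mod.optimize_threshold(
                table, set(known) & universe, universe, scan_range, config.fdr)
        except int_mod.NoEnrichableThreshold:
            warnings.warn(f"{label}: no enrichable recurrence threshold; "
                          f"falling back to {config.scan_min + 3}")
            chosen, scan = config.scan_min + 3, pd.DataFrame()
        thresholds[label] = chosen
        scans[label] = scan
        if len(scan):
            _write_tsv(scan, out_dir / f"recurrence_scan.{label}.tsv", config)
    recurrent_genes = int_mod.select_recurrent(gene_table, thresholds["genes"])
    recurrent_mirnas = int_mod.select_recurrent(mir_table, thresholds["mirnas"])
    _log_filter("recurrent.genes", len(gene_table), len(recurrent_genes))
    _log_filter("recurrent.mirnas", len(mir_table), len(recurrent_mirnas))
    rec_rows = [{"feature": f, "kind": kind,
                 "n_types": len({t for t, _ in hits}),
                 "types": ",".join(sorted({t for t, _ in hits})),
                 "directions": ",".join(f"{t}:{d}" for t, d in sorted(hits))}
                for kind, table in (("gene", gene_table), ("mirna", mir_table))
                for f, hits in sorted(table.items())]
    _write_tsv(pd.DataFrame(rec_rows), out_dir / "recurrence.tsv", config)

    # ---- pairing -----------------------------------------------------------
    pathway_universe = set().union(*cohort.pathways.values()) if cohort.pathways else set()
    instances = pair_mod.candidate_pairs(
        de_genes, de_mirnas, cohort.catalog, config.agreement, pathway_universe)
    _log_filter("candidate_pairs", len(cohort.catalog), len(instances))
    conserved = pair_mod.conserved_pairs(instances, set(recurrent_genes),
                                         set(recurrent_mirnas))
    conserved = pair_mod.flag_novel(conserved, cohort.known_pairs)
    _log_filter("conserved_pairs", len({(i.mirna_id, i.gene_id) for i in instances}),
                len(conserved))
    specificity = (pair_mod.specificity_test(instances)
                   if instances else pd.DataFrame())
    exclusive = pair_mod.exclusive_pairs(instances)
    _write_tsv(conserved.assign(
        tumour_types=[",".join(t) for t in conserved["tumour_types"]],
        orientations=[",".join(o) for o in conserved["orientations"]]),
        out_dir / "conserved_pairs.tsv", config)
    if len(specificity):
        _write_tsv(specificity, out_dir / "specificity.tsv", config)
    group_excl = (pair_mod.group_exclusive_pairs(instances, config.exclusive_group)
                  if config.exclusive_group else set())

    # ---- covariate regression ----------------------------------------------
    pair_list = list(zip(conserved["mirna"], conserved["gene"]))
    bundles = build_pair_bundles(cohort, pair_list)
    pair_results = (reg_mod.analyse_pairs(bundles, joint=config.joint)
                    if bundles else pd.DataFrame())
    if len(pair_results):
        _write_tsv(pair_results, out_dir / "pair_models.tsv", config)
        selected = reg_mod.select_significant_negative(pair_results, config.fdr)
    else:
        selected = pd.DataFrame(columns=["mirna_id", "gene_id", "correlation",
                                         "t_stat", "pvalue", "fdr"])
    _log_filter("significant_negative_pairs", len(pair_list), len(selected))
    _write_tsv(selected, out_dir / "selected_pairs.tsv", config)

    # ---- survival -----------------------------------------------------------
    clinical = {t: c for t, c in _clinical_with_prognosis(cohort).items()
                if t in accepted}
    expr_by_type = {
        ttype: reg_mod.log_expression(reg_mod.rpkm(
            cohort.types[ttype].genes, cohort.gene_lengths))[
            cohort.types[ttype].genes.samples_in_group(TUMOUR)]
        for ttype in accepted
    }
    surv_features = sorted(set(selected["gene_id"]))
    surv = surv_mod.survival_scan(clinical, expr_by_type, surv_features)
    if len(surv):
        _write_tsv(surv, out_dir / "survival.tsv", config)
    sel_keys = set(zip(selected["mirna_id"], selected["gene_id"]))
    combined = surv_mod.combine_correlation_survival(
        pair_results[[k in sel_keys for k in
                      zip(pair_results.get("mirna_id", []),
                          pair_results.get("gene_id", []))]]
        if len(pair_results) else pd.DataFrame(), surv, config.fdr)
    if len(combined):
        _write_tsv(combined, out_dir / "pair_survival_matrix.tsv", config)
    n_supported = (combined.loc[combined["supported"], ["mirna", "gene"]]
                   .drop_duplicates().shape[0] if len(combined) else 0)
    _log_filter("survival_supported_pairs", len(selected), n_supported)

    manifest = _run_manifest(config, cohort)
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "accepted_types": accepted,
        "cohort_report": report,
        "de_genes": de_genes,
        "de_mirnas": de_mirnas,
        "enrichment": enrichment,
        "recurrence": {"genes": gene_table, "mirnas": mir_table},
        "thresholds": thresholds,
        "scans": scans,
        "recurrent_genes": recurrent_genes,
        "recurrent_mirnas": recurrent_mirnas,
        "instances": instances,
        "conserved_pairs": conserved,
        "exclusive_pairs": exclusive,
        "group_exclusive_pairs": group_excl,
        "specificity": specificity,
        "pair_results": pair_results,
        "selected_pairs": selected,
        "survival": surv,
        "combined": combined,
        "manifest": manifest,
    }


def _run_manifest(config: PipelineConfig, cohort: SyntheticCohort) -> dict:
    """Parameter snapshot + deterministic input hashes."""
    hasher = hashlib.sha256()
    hashes = {}
    if config.cohort_dir and Path(config.cohort_dir).exists():
        for path in sorted(Path(config.cohort_dir).rglob("*")):
            if path.is_file():
                h = hashlib.sha256(path.read_bytes()).hexdigest()
                hashes[str(path.relative_to(config.cohort_dir))] = h
                hasher.update(h.encode())
    else:  # in-memory cohort: hash the count matrices
        for ttype, data in sorted(cohort.types.items()):
            for label, cm in (("genes", data.genes), ("mirnas", data.mirnas)):
                h = hashlib.sha256(
                    cm.counts.to_csv(sep="\t").encode()).hexdigest()
                hashes[f"{ttype}/{label}"] = h
                hasher.update(h.encode())
    import platform
    import time

    import lifelines
    import scipy
    import statsmodels

    from . import __version__
    params = {k: (list(v) if isinstance(v, (list, tuple)) else v)
              for k, v in vars(config).items()}
    versions = {"mirpair": __version__, "python": platform.python_version(),
                "numpy": np.__version__, "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
                "lifelines": lifelines.__version__}
    return {"params": params, "input_hashes": hashes,
            "combined_hash": hasher.hexdigest(), "versions": versions,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
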