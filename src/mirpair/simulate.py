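"""Synthetic multi-tumour cohort generator with planted ground truth.

Emulates the statistical structure the pipeline assumes: negative-binomial
counts around log-linear means with planted differential expression,
repressive miRNA->gene couplings of configurable slope, copy-number and
methylation confounding of gene expression, and survival times whose hazard
depends on stage and on selected genes' expression -- plus the matching
predicted-target catalogue (with agreement-1 and non-interacting decoys),
pathway GMT, known-feature and known-pair lists. Everything is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CONTROL, TUMOUR, CountMatrix
from .regression import log_expression, rpkm

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "TumourTypeData",
    "generate_cohort",
    "write_cohort",
    "simulate_survival",
]

PATHWAY_NAMES = (
    "apoptosis", "necrosis", "senescence", "ddr",
    "cell_cycle", "dna_replication", "telomere_elongation",
)

#: log hazard ratio of bad vs good prognosis in the survival generator
STAGE_LOG_HR = 0.8
#: baseline exponential hazard (per day)
BASELINE_HAZARD = 1.0 / 1000.0
#: fraction of tumour samples with bad prognosis
BAD_STAGE_RATE = 0.4
#: CNA level probabilities for levels -2..2
CNA_LEVEL_PROBS = (0.02, 0.08, 0.80, 0.08, 0.02)

MIRNA_LENGTH_BP = 22


class SimConfigError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic multi-tumour cohort.

    Counts are drawn NB with ``var = mu + dispersion * mu**2`` around
    log-linear means; ``planted_lfc`` is the log2 shift of planted-DE
    features in tumour samples of their ``planted_recurrence`` tumour
    types; ``pair_slope`` (< 0, log2 gene expression per log2 miRNA
    expression) couples planted pairs; ``cna_effect`` / ``met_effect`` are
    log2 expression shifts per CNA level and per M-value unit.
    """

    n_tumour_types: int = 15
    n_genes: int = 500
    n_mirnas: int = 150
    n_controls_per_type: int = 15
    n_tumours_per_type: int = 50
    baseline_mean_log2: float = 6.0
    dispersion: float = 0.1
    planted_de_fraction: float = 0.2
    planted_lfc: float = 2.0
    n_planted_pairs: int = 30
    pair_slope: float = -0.5
    planted_recurrence: int = 10
    cna_effect: float = 0.5
    met_effect: float = -0.25
    probes_per_gene: int = 3
    survival_gene_loghr: float = 0.7
    censor_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for f in ("n_tumour_types", "n_genes", "n_mirnas",
                  "n_controls_per_type", "n_tumours_per_type"):
            if int(getattr(self, f)) < 1:
                raise SimConfigError(f"{f} must be >= 1")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if not 0 <= self.planted_de_fraction < 1:
            raise SimConfigError("planted_de_fraction must lie in [0, 1)")
        if self.n_planted_pairs < 0:
            raise SimConfigError("n_planted_pairs must be >= 0")
        if self.n_planted_pairs > 0 and self.pair_slope > 0:
            raise SimConfigError("pair_slope must be <= 0 (planted pairs are repressive)")
        if not 1 <= self.planted_recurrence <= self.n_tumour_types:
            raise SimConfigError(
                "planted_recurrence must lie in 1..n_tumour_types")
        if self.probes_per_gene < 0:
            raise SimConfigError("probes_per_gene must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise SimConfigError("censor_rate must lie in [0, 1)")
        n_pg = round(self.planted_de_fraction * self.n_genes)
        n_pm = round(self.planted_de_fraction * self.n_mirnas)
        if self.n_planted_pairs > min(self.n_genes, self.n_mirnas):
            raise SimConfigError("n_planted_pairs exceeds the feature space")
        if self.n_planted_pairs > 0 and self.n_planted_pairs > min(n_pg, n_pm):
            raise SimConfigError(
                "n_planted_pairs exceeds the planted-DE feature count implied "
                "by planted_de_fraction")


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    de_genes_by_type: dict      # type -> set of (gene, direction)
    de_mirnas_by_type: dict     # type -> set of (mirna, direction)
    planted_pairs: set          # {(mirna, gene)}
    survival_genes: dict        # gene -> true per-unit log HR
    known_cancer_genes: set
    known_cancer_mirnas: set


@dataclass
class TumourTypeData:
    genes: CountMatrix
    mirnas: CountMatrix
    cna: pd.DataFrame            # genes x tumour samples, levels -2..2
    met: pd.DataFrame | None     # probes x tumour samples, beta values
    clinical: pd.DataFrame       # tumour samples: time, event, stage_or_gleason


@dataclass
class SyntheticCohort:
    types: dict                  # tumour type -> TumourTypeData
    gene_lengths: pd.Series
    mirna_lengths: pd.Series
    probe_map: pd.DataFrame      # columns probe, gene
    catalog: pd.DataFrame        # columns mirna, gene, agreement
    pathways: dict               # pathway -> set of genes
    known_pairs: list            # [(mirna, gene)]
    known_genes: set
    known_mirnas: set
    gleason_type: str            # the PRAD-like type using Gleason grading


def _planted_assignments(cfg: SimConfig, rng, genes, mirnas, type_names):
    """Choose planted-DE features, their directions, type sets and pairs."""
    n_pg = round(cfg.planted_de_fraction * cfg.n_genes)
    n_pm = round(cfg.planted_de_fraction * cfg.n_mirnas)
    planted_genes = list(rng.choice(genes, size=n_pg, replace=False)) if n_pg else []
    planted_mirs = list(rng.choice(mirnas, size=n_pm, replace=False)) if n_pm else []
    pairs = list(zip(planted_mirs[:cfg.n_planted_pairs],
                     planted_genes[:cfg.n_planted_pairs]))
    gene_dir: dict = {}
    mir_dir: dict = {}
    type_sets: dict = {}  # feature -> set of tumour types where planted DE
    for i, (m, g) in enumerate(pairs):
        up_mir = i % 2 == 0
        mir_dir[m] = "up" if up_mir else "down"
        gene_dir[g] = "down" if up_mir else "up"
        shared = set(rng.choice(type_names, size=cfg.planted_recurrence,
                                replace=False))
        type_sets[m] = shared
        type_sets[g] = set(shared)
    for g in planted_genes[cfg.n_planted_pairs:]:
        gene_dir[g] = "up" if rng.random() < 0.5 else "down"
        type_sets[g] = set(rng.choice(type_names, size=cfg.planted_recurrence,
                                      replace=False))
    for m in planted_mirs[cfg.n_planted_pairs:]:
        mir_dir[m] = "up" if rng.random() < 0.5 else "down"
        type_sets[m] = set(rng.choice(type_names, size=cfg.planted_recurrence,
                                      replace=False))
    return planted_genes, planted_mirs, pairs, gene_dir, mir_dir, type_sets


def _nb_draw(rng, mean: np.ndarray, disp: float) -> np.ndarray:
    if disp < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mean))


def _build_catalog(cfg: SimConfig, rng, genes, mirnas, pairs, gene_dir, mir_dir):
    """Planted edges (agreement >= 2) plus agreement-1 and null decoys."""
    rows = [{"mirna": m, "gene": g, "agreement": int(rng.integers(2, 6))}
            for m, g in pairs]
    used = set(pairs)
    n_decoy = 10 * len(pairs)
    n_agree1 = n_decoy // 2

    def random_edge():
        return (str(rng.choice(mirnas)), str(rng.choice(genes)))

    # agreement-1 decoys: half among inversely planted-DE partners so the
    # agreement filter -- not the DE filter -- is what rejects them
    planted_up_m = [m for m, d in mir_dir.items() if d == "up"]
    planted_down_g = [g for g, d in gene_dir.items() if d == "down"]

    def fill(n_wanted, planted_quota, agreement):
        made = 0
        for attempt in range(50 * max(n_wanted, 1)):
            if made >= n_wanted or len(used) >= cfg.n_genes * cfg.n_mirnas - 1:
                break
            if made < planted_quota and planted_up_m and planted_down_g:
                edge = (str(rng.choice(planted_up_m)),
                        str(rng.choice(planted_down_g)))
                if edge in used:  # pool may be exhausted; fall back to random
                    edge = random_edge()
            else:
                edge = random_edge()
            if edge in used:
                continue
            used.add(edge)
            rows.append({"mirna": edge[0], "gene": edge[1],
                         "agreement": agreement()})
            made += 1

    fill(n_agree1, n_agree1 // 2, lambda: 1)
    fill(n_decoy - n_agree1, 0, lambda: int(rng.integers(2, 6)))
    return pd.DataFrame(rows, columns=["mirna", "gene", "agreement"])


def _build_pathways(cfg: SimConfig, rng, genes, pair_genes) -> dict:
    universe_size = max(len(pair_genes), int(0.6 * cfg.n_genes))
    extra = [g for g in genes if g not in set(pair_genes)]
    picked = list(rng.choice(extra, size=min(len(extra),
                                             universe_size - len(pair_genes)),
                             replace=False))
    universe = list(pair_genes) + picked
    size = max(1, len(universe) // 4)
    pathways = {name: set(rng.choice(universe, size=size, replace=False))
                for name in PATHWAY_NAMES}
    for i, g in enumerate(pair_genes):  # every pair gene sits in >= 1 pathway
        pathways[PATHWAY_NAMES[i % len(PATHWAY_NAMES)]].add(g)
    return pathways


def _known_list(rng, planted, others, fraction=0.5):
    n_known = int(round(fraction * len(planted)))
    known = set(rng.choice(planted, size=n_known, replace=False)) if n_known else set()
    n_bg = min(len(others), n_known)
    if n_bg:
        known |= set(rng.choice(others, size=n_bg, replace=False))
    return known


def generate_cohort(config: SimConfig) -> tuple[SyntheticCohort, SyntheticTruth]:
    """Draw a full multi-tumour cohort and its planted truth.

    Deterministic given ``config.seed``: one master stream fixes the
    cohort-level structure (baselines, planted features, catalogue,
    pathways, known lists) and per-type sub-streams fix each tumour type's
    samples.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    type_names = [f"T{i + 1:02d}" for i in range(cfg.n_tumour_types)]
    gleason_type = type_names[-1]
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    mirnas = [f"hsa-miR-{i + 1:03d}" for i in range(cfg.n_mirnas)]

    gene_base = rng.normal(cfg.baseline_mean_log2, 1.5, cfg.n_genes)
    mir_base = rng.normal(cfg.baseline_mean_log2, 1.5, cfg.n_mirnas)
    gene_lengths = pd.Series(
        np.round(rng.lognormal(np.log(1500), 0.5, cfg.n_genes)).astype(int) + 100,
        index=pd.Index(genes, name="gene"), name="length_bp")
    mirna_lengths = pd.Series(np.full(cfg.n_mirnas, MIRNA_LENGTH_BP),
                              index=pd.Index(mirnas, name="mirna"), name="length_bp")

    (planted_genes, planted_mirs, pairs, gene_dir, mir_dir,
     type_sets) = _planted_assignments(cfg, rng, genes, mirnas, type_names)
    pair_of_gene = {g: m for m, g in pairs}

    # methylation probe layout and baselines (shared across types)
    probes, probe_gene, probe_base = [], [], []
    for gi, g in enumerate(genes):
        for k in range(cfg.probes_per_gene):
            probes.append(f"cg{gi:05d}{k}")
            probe_gene.append(g)
            probe_base.append(rng.normal(0.0, 2.0))
    probe_map = pd.DataFrame({"probe": probes, "gene": probe_gene})
    probe_base = np.asarray(probe_base)

    catalog = _build_catalog(cfg, rng, genes, mirnas, pairs, gene_dir, mir_dir)
    pathways = _build_pathways(cfg, rng, genes, [g for _, g in pairs])
    known_genes = _known_list(rng, planted_genes,
                              [g for g in genes if g not in set(planted_genes)])
    known_mirnas = _known_list(rng, planted_mirs,
                               [m for m in mirnas if m not in set(planted_mirs)])
    n_known_pairs = int(round(0.4 * len(pairs)))
    known_pairs = [pairs[i] for i in
                   rng.choice(len(pairs), size=n_known_pairs, replace=False)] \
        if n_known_pairs else []

    # few hazard-carrying genes: each extra carrier acts as unmodelled
    # frailty in the single-gene Cox fits and attenuates every estimate
    surv_pairs = pairs[:min(5, len(pairs))]
    survival_genes = ({g: cfg.survival_gene_loghr for _, g in surv_pairs}
                      if cfg.survival_gene_loghr != 0 else {})

    gene_rel = 2.0 ** gene_base
    gene_prop = gene_rel / gene_rel.sum()
    mir_rel = 2.0 ** mir_base
    mir_prop = mir_rel / mir_rel.sum()

    types: dict = {}
    truth_genes: dict = {}
    truth_mirs: dict = {}
    for ti, ttype in enumerate(type_names):
        trng = np.random.default_rng([cfg.seed, 1 + ti])
        nc, nt = cfg.n_controls_per_type, cfg.n_tumours_per_type
        n = nc + nt
        samples = [f"{ttype}_C{i + 1:03d}" for i in range(nc)] + \
                  [f"{ttype}_T{i + 1:03d}" for i in range(nt)]
        tum_samples = samples[nc:]
        groups = pd.Series([CONTROL] * nc + [TUMOUR] * nt, index=samples)
        is_tumour = np.r_[np.zeros(nc, bool), np.ones(nt, bool)]

        depth_g = trng.lognormal(0.0, 0.3, n)
        depth_m = trng.lognormal(0.0, 0.3, n)

        # ---- miRNA counts -------------------------------------------------
        mir_shift = np.zeros((cfg.n_mirnas, n))
        de_m = set()
        for mi, m in enumerate(mirnas):
            if m in mir_dir and ttype in type_sets[m]:
                sgn = 1.0 if mir_dir[m] == "up" else -1.0
                mir_shift[mi, is_tumour] = sgn * cfg.planted_lfc
                de_m.add((m, mir_dir[m]))
        mir_mean = (mir_prop[:, None] * 1e6 * depth_m[None, :]) * 2.0 ** mir_shift
        mir_counts = _nb_draw(trng, mir_mean, cfg.dispersion)
        mir_cm = CountMatrix(pd.DataFrame(mir_counts, index=pd.Index(mirnas, name="feature"), columns=samples),
                             groups.copy(), ttype)
        mir_log = log_expression(rpkm(mir_cm, mirna_lengths))
        ctrl_mean = mir_log.iloc[:, :nc].mean(axis=1)
        mir_log_centered = mir_log.sub(ctrl_mean, axis=0)

        # ---- methylation and CNA -----------------------------------------
        met = None
        mean_m_centered = np.zeros((cfg.n_genes, n))
        if cfg.probes_per_gene > 0:
            m_vals = probe_base[:, None] + trng.normal(0.0, 0.7,
                                                       (len(probes), nt))
            beta = 1.0 / (1.0 + 2.0 ** (-m_vals))
            beta = np.clip(beta, 1e-6, 1 - 1e-6)
            met = pd.DataFrame(beta, index=pd.Index(probes, name="probe"), columns=tum_samples)
            per_gene = (m_vals - probe_base[:, None]).reshape(
                cfg.n_genes, cfg.probes_per_gene, nt).mean(axis=1)
            mean_m_centered[:, is_tumour] = per_gene
        cna_levels = trng.choice(np.arange(-2, 3), size=(cfg.n_genes, nt),
                                 p=CNA_LEVEL_PROBS)
        cna = pd.DataFrame(cna_levels, index=pd.Index(genes, name="gene"), columns=tum_samples)
        cna_full = np.zeros((cfg.n_genes, n))
        cna_full[:, is_tumour] = cna_levels

        # ---- gene counts --------------------------------------------------
        gene_shift = np.zeros((cfg.n_genes, n))
        de_g = set()
        for gi, g in enumerate(genes):
            if g in gene_dir and ttype in type_sets[g]:
                sgn = 1.0 if gene_dir[g] == "up" else -1.0
                gene_shift[gi, is_tumour] += sgn * cfg.planted_lfc
                de_g.add((g, gene_dir[g]))
            if g in pair_of_gene and cfg.pair_slope != 0:
                partner = pair_of_gene[g]
                gene_shift[gi] += cfg.pair_slope * \
                    mir_log_centered.loc[partner].to_numpy()
        gene_shift += cfg.cna_effect * cna_full
        gene_shift += cfg.met_effect * mean_m_centered
        gene_mean = (gene_prop[:, None] * 1e6 * depth_g[None, :]) * 2.0 ** gene_shift
        gene_counts = _nb_draw(trng, gene_mean, cfg.dispersion)
        gene_cm = CountMatrix(pd.DataFrame(gene_counts, index=pd.Index(genes, name="feature"), columns=samples),
                              groups.copy(), ttype)

        # ---- survival -----------------------------------------------------
        clinical = _survival_table(cfg, trng, ttype, gene_cm, gene_lengths,
                                   tum_samples, survival_genes,
                                   gleason=(ttype == gleason_type))

        types[ttype] = TumourTypeData(gene_cm, mir_cm, cna, met, clinical)
        truth_genes[ttype] = de_g
        truth_mirs[ttype] = de_m

    cohort = SyntheticCohort(
        types=types, gene_lengths=gene_lengths, mirna_lengths=mirna_lengths,
        probe_map=probe_map, catalog=catalog, pathways=pathways,
        known_pairs=known_pairs, known_genes=known_genes,
        known_mirnas=known_mirnas, gleason_type=gleason_type)
    truth = SyntheticTruth(
        de_genes_by_type=truth_genes, de_mirnas_by_type=truth_mirs,
        planted_pairs=set(pairs), survival_genes=survival_genes,
        known_cancer_genes=known_genes, known_cancer_mirnas=known_mirnas)
    return cohort, truth


def _survival_table(cfg, trng, ttype, gene_cm, gene_lengths, tum_samples,
                    survival_genes, gleason: bool) -> pd.DataFrame:
    nt = len(tum_samples)
    bad = trng.random(nt) < BAD_STAGE_RATE
    log_haz = np.log(BASELINE_HAZARD) + STAGE_LOG_HR * bad.astype(float)
    if survival_genes:
        expr = log_expression(rpkm(gene_cm, gene_lengths))[tum_samples]
        for g, loghr in survival_genes.items():
            x = expr.loc[g].to_numpy()
            sd = x.std()
            if sd > 0:
                log_haz += loghr * (x - x.mean()) / sd
    rate = np.exp(log_haz)
    t_event = trng.exponential(1.0 / rate)
    if cfg.censor_rate > 0:
        c_rate = rate * cfg.censor_rate / (1.0 - cfg.censor_rate)
        t_cens = trng.exponential(1.0 / c_rate)
    else:
        t_cens = np.full(nt, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    if gleason:
        good_lab = np.array(["Gleason 6", "Gleason 7"])
        bad_lab = np.array(["Gleason 8", "Gleason 9", "Gleason 10"])
    else:
        good_lab = np.array(["Stage I", "Stage IA", "Stage IB",
                             "Stage II", "Stage IIA", "Stage IIB"])
        bad_lab = np.array(["Stage III", "Stage IIIA", "Stage IIIB",
                            "Stage IV", "Stage X"])
    stage = np.where(bad, trng.choice(bad_lab, nt), trng.choice(good_lab, nt))
    return pd.DataFrame({
        "time": np.maximum(time, 1e-6), "event": event,
        "stage_or_gleason": stage,
    }, index=pd.Index(tum_samples, name="sample_id"))


def simulate_survival(n: int, log_hr: float, censor_rate: float = 0.4,
                      seed: int = 0):
    """Stand-alone survival draw for calibration studies.

    Returns ``(clinical, covariate)``: a clinical frame (time, event,
    prognosis) and the standard-normal expression covariate whose true
    per-unit log hazard ratio is ``log_hr``.
    """
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    bad = rng.random(n) < BAD_STAGE_RATE
    rate = BASELINE_HAZARD * np.exp(STAGE_LOG_HR * bad + log_hr * z)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = rng.exponential((1.0 - censor_rate) / (censor_rate * rate))
    else:
        t_cens = np.full(n, np.inf)
    idx = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    clinical = pd.DataFrame({
        "time": np.minimum(t_event, t_cens),
        "event": (t_event <= t_cens).astype(int),
        "prognosis": np.where(bad, "bad", "good"),
    }, index=idx)
    return clinical, pd.Series(z, index=idx, name="expr")


# ---------------------------------------------------------------------------
# on-disk representation


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write the cohort as the pipeline's TSV/GMT input formats.

    Returns a manifest (also written as ``manifest.json``) listing every
    file; re-reading with :func:`mirpair.io.read_cohort` reproduces the
    in-memory cohort exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict = {}

    def _write(key, path, writer):
        writer(path)
        files[key] = str(path.relative_to(directory))

    _write("gene_lengths", directory / "gene_lengths.tsv",
           lambda p: cohort.gene_lengths.rename_axis("gene").to_csv(p, sep="\t"))
    _write("mirna_lengths", directory / "mirna_lengths.tsv",
           lambda p: cohort.mirna_lengths.rename_axis("mirna").to_csv(p, sep="\t"))
    _write("targets", directory / "targets.tsv",
           lambda p: cohort.catalog.to_csv(p, sep="\t", index=False))
    _write("probe_map", directory / "probe_map.tsv",
           lambda p: cohort.probe_map.to_csv(p, sep="\t", index=False))
    _write("known_genes", directory / "known_genes.txt",
           lambda p: p.write_text("".join(f"{g}\n" for g in sorted(cohort.known_genes))))
    _write("known_mirnas", directory / "known_mirnas.txt",
           lambda p: p.write_text("".join(f"{m}\n" for m in sorted(cohort.known_mirnas))))
    _write("known_pairs", directory / "known_pairs.tsv",
           lambda p: pd.DataFrame(cohort.known_pairs, columns=["mirna", "gene"])
           .to_csv(p, sep="\t", index=False))
    _write("pathways", directory / "pathways.gmt",
           lambda p: p.write_text("".join(
               "\t".join([name, "synthetic"] + sorted(genes)) + "\n"
               for name, genes in cohort.pathways.items())))

    met_absent = []
    for ttype, data in cohort.types.items():
        tdir = directory / ttype
        tdir.mkdir(exist_ok=True)
        _write(f"{ttype}/gene_counts", tdir / "gene_counts.tsv",
               lambda p, d=data: d.genes.counts.rename_axis("feature").to_csv(p, sep="\t"))
        _write(f"{ttype}/mirna_counts", tdir / "mirna_counts.tsv",
               lambda p, d=data: d.mirnas.counts.rename_axis("feature").to_csv(p, sep="\t"))
        sheet = pd.DataFrame({
            "sample_id": data.genes.sample_ids,
            "group": data.genes.groups.to_numpy(),
            "tumour_type": ttype,
        })
        _write(f"{ttype}/samples", tdir / "samples.tsv",
               lambda p, s=sheet: s.to_csv(p, sep="\t", index=False))
        _write(f"{ttype}/cna", tdir / "cna.tsv",
               lambda p, d=data: d.cna.rename_axis("gene").to_csv(p, sep="\t"))
        if data.met is not None:
            _write(f"{ttype}/met", tdir / "met_beta.tsv",
                   lambda p, d=data: d.met.rename_axis("probe").to_csv(p, sep="\t"))
        else:
            met_absent.append(ttype)
        _write(f"{ttype}/clinical", tdir / "clinical.tsv",
               lambda p, d=data: d.clinical.to_csv(p, sep="\t"))

    manifest = {
        "types": list(cohort.types),
        "gleason_type": cohort.gleason_type,
        "files": files,
        "met_absent": met_absent,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
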