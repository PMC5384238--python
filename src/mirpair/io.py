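"""Readers and writers for the pipeline's plain-text interchange formats.

Counts are features x samples TSV (or MatrixMarket MTX with sidecar
row/column files) with a sample sheet (sample_id, group, tumour_type);
pathways are GMT; targets, CNA levels, methylation betas, probe maps and
clinical tables are TSV; known-feature lists are one id per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .matrix import CountMatrix
from .simulate import SyntheticCohort, TumourTypeData

__all__ = [
    "read_counts", "write_counts_mtx", "read_counts_mtx",
    "read_sample_sheet", "read_gmt", "read_targets", "read_id_list",
    "read_known_pairs", "read_cohort", "validate_cohort",
]


def read_counts(path, sample_sheet: pd.DataFrame | None = None,
                tumour_type: str = "") -> pd.DataFrame | CountMatrix:
    """Read a features x samples count TSV; with a sample sheet, a CountMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "feature"
    if sample_sheet is None:
        return df
    groups = sample_sheet.set_index("sample_id")["group"]
    return CountMatrix(df, groups.reindex(df.columns), tumour_type)


def write_counts_mtx(df: pd.DataFrame, prefix) -> None:
    """Write counts as MatrixMarket with sidecar row/column files."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), csr_matrix(df.to_numpy()))
    prefix.with_suffix(".rows.txt").write_text("".join(f"{r}\n" for r in df.index))
    prefix.with_suffix(".cols.txt").write_text("".join(f"{c}\n" for c in df.columns))


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = mmread(str(prefix.with_suffix(".mtx"))).toarray()
    rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
    cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
    return pd.DataFrame(mat, index=pd.Index(rows, name="feature"), columns=cols)


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")
    return sheet


def read_gmt(path) -> dict:
    """GMT: one pathway per line, tab-separated name, description, genes."""
    catalog = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        catalog[parts[0]] = set(parts[2:])
    return catalog


def read_targets(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"mirna", "gene", "agreement"} - set(df.columns)
    if missing:
        raise ValueError(f"target table missing column(s): {sorted(missing)}")
    return df


def read_id_list(path) -> set:
    return {line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()}


def read_known_pairs(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["mirna"], df["gene"]))


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort directory written by :func:`mirpair.simulate.write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    gene_lengths = pd.read_csv(directory / "gene_lengths.tsv", sep="\t",
                               index_col=0)["length_bp"]
    mirna_lengths = pd.read_csv(directory / "mirna_lengths.tsv", sep="\t",
                                index_col=0)["length_bp"]
    probe_map = pd.read_csv(directory / "probe_map.tsv", sep="\t")
    catalog = read_targets(directory / "targets.tsv")
    pathways = read_gmt(directory / "pathways.gmt")
    known_pairs = read_known_pairs(directory / "known_pairs.tsv")
    known_genes = read_id_list(directory / "known_genes.txt")
    known_mirnas = read_id_list(directory / "known_mirnas.txt")

    types = {}
    for ttype in manifest["types"]:
        tdir = directory / ttype
        sheet = read_sample_sheet(tdir / "samples.tsv")
        genes = read_counts(tdir / "gene_counts.tsv", sheet, ttype)
        mirnas = read_counts(tdir / "mirna_counts.tsv", sheet, ttype)
        cna = pd.read_csv(tdir / "cna.tsv", sep="\t", index_col=0)
        met_path = tdir / "met_beta.tsv"
        met = pd.read_csv(met_path, sep="\t", index_col=0) if met_path.exists() else None
        clinical = pd.read_csv(tdir / "clinical.tsv", sep="\t", index_col=0)
        types[ttype] = TumourTypeData(genes, mirnas, cna, met, clinical)
    return SyntheticCohort(
        types=types, gene_lengths=gene_lengths, mirna_lengths=mirna_lengths,
        probe_map=probe_map, catalog=catalog, pathways=pathways,
        known_pairs=known_pairs, known_genes=known_genes,
        known_mirnas=known_mirnas, gleason_type=manifest["gleason_type"])


def validate_cohort(sample_sheets: dict, min_controls: int = 10,
                    min_control_fraction: float = 0.05):
    """Apply the cohort-inclusion filter to per-type sample sheets.

    A tumour type is accepted iff it has at least ``min_controls`` healthy
    samples and controls make up at least ``min_control_fraction`` of its
    samples. Returns ``(accepted type list, report DataFrame)``; the report
    lists each exclusion with its reason.
    """
    accepted, rows = [], []
    for ttype, sheet in sample_sheets.items():
        ids = sheet["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample ids in {ttype}: {dupes[:5]}")
        n_control = int((sheet["group"] == "control").sum())
        n_total = len(sheet)
        frac = n_control / n_total if n_total else 0.0
        reasons = []
        if n_control < min_controls:
            reasons.append(f"fewer than {min_controls} healthy samples")
        if frac < min_control_fraction:
            reasons.append(
                f"healthy samples below {min_control_fraction:.0%} of total")
        ok = not reasons
        if ok:
            accepted.append(ttype)
        rows.append({"tumour_type": ttype, "n_control": n_control,
                     "n_total": n_total, "control_fraction": frac,
                     "accepted": ok, "reason": "; ".join(reasons)})
    return accepted, pd.DataFrame(rows)
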