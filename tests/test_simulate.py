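"""Synthetic-cohort generator: determinism, invariants, round-trips."""

import numpy as np
import pandas as pd
import pytest

from mirpair.io import read_cohort
from mirpair.simulate import (SimConfig, SimConfigError, generate_cohort,
                              write_cohort)


def test_null_model_has_empty_truth():
    cfg = SimConfig(n_tumour_types=2, n_genes=40, n_mirnas=10,
                    n_controls_per_type=10, n_tumours_per_type=10,
                    planted_de_fraction=0.0, n_planted_pairs=0,
                    planted_recurrence=1, seed=0)
    cohort, truth = generate_cohort(cfg)
    assert all(len(s) == 0 for s in truth.de_genes_by_type.values())
    assert all(len(s) == 0 for s in truth.de_mirnas_by_type.values())
    assert truth.planted_pairs == set()


def test_same_seed_byte_identical_cohorts(tmp_path):
    cfg = SimConfig(n_tumour_types=2, n_genes=50, n_mirnas=15,
                    n_controls_per_type=10, n_tumours_per_type=12,
                    n_planted_pairs=3, planted_recurrence=2, seed=42)
    for d in ("a", "b"):
        cohort, _ = generate_cohort(SimConfig(**vars(cfg)))
        write_cohort(cohort, tmp_path / d)
    files_a = sorted((tmp_path / "a").rglob("*"))
    files_b = sorted((tmp_path / "b").rglob("*"))
    assert [f.name for f in files_a] == [f.name for f in files_b]
    for fa, fb in zip(files_a, files_b):
        if fa.is_file():
            assert fa.read_bytes() == fb.read_bytes(), fa.name


def test_write_read_round_trip(tmp_path, small_cohort):
    _, cohort, _ = small_cohort
    manifest = write_cohort(cohort, tmp_path / "c")
    back = read_cohort(tmp_path / "c")
    for ttype, data in cohort.types.items():
        other = back.types[ttype]
        assert data.genes == other.genes
        assert data.mirnas == other.mirnas
        pd.testing.assert_frame_equal(data.cna, other.cna)
        pd.testing.assert_frame_equal(data.met, other.met)
        pd.testing.assert_frame_equal(data.clinical, other.clinical)
    pd.testing.assert_series_equal(cohort.gene_lengths, back.gene_lengths)
    pd.testing.assert_frame_equal(cohort.catalog, back.catalog)
    assert cohort.pathways == back.pathways
    assert set(cohort.known_pairs) == set(back.known_pairs)
    assert cohort.gleason_type == back.gleason_type
    expected = {"gene_counts", "mirna_counts", "samples", "cna", "met",
                "clinical"}
    got = {k.split("/")[1] for k in manifest["files"] if "/" in k}
    assert expected <= got


def test_manifest_notes_absent_methylation(tmp_path):
    cfg = SimConfig(n_tumour_types=1, n_genes=30, n_mirnas=10,
                    n_controls_per_type=10, n_tumours_per_type=10,
                    probes_per_gene=0, n_planted_pairs=2,
                    planted_recurrence=1, seed=1)
    cohort, _ = generate_cohort(cfg)
    manifest = write_cohort(cohort, tmp_path / "nomet")
    assert manifest["met_absent"] == ["T01"]
    assert not (tmp_path / "nomet" / "T01" / "met_beta.tsv").exists()
    assert not any(k.endswith("/met") for k in manifest["files"])


def test_value_range_invariants(small_cohort):
    _, cohort, _ = small_cohort
    for data in cohort.types.values():
        counts = data.genes.counts.to_numpy()
        assert counts.min() >= 0 and np.issubdtype(counts.dtype, np.integer)
        beta = data.met.to_numpy()
        assert (beta > 0).all() and (beta < 1).all()
        assert set(np.unique(data.cna.to_numpy())) <= {-2, -1, 0, 1, 2}
        assert (data.clinical["time"] > 0).all()
        assert set(data.clinical["event"].unique()) <= {0, 1}
    assert (cohort.catalog["agreement"] >= 1).all()
    assert not cohort.catalog.duplicated(["mirna", "gene"]).any()


def test_planted_pairs_are_inversely_de_in_enough_types(small_cohort):
    cfg, cohort, truth = small_cohort
    for mirna, gene in truth.planted_pairs:
        shared = 0
        for ttype in cohort.types:
            gd = dict(truth.de_genes_by_type[ttype])
            md = dict(truth.de_mirnas_by_type[ttype])
            if gene in gd and mirna in md:
                assert gd[gene] != md[mirna]  # opposite directions
                shared += 1
        assert shared >= cfg.planted_recurrence


def test_planted_pairs_have_catalog_agreement_two_plus(small_cohort):
    _, cohort, truth = small_cohort
    edges = cohort.catalog.set_index(["mirna", "gene"])["agreement"]
    for pair in truth.planted_pairs:
        assert edges[pair] >= 2
    # decoys outnumber planted edges 10x
    assert len(cohort.catalog) == 11 * len(truth.planted_pairs)


def test_pair_genes_lie_in_pathway_universe(small_cohort):
    _, cohort, truth = small_cohort
    universe = set().union(*cohort.pathways.values())
    for _, gene in truth.planted_pairs:
        assert gene in universe


@pytest.mark.parametrize("field,value,match", [
    ("n_genes", 0, "n_genes"),
    ("dispersion", -0.1, "dispersion"),
    ("planted_de_fraction", 1.5, "planted_de_fraction"),
    ("planted_recurrence", 99, "planted_recurrence"),
    ("pair_slope", 0.5, "pair_slope"),
    ("censor_rate", 1.0, "censor_rate"),
    ("n_planted_pairs", 1000, "n_planted_pairs"),
])
def test_invalid_config_names_field(field, value, match):
    cfg = SimConfig()
    setattr(cfg, field, value)
    with pytest.raises(SimConfigError, match=match):
        cfg.validate()


def test_stronger_coupling_never_detects_fewer_pairs():
    """Planted-pair detection is monotone in |pair_slope| (seed averages)."""
    from mirpair.pairing import normalize_mirna
    from mirpair.pipeline import build_pair_bundles
    from mirpair.regression import analyse_pairs, select_significant_negative
    import warnings

    def detected(slope, seed):
        cfg = SimConfig(n_tumour_types=4, n_genes=100, n_mirnas=30,
                        n_controls_per_type=8, n_tumours_per_type=20,
                        n_planted_pairs=5, planted_recurrence=4,
                        pair_slope=slope, seed=seed)
        cohort, truth = generate_cohort(cfg)
        bundles = build_pair_bundles(cohort, sorted(truth.planted_pairs))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_significant_negative(analyse_pairs(bundles))
        planted = {(normalize_mirna(m), g) for m, g in truth.planted_pairs}
        return len(set(zip(sel["mirna_id"], sel["gene_id"])) & planted)

    counts = {s: sum(detected(s, seed) for seed in range(3))
              for s in (0.0, -0.3, -0.9)}
    assert counts[0.0] <= counts[-0.3] <= counts[-0.9]


def test_gleason_type_uses_gleason_labels(small_cohort):
    _, cohort, _ = small_cohort
    gleason = cohort.types[cohort.gleason_type].clinical["stage_or_gleason"]
    assert gleason.str.startswith("Gleason").all()
    other = next(t for t in cohort.types if t != cohort.gleason_type)
    assert cohort.types[other].clinical["stage_or_gleason"].str.startswith(
        "Stage").all()
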