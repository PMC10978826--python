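"""Synthetic-data generator: determinism, divergence calibration, inclusion
model, defect bookkeeping, and agreement with downstream pipeline calls."""

import numpy as np
import pandas as pd
import pytest

from barcode_audit import (
    ConfigurationError,
    SimulationConfig,
    align_identity,
    call_species_gap,
    curate_records,
    gap_prevalence,
    identity_search,
    simulate_barcodes,
    simulate_catalogue,
    simulate_records,
    taxonomic_coverage,
)
from barcode_audit.simulate import expected_mismatch_fraction


def small_cfg(**kw):
    base = dict(seed=1, n_species=30, n_countries=6, sequence_length=120,
                seqs_per_species=("fixed", 2))
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_divergence_bounds(self):
        with pytest.raises(ConfigurationError):
            small_cfg(intra_divergence=0.9)
        with pytest.raises(ConfigurationError):
            small_cfg(intra_divergence=0.2, inter_divergence=0.1)

    def test_single_country_needs_full_endemism(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(seed=1, n_species=5, n_countries=1,
                             endemic_frac=0.5)

    def test_fraction_bounds(self):
        with pytest.raises(ConfigurationError):
            small_cfg(endemic_frac=1.5)


class TestCatalogueGeneration:
    def test_full_endemism(self):
        cat, truth = simulate_catalogue(small_cfg(endemic_frac=1.0))
        assert all(len(cat.countries_of[sp]) == 1 for sp in cat.species)
        assert truth["endemic"].all()

    def test_endemic_fraction_matches_target(self):
        cfg = small_cfg(n_species=200, endemic_frac=0.5)
        cat, truth = simulate_catalogue(cfg)
        realized = truth["endemic"].mean()
        assert abs(realized - 0.5) <= 1 / cfg.n_species + 1e-12

    def test_determinism(self):
        cfg = small_cfg()
        cat1, t1 = simulate_catalogue(cfg)
        cat2, t2 = simulate_catalogue(cfg)
        assert cat1.countries_of == cat2.countries_of
        assert cat1.medical == cat2.medical
        pd.testing.assert_frame_equal(t1, t2)

    def test_study_scale_counts(self):
        cfg = SimulationConfig(seed=3)
        cat, _ = simulate_catalogue(cfg)
        assert cat.n_species == 3570
        assert cat.n_countries == 317


class TestBarcodeGeneration:
    def test_zero_intra_divergence_gives_identical_conspecifics(self):
        cfg = small_cfg(intra_divergence=0.0, inter_divergence=0.2,
                        n_species=6, n_countries=3,
                        seqs_per_species=("fixed", 3))
        cat, _ = simulate_catalogue(cfg)
        seqs, truth = simulate_barcodes(cat, cfg)
        intra = truth.pairwise_mismatch.query("conspecific")
        assert (intra["mismatch_fraction"] == 0.0).all()
        pair = intra.iloc[0]
        pident, _, _ = align_identity(seqs[pair["id_a"]], seqs[pair["id_b"]])
        assert pident == 100.0

    def test_fasta_determinism(self):
        cfg = small_cfg()
        seqs1, _ = simulate_barcodes(simulate_catalogue(cfg)[0], cfg)
        seqs2, _ = simulate_barcodes(simulate_catalogue(cfg)[0], cfg)
        assert seqs1 == seqs2

    def test_conspecific_divergence_calibration(self):
        """Mean realised conspecific mismatch fraction sits within 3
        Monte-Carlo SEs of the Jukes-Cantor expectation."""
        cfg = SimulationConfig(
            seed=11, n_species=100, n_countries=5, sequence_length=658,
            intra_divergence=0.02, inter_divergence=0.2,
            seqs_per_species=("fixed", 2),
        )
        cat, _ = simulate_catalogue(cfg)
        _, truth = simulate_barcodes(cat, cfg)
        intra = truth.pairwise_mismatch.query("conspecific")["mismatch_fraction"]
        assert len(intra) >= 100  # 100 species x 1 conspecific pair
        expected = expected_mismatch_fraction(cfg.intra_divergence)
        mc_se = intra.std(ddof=1) / np.sqrt(len(intra))
        assert abs(intra.mean() - expected) < 3 * mc_se

    def test_heterospecific_divergence_calibration(self):
        cfg = SimulationConfig(
            seed=12, n_species=40, n_countries=5, sequence_length=658,
            intra_divergence=0.01, inter_divergence=0.15,
            seqs_per_species=("fixed", 1),
        )
        cat, _ = simulate_catalogue(cfg)
        _, truth = simulate_barcodes(cat, cfg)
        inter = truth.pairwise_mismatch.query("~conspecific")["mismatch_fraction"]
        expected = expected_mismatch_fraction(cfg.inter_divergence)
        # heterospecific pairs share centroids and the root, so the naive
        # per-pair MC standard error understates the sampling noise; a 5%
        # relative band is the honest check here
        assert abs(inter.mean() - expected) < 0.05 * expected

    def test_truth_gap_labels_match_pipeline_when_separated(self):
        """In the well-separated regime the generator's own gap labels
        (raw divergences) and the alignment pipeline agree."""
        cfg = SimulationConfig(
            seed=13, n_species=20, n_countries=4, sequence_length=300,
            intra_divergence=0.01, inter_divergence=0.15,
            seqs_per_species=("fixed", 3),
        )
        cat, _ = simulate_catalogue(cfg)
        seqs, truth = simulate_barcodes(cat, cfg)
        hits = identity_search(seqs, top_k=len(seqs))
        calls = {
            r.species: r.gap_present
            for r in call_species_gap(hits, truth.species_of)
        }
        labels = dict(zip(truth.gap_labels["species"], truth.gap_labels["gap_true"]))
        agree = np.mean([calls[sp] == labels[sp] for sp in calls])
        assert agree >= 0.99


class TestRecordGeneration:
    def test_inclusion_probability_one_gives_full_coverage(self):
        cfg = small_cfg(coverage_intercept=1000.0, coverage_betas=(0.0,),
                        group_sigma=0.0)
        cat, _ = simulate_catalogue(cfg)
        records, truth = simulate_records(cat, cfg)
        tt = truth.country_table
        assert (tt["n_covered_true"] == tt["n_cat_species"]).all()
        for _, row in tt.iterrows():
            assert taxonomic_coverage(
                int(row["n_covered_true"]), int(row["n_cat_species"])
            ) == 100.0

    def test_inclusion_probability_zero_gives_empty_table(self):
        cfg = small_cfg(coverage_intercept=-1000.0, coverage_betas=(0.0,),
                        group_sigma=0.0)
        cat, _ = simulate_catalogue(cfg)
        records, truth = simulate_records(cat, cfg)
        assert records == []
        assert (truth.country_table["n_covered_true"] == 0).all()

    def test_determinism(self):
        cfg = small_cfg(defect_frac=0.2)
        cat, _ = simulate_catalogue(cfg)
        r1, t1 = simulate_records(cat, cfg)
        r2, t2 = simulate_records(cat, cfg)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1.country_table, t2.country_table)

    def test_defect_free_curation_is_noop(self):
        cfg = small_cfg(defect_frac=0.0)
        cat, _ = simulate_catalogue(cfg)
        records, truth = simulate_records(cat, cfg)
        curated, report = curate_records(records, cat, cfg.marker)
        assert {r.record_id for r in curated} == truth.clean_record_ids
        assert all(s.rows_removed == 0 for s in report.stages)

    def test_curation_removes_exactly_the_injected_defects(self):
        cfg = small_cfg(defect_frac=0.3, n_species=60, n_countries=8)
        cat, _ = simulate_catalogue(cfg)
        records, truth = simulate_records(cat, cfg)
        n_defects = sum(r.record_id.startswith("DEF") for r in records)
        assert n_defects > 0
        curated, _ = curate_records(records, cat, cfg.marker)
        assert {r.record_id for r in curated} == truth.clean_record_ids

    def test_country_inflation_sacrifices_species(self):
        cfg = small_cfg(defect_frac=0.5, n_species=60, n_countries=8,
                        defect_types=("extra_country",))
        cat, _ = simulate_catalogue(cfg)
        records, truth = simulate_records(cat, cfg)
        assert truth.sacrificed_species
        curated, _ = curate_records(records, cat, cfg.marker)
        surviving_species = {r.species_name for r in curated}
        assert not (surviving_species & truth.sacrificed_species)
        assert {r.record_id for r in curated} == truth.clean_record_ids


def test_end_to_end_gap_prevalence_separated_small():
    """Pipeline-level check at reduced scale: well-separated divergences
    produce a universal barcode gap."""
    cfg = SimulationConfig(
        seed=17, n_species=10, n_countries=3, sequence_length=300,
        intra_divergence=0.01, inter_divergence=0.15,
        seqs_per_species=("fixed", 3),
    )
    cat, _ = simulate_catalogue(cfg)
    seqs, truth = simulate_barcodes(cat, cfg)
    hits = identity_search(seqs, top_k=100)
    res = call_species_gap(hits, truth.species_of)
    assert gap_prevalence(res) == 100.0
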