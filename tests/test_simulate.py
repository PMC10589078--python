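import math

import numpy as np
import pandas as pd
import pytest

from pollenniche.nutrition import survival_summary
from pollenniche.simulate import (
    SimulationConfig,
    generate_provision_nutrition,
    generate_rearing_outcomes,
    generate_reference_db,
    generate_sample_reads,
    implied_ratio_mean,
    paper_like_config,
    tiny_config,
    write_fixture_set,
)


class TestConfigValidation:
    def test_rates_must_be_fractions(self):
        with pytest.raises(ValueError, match="mislabel_rate"):
            SimulationConfig(seed=1, mislabel_rate=1.5)

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(seed=1, composition={"Malus": 0.5, "Acer": 0.4})

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="SD"):
            SimulationConfig(seed=1, lipid_sd=-1.0)

    def test_survival_probabilities_validated(self):
        with pytest.raises(ValueError, match="baddiet"):
            SimulationConfig(seed=1, diet_survival={"baddiet": (1.2, 0.5, 0.5)})


class TestReferenceDbGenerator:
    def test_zero_mislabel_rate_plants_nothing(self):
        refset = generate_reference_db(tiny_config(1))
        assert (refset.truth.status == "mislabeled").sum() == 0

    def test_mislabel_bookkeeping_is_exact(self):
        cfg = SimulationConfig(seed=2, n_genera=10, species_per_genus=5,
                               mislabel_rate=0.1, nonplant_contaminant_count=6)
        refset = generate_reference_db(cfg)
        truth = refset.truth
        assert len(truth) == 100  # 10 genera x 5 species x 2 loci
        assert (truth.status == "mislabeled").sum() == 10
        # planted sequences really are exact copies from the stated source
        by_id = {b.id: b for recs in refset.barcodes.values() for b in recs}
        plant_seqs = {r.sequence for r in refset.plant.records}
        for row in truth[truth.status == "mislabeled"].itertuples():
            seq = by_id[row.barcode_id].sequence
            if row.source == "non_plant":
                assert any(seq in r.sequence for r in refset.nonplant.records)
            else:
                assert any(seq in s for s in plant_seqs)

    def test_same_seed_gives_identical_databases(self):
        a = generate_reference_db(paper_like_config(5))
        b = generate_reference_db(paper_like_config(5))
        for locus in a.barcodes:
            assert [(x.id, x.sequence) for x in a.barcodes[locus]] == \
                   [(x.id, x.sequence) for x in b.barcodes[locus]]
        assert a.truth.equals(b.truth)

    def test_truth_covers_every_barcode_exactly_once(self):
        refset = generate_reference_db(paper_like_config(3))
        all_ids = [b.id for recs in refset.barcodes.values() for b in recs]
        assert sorted(refset.truth.barcode_id) == sorted(all_ids)
        assert refset.truth.barcode_id.is_unique


class TestReadGenerator:
    def test_zero_error_single_genus_reads_copy_references(self):
        cfg = SimulationConfig(seed=3, n_genera=2, species_per_genus=2,
                               barcode_length=80,
                               composition={"Malus": 1.0},
                               reads_per_locus=50,
                               substitution_error_rate=0.0)
        refset = generate_reference_db(cfg)
        reads, truth = generate_sample_reads(cfg, refset, "S1")
        assert set(truth.genus) == {"Malus"}
        for locus in ("ITS1", "ITS2"):
            templates = {s for _, s in refset.true_sequences[locus]["Malus"]}
            assert all(r.sequence in templates for r in reads[locus])

    def test_amplification_bias_reweights_locus_shares(self):
        # composition 50/50 with a 2x ITS1 bias for Malus -> expected ITS1
        # share of Malus = 2/3; check within 3 binomial SDs
        cfg = SimulationConfig(
            seed=4, n_genera=2, species_per_genus=2, barcode_length=80,
            composition={"Malus": 0.5, "Cercis": 0.5},
            locus_bias={"ITS1": {"Malus": 2.0}},
            reads_per_locus=2000, substitution_error_rate=0.0,
        )
        refset = generate_reference_db(cfg)
        _, truth = generate_sample_reads(cfg, refset, "S1")
        its1 = truth[truth.locus == "ITS1"]
        share = (its1.genus == "Malus").mean()
        sd = math.sqrt((2 / 3) * (1 / 3) / 2000)
        assert abs(share - 2 / 3) < 3 * sd
        its2 = truth[truth.locus == "ITS2"]
        assert abs((its2.genus == "Malus").mean() - 0.5) < 3 * math.sqrt(0.25 / 2000)

    def test_zero_reads_is_valid_and_empty(self):
        cfg = tiny_config(1)
        cfg.reads_per_locus = 0
        refset = generate_reference_db(cfg)
        reads, truth = generate_sample_reads(cfg, refset, "S1")
        assert all(not v for v in reads.values()) and truth.empty

    def test_unknown_composition_genus_rejected(self):
        cfg = tiny_config(1)
        refset = generate_reference_db(cfg)
        cfg.composition = {"Quercus": 1.0}
        with pytest.raises(ValueError, match="Quercus"):
            generate_sample_reads(cfg, refset, "S1")

    def test_different_samples_use_independent_substreams(self):
        cfg = tiny_config(6)
        refset = generate_reference_db(cfg)
        reads_a, _ = generate_sample_reads(cfg, refset, "S1")
        reads_b, _ = generate_sample_reads(cfg, refset, "S2")
        reads_a2, _ = generate_sample_reads(cfg, refset, "S1")
        assert [r.sequence for r in reads_a["ITS1"]] == \
               [r.sequence for r in reads_a2["ITS1"]]
        assert [r.sequence for r in reads_a["ITS1"]] != \
               [r.sequence for r in reads_b["ITS1"]]


class TestNutritionGenerator:
    def test_zero_sd_degenerates_to_the_means(self):
        cfg = SimulationConfig(seed=1, protein_sd=0.0, lipid_sd=0.0)
        samples = generate_provision_nutrition(cfg, 10)
        assert all(s.protein == cfg.protein_mean for s in samples)
        assert all(s.lipid == cfg.lipid_mean for s in samples)

    def test_same_seed_gives_identical_tables(self):
        cfg = SimulationConfig(seed=8)
        a = generate_provision_nutrition(cfg, 20)
        assert a == generate_provision_nutrition(cfg, 20)

    def test_moment_recovery_at_large_n(self):
        cfg = SimulationConfig(seed=1)
        samples = generate_provision_nutrition(cfg, 10_000)
        protein = np.array([s.protein for s in samples])
        lipid = np.array([s.lipid for s in samples])
        # truncation bias is negligible at these CVs; 3-sigma CLT bounds
        assert abs(protein.mean() - cfg.protein_mean) < 3 * cfg.protein_sd / 100
        assert abs(lipid.mean() - cfg.lipid_mean) < 3 * cfg.lipid_sd / 100
        assert (protein > 0).all() and (lipid > 0).all()

    def test_ratio_mean_matches_finite_sample_prediction(self):
        cfg = SimulationConfig(seed=1)
        n = 10_000
        samples = generate_provision_nutrition(cfg, n)
        ratios = np.array([s.protein / s.lipid for s in samples])
        se = ratios.std(ddof=1) / math.sqrt(n)
        assert abs(ratios.mean() - implied_ratio_mean(cfg, n=n)) < 2 * se

    def test_metadata_assigned_round_robin(self):
        cfg = SimulationConfig(seed=1)
        samples = generate_provision_nutrition(cfg, 9)
        assert [s.site for s in samples[:5]] == ["A", "B", "C", "D", "A"]
        assert [s.week for s in samples[:7]] == [1, 2, 3, 4, 5, 6, 1]

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            generate_provision_nutrition(SimulationConfig(seed=1), 0)


class TestRearingGenerator:
    def test_certain_survival_reaches_adult_everywhere(self):
        cfg = SimulationConfig(seed=1, diet_survival={"d": (1.0, 1.0, 1.0)})
        records = generate_rearing_outcomes(cfg, 10)
        assert all(r.adult_survived for r in records)

    def test_zero_cocoon_probability_zeroes_the_summary(self):
        cfg = SimulationConfig(seed=1, diet_survival={"d": (0.0, 1.0, 1.0)})
        row = survival_summary(generate_rearing_outcomes(cfg, 10)).iloc[0]
        assert row.pct_cocoon == 0.0
        assert math.isnan(row.pct_pupated) and math.isnan(row.pct_adult)

    def test_observed_rate_within_binomial_bounds(self):
        cfg = SimulationConfig(seed=2, diet_survival={"d": (0.6, 1.0, 1.0)})
        records = generate_rearing_outcomes(cfg, 500)
        observed = sum(r.cocoon_completed for r in records) / 500
        assert abs(observed - 0.6) < 3 * math.sqrt(0.6 * 0.4 / 500)

    def test_timings_unknown_for_unreached_stages(self):
        cfg = SimulationConfig(seed=3, diet_survival={"d": (0.5, 0.5, 0.5)})
        for rec in generate_rearing_outcomes(cfg, 50):
            assert (rec.hatch_to_cocoon_days is None) == (not rec.cocoon_completed)
            assert (rec.cocoon_to_pupation_days is None) == (not rec.pupated)


class TestFixtureSet:
    def test_same_seed_writes_byte_identical_files(self, tmp_path):
        cfg = tiny_config(7)
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        write_fixture_set(cfg, dir_a, n_samples=1, n_nutrition=5, n_per_diet=3)
        write_fixture_set(cfg, dir_b, n_samples=1, n_nutrition=5, n_per_diet=3)
        names = sorted(p.name for p in dir_a.iterdir())
        assert names == sorted(p.name for p in dir_b.iterdir())
        for name in names:
            if name == "manifest.tsv":
                continue  # holds absolute paths into each directory
            assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes(), name

    def test_fixture_set_is_complete(self, tmp_path):
        manifest_path = write_fixture_set(
            tiny_config(7), tmp_path, n_samples=2, n_nutrition=5, n_per_diet=3
        )
        expected = {
            "references_ITS1.fasta", "references_ITS2.fasta", "lineages.tsv",
            "plant_contrast.fasta", "plant_lineages.tsv",
            "nonplant_contrast.fasta", "nonplant_lineages.tsv",
            "truth_barcodes.tsv", "truth_reads.tsv", "truth_composition.tsv",
            "nutrition.tsv", "rearing.tsv", "manifest.tsv",
        }
        present = {p.name for p in tmp_path.iterdir()}
        assert expected <= present
        assert manifest_path.name == "manifest.tsv"
        reads = pd.read_csv(tmp_path / "truth_reads.tsv", sep="\t")
        assert set(reads.sample_id) == {"WP01", "WP02"}
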