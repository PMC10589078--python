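from types import SimpleNamespace

import numpy as np
import pytest

from pollenniche.refdb import (
    CORRECTLY_LABELED,
    MISLABELED,
    RULE_NON_MAGNOLIOPSIDA,
    RULE_NONPLANT_EXACT,
    RULE_PLANT_MATCH,
    RULE_PLANT_MISMATCH,
    RULE_TOPHIT_OTHER,
    RULE_TOPHIT_SAME,
    BarcodeRecord,
    ContrastDatabase,
    ContrastRecord,
    clean_database,
    exact_full_matches,
    flag_barcode,
)
from pollenniche.simulate import generate_reference_db, SimulationConfig
from pollenniche.taxonomy import Lineage

from _oracles import semiglobal_oracle, substring_offsets_oracle


def _plant_lineage(genus, species=None, class_="Magnoliopsida"):
    return Lineage(("Viridiplantae", "Streptophyta", class_, "Rosales",
                    "Rosaceae", genus, species or f"{genus} demo"))


def _fungal_lineage(genus="Cladosporium"):
    return Lineage(("Fungi", "Ascomycota", "Dothideomycetes", "Capnodiales",
                    "Cladosporiaceae", genus, f"{genus} demo"))


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def plant_db(rng):
    seqs = {g: _rand_seq(rng, 100) for g in ("Malus", "Prunus", "Rubus")}
    return seqs, ContrastDatabase(
        "plant",
        tuple(ContrastRecord(f"PL_{g}", s, _plant_lineage(g))
              for g, s in seqs.items()),
    )


@pytest.fixture
def nonplant_db(rng):
    return ContrastDatabase(
        "non_plant",
        tuple(ContrastRecord(f"NP_{i}", _rand_seq(rng, 100), _fungal_lineage())
              for i in range(3)),
    )


class TestExactFullMatches:
    def test_equal_length_identity(self):
        bc = BarcodeRecord("b", "ITS1", "ACGTACGT", _plant_lineage("Malus"))
        db = ContrastDatabase("plant", (ContrastRecord("r1", "ACGTACGT"),))
        assert exact_full_matches(bc, db) == ["r1"]

    def test_single_mismatch_breaks_the_hit(self):
        bc = BarcodeRecord("b", "ITS1", "ACGTACGT", _plant_lineage("Malus"))
        db = ContrastDatabase("plant", (ContrastRecord("r1", "ACGTACGA"),))
        assert exact_full_matches(bc, db) == []

    def test_substring_containment_counts_as_full_coverage(self):
        bc = BarcodeRecord("b", "ITS1", "CGTAC", _plant_lineage("Malus"))
        db = ContrastDatabase("plant", (ContrastRecord("r1", "AACGTACGTT"),))
        assert exact_full_matches(bc, db) == ["r1"]

    def test_n_in_barcode_precludes_any_hit(self):
        bc = BarcodeRecord("b", "ITS1", "ACGNACGT", _plant_lineage("Malus"))
        db = ContrastDatabase("plant", (ContrastRecord("r1", "ACGNACGT"),))
        assert exact_full_matches(bc, db) == []

    def test_invalid_characters_rejected(self):
        bad = SimpleNamespace(id="b", sequence="ACGU")
        db = ContrastDatabase("plant", (ContrastRecord("r1", "ACGT"),))
        with pytest.raises(ValueError, match="ACGTN"):
            exact_full_matches(bad, db)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_naive_offset_scan(self, seed):
        rng = np.random.default_rng(seed)
        hay = _rand_seq(rng, 60)
        for _ in range(20):
            k = int(rng.integers(3, 12))
            if rng.random() < 0.5:
                off = int(rng.integers(0, 60 - k))
                needle = hay[off:off + k]
            else:
                needle = _rand_seq(rng, k)
            bc = BarcodeRecord("b", "ITS1", needle, _plant_lineage("Malus"))
            db = ContrastDatabase("plant", (ContrastRecord("r1", hay),))
            expected = ["r1"] if substring_offsets_oracle(needle, hay) else []
            assert exact_full_matches(bc, db) == expected


class TestFlagBarcode:
    def test_fungal_copy_flagged_by_rule_one(self, plant_db, nonplant_db):
        _, plant = plant_db
        fungal_seq = nonplant_db.records[0].sequence
        bc = BarcodeRecord("b", "ITS1", fungal_seq, _plant_lineage("Malus"))
        decision = flag_barcode(bc, nonplant_db, plant)
        assert decision.status == MISLABELED
        assert decision.rule == RULE_NONPLANT_EXACT
        assert decision.evidence == ("NP_0",)

    def test_own_genus_plant_copy_confirmed(self, plant_db, nonplant_db):
        seqs, plant = plant_db
        bc = BarcodeRecord("b", "ITS1", seqs["Malus"], _plant_lineage("Malus"))
        decision = flag_barcode(bc, nonplant_db, plant)
        assert decision.status == CORRECTLY_LABELED
        assert decision.rule == RULE_PLANT_MATCH

    def test_cross_genus_plant_copy_refuted(self, plant_db, nonplant_db):
        seqs, plant = plant_db
        bc = BarcodeRecord("b", "ITS1", seqs["Prunus"], _plant_lineage("Malus"))
        decision = flag_barcode(bc, nonplant_db, plant)
        assert decision.status == MISLABELED
        assert decision.rule == RULE_PLANT_MISMATCH

    def test_same_genus_wins_when_exact_hits_conflict(self, nonplant_db, rng):
        seq = _rand_seq(rng, 80)
        plant = ContrastDatabase("plant", (
            ContrastRecord("PL_same", seq, _plant_lineage("Malus")),
            ContrastRecord("PL_other", seq, _plant_lineage("Prunus")),
        ))
        bc = BarcodeRecord("b", "ITS1", seq, _plant_lineage("Malus"))
        decision = flag_barcode(bc, nonplant_db, plant)
        assert decision.status == CORRECTLY_LABELED
        assert decision.evidence == ("PL_same",)

    def test_relaxed_tophit_same_genus_confirms(self, plant_db, nonplant_db):
        seqs, plant = plant_db
        mutated = list(seqs["Malus"])
        for pos in (10, 40, 70):  # 3 of 100 bases -> 97% identity
            mutated[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[pos]]
        bc = BarcodeRecord("b", "ITS1", "".join(mutated), _plant_lineage("Malus"))
        decision = flag_barcode(bc, nonplant_db, plant)
        assert decision.status == CORRECTLY_LABELED
        assert decision.rule == RULE_TOPHIT_SAME
        # independent check: brute-force DP agrees the best accepted plant hit
        # (identity among alignments covering >=80% of the barcode) is Malus
        def oracle_key(rec):
            _, identity, coverage = semiglobal_oracle(bc.sequence, rec.sequence)
            return identity if coverage >= 0.8 else -1.0

        assert max(plant.records, key=oracle_key).lineage.genus == "Malus"

    def test_relaxed_tophit_other_genus_refutes(self, plant_db, nonplant_db):
        seqs, plant = plant_db
        mutated = seqs["Prunus"][:50] + ("A" if seqs["Prunus"][50] != "A" else "C") \
            + seqs["Prunus"][51:]
        bc = BarcodeRecord("b", "ITS1", mutated, _plant_lineage("Malus"))
        decision = flag_barcode(bc, nonplant_db, plant)
        assert decision.status == MISLABELED
        assert decision.rule == RULE_TOPHIT_OTHER

    def test_no_relaxed_hit_refutes_with_empty_evidence(self, plant_db, nonplant_db):
        seqs, plant = plant_db
        bc = BarcodeRecord("b", "ITS1", _rand_seq(np.random.default_rng(7), 100),
                           _plant_lineage("Malus"))
        decision = flag_barcode(bc, nonplant_db, plant,
                                relaxed_min_identity=0.99)
        assert decision.status == MISLABELED
        assert decision.rule == RULE_TOPHIT_OTHER
        assert decision.evidence == ()

    def test_non_magnoliopsida_exact_hit_overrides_genus_match(self, nonplant_db, rng):
        seq = _rand_seq(rng, 80)
        plant = ContrastDatabase("plant", (
            ContrastRecord("PL_fern", seq,
                           _plant_lineage("Malus", class_="Polypodiopsida")),
        ))
        bc = BarcodeRecord("b", "ITS1", seq, _plant_lineage("Malus"))
        decision = flag_barcode(bc, nonplant_db, plant)
        assert decision.status == MISLABELED
        assert decision.rule == RULE_NON_MAGNOLIOPSIDA

    def test_empty_contrast_database_rejected(self, plant_db):
        seqs, plant = plant_db
        bc = BarcodeRecord("b", "ITS1", seqs["Malus"], _plant_lineage("Malus"))
        with pytest.raises(ValueError, match="non-empty"):
            flag_barcode(bc, ContrastDatabase("non_plant", ()), plant)

    def test_unknown_genus_rejected_at_construction(self):
        with pytest.raises(ValueError, match="genus"):
            BarcodeRecord("b", "ITS1", "ACGT",
                          Lineage(("Viridiplantae",) + (None,) * 6))


class TestCleanDatabase:
    def test_all_concordant_database_keeps_everything(self, plant_db, nonplant_db):
        seqs, plant = plant_db
        barcodes = [
            BarcodeRecord(f"b_{g}", "ITS1", s, _plant_lineage(g))
            for g, s in seqs.items()
        ]
        retained, report = clean_database(barcodes, nonplant_db, plant)
        assert retained == barcodes
        assert report.removed_fraction() == {"ITS1": 0.0}

    def test_empty_collection_gives_empty_report(self, plant_db, nonplant_db):
        _, plant = plant_db
        retained, report = clean_database([], nonplant_db, plant)
        assert retained == [] and report.counts_by_rule() == {}

    def test_planted_mislabels_removed_exactly(self):
        # 100 barcodes (10 genera x 5 species x 2 loci), 10 planted mislabels
        cfg = SimulationConfig(seed=9, n_genera=10, species_per_genus=5,
                               barcode_length=120, mislabel_rate=0.1,
                               nonplant_contaminant_count=8)
        refset = generate_reference_db(cfg)
        truth_mislabeled = set(
            refset.truth[refset.truth.status == "mislabeled"].barcode_id
        )
        assert len(truth_mislabeled) == 10
        removed = set()
        for locus, barcodes in refset.barcodes.items():
            retained, _ = clean_database(barcodes, refset.nonplant, refset.plant)
            removed |= {b.id for b in barcodes} - {b.id for b in retained}
        assert removed == truth_mislabeled  # precision = recall = 1

    def test_decisions_do_not_depend_on_record_order(self, plant_db, nonplant_db, rng):
        seqs, plant = plant_db
        barcodes = [
            BarcodeRecord(f"b_{g}", "ITS1", s, _plant_lineage(g))
            for g, s in seqs.items()
        ]
        barcodes.append(
            BarcodeRecord("b_bad", "ITS1", seqs["Prunus"], _plant_lineage("Rubus"))
        )
        _, report_a = clean_database(barcodes, nonplant_db, plant)
        shuffled = list(barcodes)
        rng.shuffle(shuffled)
        _, report_b = clean_database(shuffled, nonplant_db, plant)
        decisions_a = {d.barcode_id: (d.status, d.rule, d.evidence)
                       for d in report_a.decisions}
        decisions_b = {d.barcode_id: (d.status, d.rule, d.evidence)
                       for d in report_b.decisions}
        assert decisions_a == decisions_b

    def test_report_counts_per_rule_and_locus(self, plant_db, nonplant_db):
        seqs, plant = plant_db
        barcodes = [
            BarcodeRecord("ok", "ITS1", seqs["Malus"], _plant_lineage("Malus")),
            BarcodeRecord("bad", "ITS2", seqs["Prunus"], _plant_lineage("Malus")),
        ]
        _, report = clean_database(barcodes, nonplant_db, plant)
        assert report.counts_by_rule() == {RULE_PLANT_MATCH: 1,
                                           RULE_PLANT_MISMATCH: 1}
        assert report.counts_by_locus_rule() == {
            ("ITS1", RULE_PLANT_MATCH): 1, ("ITS2", RULE_PLANT_MISMATCH): 1}
        assert report.removed_fraction() == {"ITS1": 0.0, "ITS2": 1.0}
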