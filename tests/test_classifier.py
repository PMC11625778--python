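import numpy as np
import pytest

import refforge as rf
from refforge.classifier import _query_words, _word_set, assigned_fraction

from conftest import grouped_reads


def _db(seq_by_id, lineage_by_id):
    records = [rf.SequenceRecord(id=i, seq=s) for i, s in seq_by_id.items()]
    tax = {i: rf.Taxonomy(l) for i, l in lineage_by_id.items()}
    return rf.ReferenceDB(records=records, taxonomy=tax)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestTrain:
    def test_word_prior_formula(self):
        rng = np.random.default_rng(0)
        db = _db(
            {"r1": _random_seq(rng, 100), "r2": _random_seq(rng, 100)},
            {"r1": ("Bacteria",), "r2": ("Bacteria",)},
        )
        model = rf.train(db, k=8)
        # a word present in exactly one of two references
        only_r1 = next(iter(model.word_sets[0] - model.word_sets[1]))
        assert model.word_prior(only_r1) == pytest.approx((1 + 0.5) / (2 + 1))
        # a word absent from every reference
        absent = next(w for w in range(4**8) if all(w not in s for s in model.word_sets))
        assert model.word_prior(absent) == pytest.approx(0.5 / 3)

    def test_reverse_complement_words_included(self):
        db = _db({"r1": "ACGTTGCAACGTAGCTAG"}, {"r1": ("Bacteria",)})
        model = rf.train(db, k=8)
        fwd = set(_query_words("ACGTTGCAACGTAGCTAG", 8))
        rev = set(_query_words("CTAGCTACGTTGCAACGT", 8))
        assert (fwd | rev) <= model.word_sets[0]

    def test_short_reference_rejected(self):
        db = _db({"r1": "ACGT"}, {"r1": ("Bacteria",)})
        with pytest.raises(ValueError, match="shorter"):
            rf.train(db, k=8)

    def test_model_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        db = _db(
            {"r1": _random_seq(rng, 80), "r2": _random_seq(rng, 80)},
            {"r1": ("Bacteria", "P1"), "r2": ("Bacteria", "P2")},
        )
        model = rf.train(db, k=8)
        model.save(tmp_path / "m.json")
        back = rf.ClassifierModel.load(tmp_path / "m.json")
        assert back.ref_ids == model.ref_ids
        assert back.word_sets == model.word_sets
        assert back.taxonomy == model.taxonomy


class TestClassify:
    def test_exact_copy_full_confidence(self):
        rng = np.random.default_rng(2)
        lineages = {
            "r1": ("Bacteria", "P1", "C1", "O1", "F1", "G1", "S1"),
            "r2": ("Bacteria", "P2", "C2", "O2", "F2", "G2", "S2"),
        }
        db = _db(
            {"r1": _random_seq(rng, 300), "r2": _random_seq(rng, 300)}, lineages
        )
        model = rf.train(db, k=8)
        a = rf.classify(db.records[0].seq, model, seed=0)
        assert a.lineage.ranks == lineages["r1"]
        assert all(c == 1.0 for c in a.confidence)

    def test_chimera_splits_genus_votes_but_keeps_family(self):
        """A 50/50 chimera of two genera in one family is confidently
        family-level but ambiguous (~0.5/0.5) at genus, so the reported
        lineage truncates at family."""
        rng = np.random.default_rng(3)
        shared_family = ("Bacteria", "P1", "C1", "O1", "F1")
        db = _db(
            {"g1": _random_seq(rng, 400), "g2": _random_seq(rng, 400)},
            {
                "g1": shared_family + ("G1", "S1"),
                "g2": shared_family + ("G2", "S2"),
            },
        )
        model = rf.train(db, k=8)
        chimera = db.records[0].seq[:200] + db.records[1].seq[200:]
        a = rf.classify(chimera, model, bootstraps=1000, seed=4)
        assert a.confidence[4] == 1.0  # family
        assert abs(a.confidence[5] - 0.5) <= 0.1  # genus
        assert a.lineage.depth == 5  # truncated at family

    def test_query_shorter_than_k_rejected(self):
        rng = np.random.default_rng(5)
        db = _db({"r1": _random_seq(rng, 100)}, {"r1": ("Bacteria",)})
        model = rf.train(db, k=8)
        with pytest.raises(ValueError):
            rf.classify("ACGT", model)

    def test_deterministic_under_seed(self, small_world):
        model = rf.train(small_world.reference_db())
        read = small_world.v3v4(small_world.taxa[3])
        a1 = rf.classify(read, model, seed=11)
        a2 = rf.classify(read, model, seed=11)
        assert a1.lineage == a2.lineage and a1.confidence == a2.confidence

    def test_vote_fractions_stable_across_seeds(self, small_world):
        model = rf.train(small_world.reference_db())
        read = small_world.v3v4(small_world.taxa[0])
        confs = [
            rf.classify(read, model, bootstraps=100, seed=s).confidence
            for s in range(4)
        ]
        for rank in range(7):
            vals = [c[rank] for c in confs]
            assert max(vals) - min(vals) <= 0.05 + 1e-9

    def test_error_free_reads_recover_species(self, small_world):
        """Error-free V3-V4 reads from training taxa return to their own
        species and genus at high accuracy."""
        model = rf.train(small_world.reference_db())
        reads, truth = grouped_reads(small_world, per_taxon=3, error_rate=0.0, seed=12)
        rng = np.random.default_rng(13)
        genus_ok = species_ok = 0
        for read in reads:
            a = rf.classify(read, model, seed=int(rng.integers(2**31)))
            want = small_world.taxonomy[truth[read.id]]
            genus_ok += a.lineage.ranks[5] == want.ranks[5]
            species_ok += a.lineage.ranks[6] == want.ranks[6]
        assert genus_ok / len(reads) >= 0.99
        assert species_ok / len(reads) >= 0.95


class TestAssignTable:
    def test_single_species_sample_has_unit_abundance(self):
        rng = np.random.default_rng(6)
        lineage = ("Bacteria", "P1", "C1", "O1", "F1", "G1", "S1")
        db = _db({"r1": _random_seq(rng, 300)}, {"r1": lineage})
        model = rf.train(db, k=8)
        reads = [
            rf.SequenceRecord(id=f"q{i}", seq=db.records[0].seq[j : j + 150])
            for i, j in enumerate(range(0, 100, 10))
        ]
        tables, assignments = rf.assign_table({"s1": reads}, model, seed=7)
        rel = tables["species"].relative()
        label = ";".join(lineage)
        col = tables["species"].asv_ids.index(label)
        assert rel[0, col] == pytest.approx(1.0)

    def test_relative_abundances_sum_to_one_per_rank(self, small_world):
        model = rf.train(small_world.reference_db())
        reads, _ = rf.simulate_reads(small_world, "S1", "v3v4", depth=12, seed=8)
        tables, _ = rf.assign_table({"S1": reads}, model, seed=9)
        for rank, table in tables.items():
            assert table.relative().sum(axis=1) == pytest.approx([1.0])

    def test_missing_species_labels_reduce_species_fraction(self, small_world):
        """A DB whose species labels are stripped for half the taxa assigns
        fewer reads at species rank than at genus rank."""
        db = small_world.reference_db()
        stripped = {}
        for i, (rid, tax) in enumerate(db.taxonomy.items()):
            stripped[rid] = tax.truncate(6) if i % 2 == 0 else tax
        db2 = rf.ReferenceDB(records=db.records, taxonomy=stripped)
        model = rf.train(db2)
        reads, _ = grouped_reads(small_world, per_taxon=2, error_rate=0.0, seed=14)
        tables, _ = rf.assign_table(
            {"s": reads}, model, seed=15
        )
        f_species = assigned_fraction(tables["species"])
        f_genus = assigned_fraction(tables["genus"])
        assert f_species < f_genus
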