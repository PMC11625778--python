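import numpy as np
import pytest

import refforge as rf
from refforge.identity import reverse_complement


def dp_semiglobal_score(q, r, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Independent affine-gap oracle for the end-gap-free alignment score.

    Plain O(nm) Gotoh recursion over ref (i) x query (j): gaps along the
    matrix borders (one sequence's overhang past the other's end) are
    free, internal gaps of length L cost gap_open + L * gap_extend.
    """
    NEG = float("-inf")
    n, m = len(r), len(q)
    go = gap_open + gap_extend  # first gap column
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (ref consumed)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (query consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = 0.0  # ref left overhang free
    for j in range(1, m + 1):
        Iy[0][j] = 0.0  # query left overhang free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if r[i - 1] == q[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            # right-border gaps (j == m or i == n) are free end gaps
            if j == m:
                Ix[i][j] = max(M[i - 1][j], Ix[i - 1][j], Iy[i - 1][j])
            else:
                Ix[i][j] = max(M[i - 1][j] + go, Ix[i - 1][j] + gap_extend)
            if i == n:
                Iy[i][j] = max(M[i][j - 1], Iy[i][j - 1], Ix[i][j - 1])
            else:
                Iy[i][j] = max(M[i][j - 1] + go, Iy[i][j - 1] + gap_extend)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def _random_db(rng, n_refs=6, length=120):
    records = []
    for i in range(n_refs):
        records.append(
            rf.SequenceRecord(
                id=f"r{i}", seq="".join(rng.choice(list("ACGT"), length))
            )
        )
    tax = {r.id: rf.Taxonomy(("Bacteria",)) for r in records}
    return rf.ReferenceDB(records=records, taxonomy=tax)


class TestSemiglobalAlign:
    def test_identical_sequences(self):
        m, l, s = rf.semiglobal_align("ACGTACGTAC", "ACGTACGTAC")
        assert (m, l) == (10, 10)
        assert 100.0 * m / l == 100.0

    def test_single_substitution(self):
        rng = np.random.default_rng(0)
        ref = "".join(rng.choice(list("ACGT"), 100))
        q = ref[:50] + ("A" if ref[50] != "A" else "C") + ref[51:]
        m, l, _ = rf.semiglobal_align(q, ref)
        assert (m, l) == (99, 100)

    def test_substring_has_free_end_gaps(self):
        rng = np.random.default_rng(1)
        ref = "".join(rng.choice(list("ACGT"), 1500))
        q = ref[500:900]
        m, l, s = rf.semiglobal_align(q, ref)
        assert (m, l) == (400, 400)
        assert s == 800

    def test_internal_gap_counted_in_columns(self):
        rng = np.random.default_rng(21)
        ref = "".join(rng.choice(list("ACGT"), 30))
        q = ref[:12] + ref[15:]  # 3-base deletion
        m, l, _ = rf.semiglobal_align(q, ref)
        assert m == 27 and l == 30

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            rf.semiglobal_align("", "ACGT")

    @pytest.mark.parametrize("seed", range(8))
    def test_score_matches_independent_dp(self, seed):
        """Wrapper score equals a hand-written Gotoh patch-alignment oracle."""
        rng = np.random.default_rng(seed)
        ref = "".join(rng.choice(list("ACGT"), 60))
        # mutated, indel-bearing fragment of the reference
        frag = list(ref[10:45])
        for _ in range(4):
            pos = int(rng.integers(len(frag)))
            op = rng.integers(3)
            if op == 0:
                frag[pos] = str(rng.choice(list("ACGT")))
            elif op == 1 and len(frag) > 5:
                del frag[pos]
            else:
                frag.insert(pos, str(rng.choice(list("ACGT"))))
        q = "".join(frag)
        _, _, score = rf.semiglobal_align(q, ref)
        assert score == dp_semiglobal_score(q, ref)


class TestIndexAndTopHit:
    def test_index_word_count_single_ref(self):
        db = _random_db(np.random.default_rng(2), n_refs=1, length=100)
        index = rf.build_index(db, k=11)
        assert sum(len(v) for v in index.words.values()) == 100 - 10

    def test_no_shared_kmers_no_candidates(self):
        db = _random_db(np.random.default_rng(3), n_refs=2, length=60)
        index = rf.build_index(db, k=11)
        assert index.candidates("T" * 40) == set()

    def test_exact_query_hits_its_reference(self):
        db = _random_db(np.random.default_rng(4), n_refs=2, length=150)
        index = rf.build_index(db, k=11)
        hit = rf.top_hit(db.records[1].seq, index)
        assert hit.ref_id == "r1" and hit.identity == 100.0

    def test_reverse_complement_strand_found(self):
        db = _random_db(np.random.default_rng(5), n_refs=2, length=150)
        index = rf.build_index(db, k=11)
        hit = rf.top_hit(reverse_complement(db.records[0].seq), index)
        assert hit.ref_id == "r0" and hit.identity == 100.0 and hit.strand == "-"

    def test_random_query_is_no_hit(self):
        db = _random_db(np.random.default_rng(6), n_refs=2, length=60)
        index = rf.build_index(db, k=11)
        rng = np.random.default_rng(7)
        assert rf.top_hit("".join(rng.choice(list("ACGT"), 50)), index) is None

    def test_planted_substitutions_match_exhaustive_alignment(self):
        """Top-hit identity equals brute-force alignment over every reference."""
        rng = np.random.default_rng(8)
        db = _random_db(rng, n_refs=12, length=400)
        src = db.records[4].seq
        q = list(src[30:330])
        for pos in rng.choice(len(q), size=5, replace=False):
            q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
        q = "".join(q)
        index = rf.build_index(db, k=11)
        hit = rf.top_hit(q, index)
        brute = []
        for strand_seq in (q, reverse_complement(q)):
            for rec in db.records:
                m, l, s = rf.semiglobal_align(strand_seq, rec.seq)
                brute.append((s, 100.0 * m / l if l else 0.0, rec.id))
        best = max(brute)
        assert hit.score == best[0]
        assert hit.identity == pytest.approx(best[1])

    def test_adding_references_never_lowers_identity(self):
        rng = np.random.default_rng(9)
        db_small = _random_db(rng, n_refs=4, length=200)
        extra = _random_db(rng, n_refs=3, length=200)
        extra_records = [
            rf.SequenceRecord(id=f"x{i}", seq=r.seq)
            for i, r in enumerate(extra.records)
        ]
        db_big = rf.ReferenceDB(
            records=db_small.records + extra_records,
            taxonomy={
                **db_small.taxonomy,
                **{r.id: rf.Taxonomy(("Bacteria",)) for r in extra_records},
            },
        )
        q = db_small.records[0].seq[20:180]
        h1 = rf.top_hit(q, rf.build_index(db_small, k=11))
        h2 = rf.top_hit(q, rf.build_index(db_big, k=11))
        assert h2.identity >= h1.identity


class TestStratify:
    def _hits(self, identities):
        out = []
        for i, ident in enumerate(identities):
            if ident is None:
                out.append((f"q{i}", None))
            else:
                out.append(
                    (f"q{i}", rf.AlignmentHit(
                        query_id=f"q{i}", ref_id="r", matches=int(round(ident * 10)),
                        aln_len=1000, score=1.0,
                    ))
                )
        return out

    def test_one_query_per_stratum(self):
        profile = rf.stratify(self._hits([100.0, 96.0, 89.0, None]))
        assert profile.counts == {
            ">=97%": 1, "[90%,97%)": 1, "<90%": 1, "unaligned": 1
        }
        assert all(f == 0.25 for f in profile.fractions.values())

    def test_all_perfect(self):
        profile = rf.stratify(self._hits([100.0] * 5))
        assert profile.fraction(">=97%") == 1.0

    def test_order_invariant(self):
        idents = [100.0, 96.0, 89.0, None, 98.0, 91.5]
        p1 = rf.stratify(self._hits(idents))
        p2 = rf.stratify(self._hits(idents[::-1]))
        assert p1.counts == p2.counts

    def test_boundary_rounds_to_one_decimal(self):
        # 96.95% rounds to 97.0 and lands in the species stratum
        hit = rf.AlignmentHit(query_id="q", ref_id="r", matches=9695,
                              aln_len=10000, score=1.0)
        profile = rf.stratify([("q", hit)])
        assert profile.counts[">=97%"] == 1

    def test_thresholds_must_descend(self):
        with pytest.raises(ValueError):
            rf.stratify([], thresholds=[90.0, 97.0])


class TestComplementarySelection:
    def test_constructed_gap_selected(self):
        rng = np.random.default_rng(10)
        novel = "".join(rng.choice(list("ACGT"), 300))
        # base holds a 95%-identity relative; candidate holds the novel seq
        relative = list(novel)
        for pos in rng.choice(300, size=15, replace=False):
            relative[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[relative[pos]]
        tax = lambda ids: {i: rf.Taxonomy(("Bacteria",)) for i in ids}
        base = rf.ReferenceDB(
            records=[rf.SequenceRecord(id="rel", seq="".join(relative))],
            taxonomy=tax(["rel"]),
        )
        cand = rf.ReferenceDB(
            records=[rf.SequenceRecord(id="nov", seq=novel)], taxonomy=tax(["nov"])
        )
        reads = [rf.SequenceRecord(id="q1", seq=novel[10:290])]
        selected, support = rf.select_complementary(reads, base, cand)
        assert selected == {"nov"} and support["nov"] == ["q1"]

    def test_good_base_hit_selects_nothing(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 300))
        tax = lambda ids: {i: rf.Taxonomy(("Bacteria",)) for i in ids}
        base = rf.ReferenceDB(
            records=[rf.SequenceRecord(id="b", seq=seq)], taxonomy=tax(["b"])
        )
        cand = rf.ReferenceDB(
            records=[rf.SequenceRecord(id="c", seq=seq)], taxonomy=tax(["c"])
        )
        reads = [rf.SequenceRecord(id="q1", seq=seq[10:290])]
        selected, _ = rf.select_complementary(reads, base, cand)
        assert selected == set()


class TestAugment:
    def _dbs(self):
        rng = np.random.default_rng(12)
        recs = [
            rf.SequenceRecord(id=f"r{i}", seq="".join(rng.choice(list("ACGT"), 200)))
            for i in range(4)
        ]
        tax = {r.id: rf.Taxonomy(("Bacteria",)) for r in recs}
        base = rf.ReferenceDB(records=recs[:2], taxonomy={k: tax[k] for k in ("r0", "r1")})
        cand = rf.ReferenceDB(records=recs[2:], taxonomy={k: tax[k] for k in ("r2", "r3")})
        return base, cand

    def test_empty_selection_is_identity(self):
        base, cand = self._dbs()
        assert rf.augment_db(base, cand, set()).ids == base.ids

    def test_size_additive_without_collisions(self):
        base, cand = self._dbs()
        assert len(rf.augment_db(base, cand, {"r2", "r3"})) == 4

    def test_collision_suffixed(self):
        base, cand = self._dbs()
        cand2 = rf.ReferenceDB(
            records=[rf.SequenceRecord(id="r0", seq=cand.records[0].seq)],
            taxonomy={"r0": rf.Taxonomy(("Bacteria", "Firmicutes"))},
        )
        augmented = rf.augment_db(base, cand2, {"r0"})
        assert "r0+pac" in augmented.ids
        assert augmented.taxonomy["r0+pac"].ranks[1] == "Firmicutes"

    def test_superset_never_lowers_species_fraction(self):
        base, cand = self._dbs()
        augmented = rf.augment_db(base, cand, {"r2", "r3"})
        rng = np.random.default_rng(13)
        queries = [
            rf.SequenceRecord(id=f"q{i}", seq=rec.seq[5:195])
            for i, rec in enumerate(cand.records)
        ] + [rf.SequenceRecord(id="qr", seq="".join(rng.choice(list("ACGT"), 150)))]
        f_base = rf.stratify(rf.search_all(queries, base)).fraction(">=97%")
        f_aug = rf.stratify(rf.search_all(queries, augmented)).fraction(">=97%")
        assert f_aug >= f_base
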