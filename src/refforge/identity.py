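"""Top-hit percent-identity search of short reads against a reference DB.

Short V3-V4 reads (~400-470 bp) are aligned inside full-length 16S
references (~1.5 kb) with an end-gap-free ("semi-global") affine-gap
alignment, so overhang costs nothing.  A k-mer prefilter selects
candidate references, the best alignment per query is kept, and queries
are stratified by percent identity into the bands the 16S literature
treats as species (>=97%), genus (90-97%) and family (<90%) resolution.

The identity-gap augmentation rule picks, from a candidate DB, those ASVs
that rescue queries stuck below the species band in a base DB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import Align

from .formats import ReferenceDB, SequenceRecord

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Scoring:
    """Affine alignment scoring; a gap of length L costs gap_open + L*gap_extend.

    Defaults are megablast-like: match +2, mismatch -3, gap open -5,
    gap extend -2.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class AlignmentHit:
    """Top-hit statistics for one query: matches, columns, identity, score.

    ``aln_len`` counts every alignment column (including internal gaps)
    between the first and last aligned pair; ``identity`` is
    100 * matches / aln_len, the common BLAST pident convention.
    """

    query_id: str
    ref_id: str
    matches: int
    aln_len: int
    score: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.matches <= self.aln_len and self.aln_len > 0:
            raise ValueError("matches must lie in [0, aln_len]")

    @property
    def identity(self) -> float:
        if self.aln_len == 0:
            return 0.0
        return 100.0 * self.matches / self.aln_len


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # PairwiseAligner charges open_gap_score for the first gap column and
    # extend_gap_score for each further one; shift so length-L gaps cost
    # gap_open + L * gap_extend.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


_ALIGNER_CACHE: dict[Scoring, Align.PairwiseAligner] = {}


def _aligner_for(scoring: Scoring) -> Align.PairwiseAligner:
    if scoring not in _ALIGNER_CACHE:
        _ALIGNER_CACHE[scoring] = _make_aligner(scoring)
    return _ALIGNER_CACHE[scoring]


def semiglobal_align(
    query: str, ref: str, scoring: Scoring = Scoring()
) -> tuple[int, int, float]:
    """Optimal end-gap-free affine alignment of query inside/against ref.

    Returns ``(matches, aln_len, score)``.  End gaps on either sequence
    are free, so a short read aligns within a full-length reference
    without penalty.
    """
    if not query or not ref:
        raise ValueError("sequences must be nonempty")
    aligner = _aligner_for(scoring)
    aln = aligner.align(ref.upper(), query.upper())[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return 0, 0, float(aln.score)
    matches = 0
    diag = 0
    tseq, qseq = str(aln.target), str(aln.query)
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        diag += te - ts
        matches += sum(
            1 for a, b in zip(tseq[ts:te], qseq[qs:qe]) if a == b
        )
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    aln_len = t_span + q_span - diag
    return matches, aln_len, float(aln.score)


@dataclass
class SearchIndex:
    """k-mer word index over a reference DB, the seed prefilter for search."""

    db: ReferenceDB
    k: int = 11
    min_seed_count: int = 1
    words: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not 8 <= self.k <= 15:
            raise ValueError(f"word size {self.k} outside [8, 15]")
        if len(self.db) == 0:
            raise ValueError("cannot index an empty reference DB")
        for rec in self.db.records:
            for word in _kmers(rec.seq, self.k):
                self.words.setdefault(word, set()).add(rec.id)

    def candidates(self, query: str) -> set[str]:
        """Reference ids sharing >= min_seed_count words with the query."""
        counts: dict[str, int] = {}
        for word in set(_kmers(query.upper(), self.k)):
            for rid in self.words.get(word, ()):
                counts[rid] = counts.get(rid, 0) + 1
        return {rid for rid, c in counts.items() if c >= self.min_seed_count}


def _kmers(seq: str, k: int):
    """Yield ACGT-only k-mers; words containing ambiguity codes are skipped."""
    ok = set("ACGT")
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if set(word) <= ok:
            yield word


def build_index(db: ReferenceDB, k: int = 11, min_seed_count: int = 1) -> SearchIndex:
    return SearchIndex(db=db, k=k, min_seed_count=min_seed_count)


def top_hit(
    query: SequenceRecord | str,
    index: SearchIndex,
    scoring: Scoring = Scoring(),
    identity_floor: float = 75.0,
) -> AlignmentHit | None:
    """Best-scoring hit of a query against the index, or None.

    Both the query and its reverse complement are searched; the better
    alignment wins.  Ties break by higher identity, then lexicographically
    smaller reference id.  Hits below ``identity_floor`` percent identity
    are reported as no-hit.
    """
    if isinstance(query, SequenceRecord):
        qid, qseq = query.id, query.seq
    else:
        qid, qseq = "query", query.upper()
    best: AlignmentHit | None = None
    for strand, seq in (("+", qseq), ("-", reverse_complement(qseq))):
        for rid in sorted(index.candidates(seq)):
            ref = index.db.record(rid)
            matches, aln_len, score = semiglobal_align(seq, ref.seq, scoring)
            hit = AlignmentHit(
                query_id=qid, ref_id=rid, matches=matches,
                aln_len=aln_len, score=score, strand=strand,
            )
            if _better(hit, best):
                best = hit
    if best is None or best.identity < identity_floor:
        return None
    return best


def _better(a: AlignmentHit, b: AlignmentHit | None) -> bool:
    if b is None:
        return True
    if a.score != b.score:
        return a.score > b.score
    if a.identity != b.identity:
        return a.identity > b.identity
    return a.ref_id < b.ref_id


@dataclass
class IdentityProfile:
    """Per-stratum query counts: >=97%, [90,97), <90, unaligned."""

    n_queries: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_queries:
            raise ValueError("stratum counts must sum to n_queries")

    @property
    def fractions(self) -> dict[str, float]:
        if self.n_queries == 0:
            return {k: 0.0 for k in self.counts}
        return {k: v / self.n_queries for k, v in self.counts.items()}

    def fraction(self, stratum: str) -> float:
        return self.fractions[stratum]


def stratum_labels(thresholds: list[float]) -> list[str]:
    labels = [f">={thresholds[0]:g}%"]
    for hi, lo in zip(thresholds, thresholds[1:]):
        labels.append(f"[{lo:g}%,{hi:g}%)")
    labels.append(f"<{thresholds[-1]:g}%")
    labels.append("unaligned")
    return labels


def stratify(
    hits: list[tuple[str, AlignmentHit | None]],
    thresholds: list[float] = (97.0, 90.0),
) -> IdentityProfile:
    """Assign each query to exactly one identity stratum.

    Identities are rounded to one decimal before comparison, so the
    species band ">=97%" admits a read at 96.95+.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be strictly descending")
    labels = stratum_labels(thresholds)
    counts = {lab: 0 for lab in labels}
    for _, hit in hits:
        if hit is None:
            counts["unaligned"] += 1
            continue
        ident = round(hit.identity, 1)
        for t, lab in zip(thresholds, labels):
            if ident >= t:
                counts[lab] += 1
                break
        else:
            counts[labels[len(thresholds)]] += 1
    return IdentityProfile(n_queries=len(hits), counts=counts)


def search_all(
    queries: list[SequenceRecord],
    db: ReferenceDB,
    scoring: Scoring = Scoring(),
    k: int = 11,
    min_seed_count: int = 1,
    identity_floor: float = 75.0,
) -> list[tuple[str, AlignmentHit | None]]:
    """Top-hit search of every query against the DB (index built once)."""
    index = build_index(db, k=k, min_seed_count=min_seed_count)
    return [
        (q.id, top_hit(q, index, scoring, identity_floor)) for q in queries
    ]


def select_complementary(
    queries: list[SequenceRecord],
    base_db: ReferenceDB,
    candidate_db: ReferenceDB,
    high: float = 97.0,
    scoring: Scoring = Scoring(),
    k: int = 11,
) -> tuple[set[str], dict[str, list[str]]]:
    """Candidate ASVs that rescue queries the base DB resolves poorly.

    A query supports a candidate ASV when its top hit against the
    candidate DB reaches >= ``high`` percent identity while its top hit
    against the base DB stays below ``high`` (or is absent).  Returns the
    deduplicated set of candidate ASV ids and a map
    candidate id -> supporting query ids.
    """
    base_hits = dict(search_all(queries, base_db, scoring, k))
    cand_hits = dict(search_all(queries, candidate_db, scoring, k))
    selected: dict[str, list[str]] = {}
    for q in queries:
        ch = cand_hits.get(q.id)
        if ch is None or round(ch.identity, 1) < high:
            continue
        bh = base_hits.get(q.id)
        if bh is not None and round(bh.identity, 1) >= high:
            continue
        selected.setdefault(ch.ref_id, []).append(q.id)
    return set(selected), selected


def augment_db(
    base_db: ReferenceDB, candidate_db: ReferenceDB, selected_ids
) -> ReferenceDB:
    """Union of the base DB with selected candidate ASVs.

    Taxonomy is carried from the candidate DB; an id colliding with the
    base DB is suffixed ``+pac``.
    """
    cand_ids = set(candidate_db.ids)
    missing = set(selected_ids) - cand_ids
    if missing:
        raise ValueError(f"selected ids not in candidate DB: {sorted(missing)[:5]}")
    records = list(base_db.records)
    taxonomy = dict(base_db.taxonomy)
    base_ids = set(base_db.ids)
    for rid in sorted(selected_ids):
        rec = candidate_db.record(rid)
        if rid not in candidate_db.taxonomy:
            raise ValueError(f"selected id {rid!r} has no taxonomy")
        new_id = rid + "+pac" if rid in base_ids else rid
        records.append(
            SequenceRecord(
                id=new_id, seq=rec.seq, prevalence=rec.prevalence,
                description=rec.description,
            )
        )
        taxonomy[new_id] = candidate_db.taxonomy[rid]
    return ReferenceDB(records=records, taxonomy=taxonomy)
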