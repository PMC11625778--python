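"""k-mer naive Bayes taxonomic classification with bootstrap confidence.

The classifier follows the RDP contract: each reference contributes the
set of 8-mers found in it (and its reverse complement); a word's prior is
P(w) = (n(w) + 0.5) / (N + 1) over N references, and the per-reference
conditional is P(w|ref) = (m(w) + P(w)) / (M + 1) with m(w) in {0, 1} and
M = 1.  A query is scored by the sum of log conditionals over its words;
each of 100 bootstraps rescores a with-replacement sample of 1/8 of the
words and votes for the best reference's lineage.  Per-rank confidence is
the fraction of votes agreeing with the full-word winner's lineage at
that rank, and the reported lineage is truncated at the deepest rank with
confidence >= 0.8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .formats import RANKS, AsvTable, ReferenceDB, SequenceRecord, Taxonomy
from .identity import reverse_complement

_ENC = {c: i for i, c in enumerate("ACGT")}


def _word_set(seq: str, k: int) -> set[int]:
    """Distinct 2-bit-encoded k-mers; words with ambiguity codes skipped."""
    out: set[int] = set()
    for s in (seq, reverse_complement(seq)):
        code = 0
        run = 0
        for ch in s:
            v = _ENC.get(ch)
            if v is None:
                run = 0
                code = 0
                continue
            code = ((code << 2) | v) & ((1 << (2 * k)) - 1)
            run += 1
            if run >= k:
                out.add(code)
    return out


def _query_words(seq: str, k: int) -> list[int]:
    """Encoded k-mers of the query in order (forward strand only)."""
    out: list[int] = []
    code = 0
    run = 0
    for ch in seq:
        v = _ENC.get(ch)
        if v is None:
            run = 0
            code = 0
            continue
        code = ((code << 2) | v) & ((1 << (2 * k)) - 1)
        run += 1
        if run >= k:
            out.append(code)
    return out


@dataclass
class ClassifierModel:
    """Trained word-presence naive Bayes model over a reference DB."""

    k: int
    ref_ids: list[str]
    word_sets: list[set[int]]
    taxonomy: dict[str, Taxonomy]
    version: int = 1
    _word_refs: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def n_refs(self) -> int:
        return len(self.ref_ids)

    def __post_init__(self) -> None:
        if not self._word_refs:
            index: dict[int, list[int]] = {}
            for i, words in enumerate(self.word_sets):
                for w in words:
                    index.setdefault(w, []).append(i)
            self._word_refs = {
                w: np.array(refs, dtype=np.int64) for w, refs in index.items()
            }

    def word_prior(self, word: int) -> float:
        n_w = len(self._word_refs.get(word, ()))
        return (n_w + 0.5) / (self.n_refs + 1)

    def log_conditionals(self, words: list[int]) -> np.ndarray:
        """Matrix L[ref, j] = log P(words[j] | ref)."""
        n, w = self.n_refs, len(words)
        presence = np.zeros((n, w))
        priors = np.empty(w)
        for j, word in enumerate(words):
            refs = self._word_refs.get(word)
            if refs is not None:
                presence[refs, j] = 1.0
            priors[j] = self.word_prior(word)
        return np.log((presence + priors[None, :]) / 2.0)

    def save(self, path) -> None:
        payload = {
            "format": "refforge-nb-classifier",
            "version": self.version,
            "k": self.k,
            "refs": [
                {
                    "id": rid,
                    "lineage": self.taxonomy[rid].to_string(prefixed=True),
                    "words": sorted(words),
                }
                for rid, words in zip(self.ref_ids, self.word_sets)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "refforge-nb-classifier":
            raise ValueError(f"{path}: not a refforge classifier model")
        return cls(
            k=payload["k"],
            ref_ids=[r["id"] for r in payload["refs"]],
            word_sets=[set(r["words"]) for r in payload["refs"]],
            taxonomy={
                r["id"]: Taxonomy.from_string(r["lineage"]) for r in payload["refs"]
            },
            version=payload["version"],
        )


@dataclass
class Assignment:
    """One read's lineage call with per-rank bootstrap confidence."""

    query_id: str
    lineage: Taxonomy
    confidence: tuple[float, ...]
    best_ref: str = ""

    def confident_depth(self, cutoff: float = 0.8) -> int:
        depth = 0
        for c, label in zip(self.confidence, self.lineage.ranks):
            if c >= cutoff and label:
                depth += 1
            else:
                break
        return depth


def train(db: ReferenceDB, k: int = 8) -> ClassifierModel:
    """Build word-presence sets (forward + reverse complement) and priors."""
    if len(db) == 0:
        raise ValueError("cannot train on an empty DB")
    word_sets = []
    for rec in db.records:
        if len(rec.seq) < k:
            raise ValueError(f"reference {rec.id!r} shorter than word size {k}")
        words = _word_set(rec.seq, k)
        if not words:
            raise ValueError(f"reference {rec.id!r} has no unambiguous {k}-mers")
        word_sets.append(words)
    return ClassifierModel(
        k=k, ref_ids=db.ids, word_sets=word_sets, taxonomy=dict(db.taxonomy)
    )


def classify(
    query: SequenceRecord | str,
    model: ClassifierModel,
    bootstraps: int = 100,
    confidence_cutoff: float = 0.8,
    seed: int | None = None,
) -> Assignment:
    """Assign a lineage with bootstrap confidence; truncate below cutoff."""
    if isinstance(query, SequenceRecord):
        qid, seq = query.id, query.seq
    else:
        qid, seq = "query", query.upper()
    words = _query_words(seq, model.k)
    if not words:
        raise ValueError(f"query {qid!r} yields no {model.k}-mers")
    rng = np.random.default_rng(seed)
    L = model.log_conditionals(words)
    # point estimate from all words
    full_scores = L.sum(axis=1)
    best = int(np.argmax(full_scores))
    best_lineage = model.taxonomy[model.ref_ids[best]]

    n_sub = max(1, len(words) // 8)
    idx = rng.integers(0, len(words), size=(bootstraps, n_sub))
    agree = np.zeros(len(RANKS))
    for b in range(bootstraps):
        scores = L[:, idx[b]].sum(axis=1)
        vote = model.taxonomy[model.ref_ids[int(np.argmax(scores))]]
        for r in range(len(RANKS)):
            if vote.ranks[r] == best_lineage.ranks[r]:
                agree[r] += 1
            else:
                break
    confidence = tuple(agree / bootstraps)
    assignment = Assignment(
        query_id=qid,
        lineage=best_lineage,
        confidence=confidence,
        best_ref=model.ref_ids[best],
    )
    depth = assignment.confident_depth(confidence_cutoff)
    return Assignment(
        query_id=qid,
        lineage=best_lineage.truncate(depth),
        confidence=confidence,
        best_ref=model.ref_ids[best],
    )


def assign_table(
    reads_per_sample: dict[str, list[SequenceRecord]],
    model: ClassifierModel,
    bootstraps: int = 100,
    confidence_cutoff: float = 0.8,
    seed: int | None = None,
) -> tuple[dict[str, AsvTable], dict[str, Assignment]]:
    """Classify all reads and collapse to per-rank relative-abundance tables.

    At rank r a read whose lineage was truncated above r falls into an
    ``<deepest assigned label>;unassigned`` bin, so per-sample abundances
    still sum to 1 at every rank.
    """
    rng = np.random.default_rng(seed)
    assignments: dict[str, Assignment] = {}
    labels_per_rank: list[dict[str, dict[str, int]]] = [
        {} for _ in RANKS
    ]  # rank -> sample -> label -> count
    for sample, reads in reads_per_sample.items():
        for read in reads:
            a = classify(
                read, model, bootstraps, confidence_cutoff,
                seed=int(rng.integers(2**31)),
            )
            assignments[read.id] = a
            depth = a.lineage.depth
            for r in range(len(RANKS)):
                if r < depth:
                    label = ";".join(a.lineage.ranks[: r + 1])
                else:
                    assigned = ";".join(a.lineage.ranks[:depth])
                    label = f"{assigned};unassigned" if assigned else "unassigned"
                bucket = labels_per_rank[r].setdefault(sample, {})
                bucket[label] = bucket.get(label, 0) + 1
    samples = list(reads_per_sample)
    tables: dict[str, AsvTable] = {}
    for r, rank in enumerate(RANKS):
        labels = sorted({l for s in labels_per_rank[r].values() for l in s})
        counts = np.array(
            [[labels_per_rank[r].get(s, {}).get(l, 0) for l in labels] for s in samples]
        )
        tables[rank] = AsvTable(sample_ids=samples, asv_ids=labels, counts=counts)
    return tables, assignments


def assigned_fraction(table: AsvTable) -> float:
    """Fraction of reads carrying a real label (not an unassigned bin)."""
    import numpy as np

    mask = np.array(
        [not l.endswith("unassigned") for l in table.asv_ids], dtype=bool
    )
    total = table.counts.sum()
    if total == 0:
        return 0.0
    return float(table.counts[:, mask].sum() / total)
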