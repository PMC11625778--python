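"""On-disk formats and shared domain types.

Sequences travel as FASTA, lineages as two-column TSV (id TAB
semicolon-joined ranks, with or without ``k__``-style prefixes), trees as
newick.  Parsing is delegated to Biopython / scikit-bio; this module adds
the domain types and the validation the rest of the package relies on
(unique ids, the taxonomy prefix property, labelled tips).

All coordinates used anywhere in the package are 0-based, half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: canonical rank names, coarse to fine
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("k__", "d__", "p__", "c__", "o__", "f__", "g__", "s__")
_WRITE_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")


class FormatError(ValueError):
    """A file violated its declared format; message carries the location."""


@dataclass
class SequenceRecord:
    """One identified DNA sequence, optionally with a sample-prevalence count.

    ``prevalence`` is the number of samples the sequence was observed in
    (0 when unknown); pooled reference candidates carry it into tree
    trimming, where it decides which near-duplicate survives.
    """

    id: str
    seq: str
    prevalence: int = 0
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        if self.prevalence < 0:
            raise ValueError("prevalence must be non-negative")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Taxonomy:
    """An ordered lineage of up to 7 ranks, possibly empty-suffixed.

    The prefix property holds: once a rank is unassigned (empty string),
    every deeper rank is unassigned too.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        ranks = tuple(self.ranks)
        if len(ranks) > len(RANKS):
            raise ValueError(f"at most {len(RANKS)} ranks, got {len(ranks)}")
        # pad to 7 so downstream rank indexing is uniform
        ranks = ranks + ("",) * (len(RANKS) - len(ranks))
        seen_empty = False
        for label in ranks:
            if label == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"empty rank precedes nonempty rank in lineage {ranks}"
                )
        object.__setattr__(self, "ranks", ranks)

    @property
    def depth(self) -> int:
        """Number of assigned (nonempty) ranks."""
        return sum(1 for r in self.ranks if r)

    def truncate(self, depth: int) -> "Taxonomy":
        return Taxonomy(self.ranks[:depth])

    def to_string(self, prefixed: bool = True) -> str:
        if prefixed:
            return ";".join(p + r for p, r in zip(_WRITE_PREFIXES, self.ranks))
        return ";".join(self.ranks)

    @classmethod
    def from_string(cls, lineage: str) -> "Taxonomy":
        labels = []
        for part in lineage.split(";")[: len(RANKS)]:
            part = part.strip()
            for pre in _RANK_PREFIXES:
                if part.lower().startswith(pre):
                    part = part[len(pre):]
                    break
            labels.append(part.strip())
        return cls(tuple(labels))


@dataclass
class ReferenceDB:
    """A reference database: sequence records plus a lineage per record."""

    records: list[SequenceRecord]
    taxonomy: dict[str, Taxonomy]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in reference DB: {dupes}")
        missing = [i for i in ids if i not in self.taxonomy]
        if missing:
            raise ValueError(f"records without taxonomy: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, rid: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rid:
                return r
        raise KeyError(rid)


@dataclass
class AsvTable:
    """Per-sample feature counts: samples x features, non-negative integers."""

    sample_ids: list[str]
    asv_ids: list[str]
    counts: "object" = field(default=None)  # numpy (n_samples, n_asvs)

    def __post_init__(self) -> None:
        import numpy as np

        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sample_ids), len(self.asv_ids)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.asv_ids)} features"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def relative(self):
        import numpy as np

        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA into SequenceRecords (uppercased; empty file -> [])."""
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                first = (lineno, line)
                break
        if first is not None and not first[1].startswith(">"):
            raise FormatError(
                f"{path}: line {first[0]}: expected FASTA header starting "
                f"with '>', got {first[1].strip()[:30]!r}"
            )
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), description=desc))
    return records


def write_fasta(records, path) -> None:
    """Write records as 60-column wrapped FASTA."""
    bio = [
        _BioRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta")


# ---------------------------------------------------------------------------
# Taxonomy TSV


def read_taxonomy(path) -> dict[str, Taxonomy]:
    """Read a two-column TSV of id TAB semicolon-joined lineage."""
    out: dict[str, Taxonomy] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in ("id", "feature id", "#otu id"):
                continue
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rid, lineage = parts[0].strip(), parts[1]
            if rid in out:
                raise FormatError(f"{path}: line {lineno}: duplicate id {rid!r}")
            try:
                out[rid] = Taxonomy.from_string(lineage)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_taxonomy(taxonomy: dict[str, Taxonomy], path) -> None:
    """Write the prefixed 7-rank dialect."""
    with open(path, "w") as fh:
        for rid, tax in taxonomy.items():
            fh.write(f"{rid}\t{tax.to_string(prefixed=True)}\n")


# ---------------------------------------------------------------------------
# Newick


def read_newick(path) -> TreeNode:
    """Read a newick tree; tips must be labelled, missing lengths become 0."""
    tree = TreeNode.read(str(path), format="newick")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.is_tip() and not node.name:
            raise FormatError(f"{path}: unlabeled tip in newick tree")
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    tree.length = tree.length or 0.0
    if n_missing:
        msg = f"{path}: {n_missing} branch length(s) missing, treated as 0"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise FormatError(f"{path}: duplicate tip labels in newick tree")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
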