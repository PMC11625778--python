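"""Distance-based trees over ASVs and pendant-branch trimming.

A redundant pooled reference carries many near-duplicate ASVs.  Building
a branch-length tree over them and iteratively collapsing "cherries"
(sister tip pairs) whose pendant edges are both shorter than a threshold
keeps one representative per near-duplicate group while leaving distinct
taxa untouched — shrinking the DB with little loss of search identity.

Distances are Jukes-Cantor corrected pairwise-alignment mismatch
fractions; the tree comes from neighbor joining (scikit-bio), or any
external newick tree with matching tip labels may be supplied instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .formats import ReferenceDB, SequenceRecord
from .identity import Scoring, semiglobal_align

logger = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Observed mismatch fraction at/beyond the Jukes-Cantor domain edge."""


def p_distance(a: str, b: str, scoring: Scoring = Scoring()) -> float:
    """Mismatch fraction over pairwise-aligned non-gap columns."""
    matches, _aln_len, _score = semiglobal_align(a, b, scoring)
    # aligned (non-gap) columns = matched + mismatched pairs; recompute the
    # diagonal span from a second pass is unnecessary: semiglobal_align's
    # aln_len includes internal gap columns, so derive the pair count here.
    pairs = _aligned_pairs(a, b, scoring)
    if pairs == 0:
        raise ValueError("sequences share no aligned columns")
    return (pairs - matches) / pairs


def _aligned_pairs(a: str, b: str, scoring: Scoring) -> int:
    from .identity import _aligner_for

    aln = _aligner_for(scoring).align(b.upper(), a.upper())[0]
    t_blocks, _ = aln.aligned
    return int(sum(te - ts for ts, te in t_blocks))


def jc69_distance(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3); saturates at p=0.75."""
    if p < 0:
        raise ValueError("mismatch fraction must be >= 0")
    if p >= 0.75:
        raise SaturationError(
            f"mismatch fraction {p:.3f} >= 0.75: distance saturated under JC69"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_distance(a: str, b: str, scoring: Scoring = Scoring()) -> float:
    """JC69 distance between two alignable sequences."""
    return jc69_distance(p_distance(a, b, scoring))


def distance_matrix(
    records: list[SequenceRecord], scoring: Scoring = Scoring()
) -> tuple[list[str], np.ndarray]:
    """All-pairs JC69 distance matrix over records."""
    n = len(records)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(records[i].seq, records[j].seq, scoring)
            dm[i, j] = dm[j, i] = d
    return [r.id for r in records], dm


def nj_tree(ids: list[str], dm: np.ndarray) -> TreeNode:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    Negative branch lengths produced by NJ on non-additive matrices are
    clamped to zero (the clamped deficit is logged).
    """
    dm = np.asarray(dm, dtype=float)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa")
    if dm.shape != (len(ids), len(ids)):
        raise ValueError("matrix shape does not match id list")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
        raise ValueError("matrix must be symmetric with zero diagonal")
    if len(ids) == 2:
        tree = TreeNode.read([f"({ids[0]}:{dm[0, 1] / 2},{ids[1]}:{dm[0, 1] / 2});"])
        return tree
    skdm = DistanceMatrix(dm, ids)
    tree = _skbio_nj(skdm)
    deficit = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            deficit += -node.length
            node.length = 0.0
        elif node.length is None:
            node.length = 0.0
    if deficit > 0:
        logger.info("clamped negative NJ branch lengths (total deficit %.3g)", deficit)
    return tree


@dataclass
class TrimResult:
    """Outcome of pendant-branch trimming at one threshold."""

    threshold: float
    retained_ids: list[str]
    dropped_ids: list[str]
    representative_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.representative_map) != set(self.dropped_ids):
            raise ValueError("representative_map keys must equal dropped_ids")
        bad = set(self.representative_map.values()) - set(self.retained_ids)
        if bad:
            raise ValueError(f"representatives not retained: {sorted(bad)[:5]}")

    def to_frame(self):
        import pandas as pd

        rows = [{"id": i, "status": "retained", "representative": i}
                for i in self.retained_ids]
        rows += [{"id": i, "status": "dropped",
                  "representative": self.representative_map[i]}
                 for i in self.dropped_ids]
        return pd.DataFrame(rows)


def _cherries(tree: TreeNode, threshold: float):
    """Yield (node, tip_a, tip_b): sister-tip pairs both below threshold.

    Polytomies (e.g. the unrooted trifurcation of an NJ tree) qualify
    through their two shortest-pendant tip children.
    """
    for node in tree.non_tips(include_self=True):
        tips = [c for c in node.children
                if c.is_tip() and (c.length or 0.0) < threshold]
        if len(tips) >= 2:
            tips.sort(key=lambda c: ((c.length or 0.0), c.name))
            yield node, tips[0], tips[1]


def _suppress_degree_two_root(work: TreeNode) -> TreeNode:
    """Re-root a degree-2 root onto its internal child.

    The tree is conceptually unrooted; a rooted representation whose
    root has two children hides sister-tip relations (the two root edges
    are really one edge), so merge them before looking for cherries.
    """
    while len(work.children) == 2:
        internal = [c for c in work.children if not c.is_tip()]
        if not internal:
            break
        new_root = internal[0]
        other = next(c for c in work.children if c is not new_root)
        work.remove(new_root)
        work.remove(other)
        other.length = (other.length or 0.0) + (new_root.length or 0.0)
        new_root.append(other)
        new_root.parent = None
        new_root.length = None
        work = new_root
    return work


def trim_tree(
    tree: TreeNode,
    threshold: float,
    prevalence: dict[str, int] | None = None,
    seq_length: dict[str, int] | None = None,
) -> TrimResult:
    """Iteratively collapse sub-threshold cherries, keeping one representative.

    At each step the cherry whose two pendant edges are both shorter than
    ``threshold`` and whose pendant-length sum is smallest is collapsed:
    the tip with lower prevalence is dropped (ties: the shorter sequence,
    then the lexicographically larger id).  The survivor absorbs the
    parent edge, so a clade always keeps at least one representative;
    singleton sub-threshold tips not in a qualifying cherry are retained.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    prevalence = prevalence or {}
    seq_length = seq_length or {}
    work = tree.copy()
    all_tips = [t.name for t in work.tips()]
    dropped: dict[str, str] = {}

    def survives(x: str, y: str) -> bool:
        """True if tip x is the preferred survivor over tip y."""
        px, py = prevalence.get(x, 0), prevalence.get(y, 0)
        if px != py:
            return px > py
        lx, ly = seq_length.get(x, 0), seq_length.get(y, 0)
        if lx != ly:
            return lx > ly
        return x < y  # lexicographically larger id dropped

    while True:
        work = _suppress_degree_two_root(work)
        best = None
        for node, a, b in _cherries(work, threshold):
            key = ((a.length or 0.0) + (b.length or 0.0), min(a.name, b.name))
            if best is None or key < best[0]:
                best = (key, node, a, b)
        if best is None:
            break
        _, node, a, b = best
        survivor, loser = (a, b) if survives(a.name, b.name) else (b, a)
        dropped[loser.name] = survivor.name
        node.remove(loser)
        if len(node.children) > 1:
            continue
        # node became unary: its remaining child absorbs the parent edge
        only = node.children[0]
        only.length = (only.length or 0.0) + (node.length or 0.0)
        parent = node.parent
        node.remove(only)
        if parent is None:
            work = only
            only.parent = None
            if only.is_tip():
                break
        else:
            parent.remove(node)
            parent.append(only)

    # resolve chains dropped -> ... -> retained
    def resolve(name: str) -> str:
        while name in dropped:
            name = dropped[name]
        return name

    retained = [t.name for t in ([work] if work.is_tip() else work.tips())]
    retained_set = set(retained)
    rep_map = {d: resolve(d) for d in dropped}
    dropped_ids = [t for t in all_tips if t not in retained_set]
    return TrimResult(
        threshold=threshold,
        retained_ids=retained,
        dropped_ids=dropped_ids,
        representative_map=rep_map,
    )


def subset_db(db: ReferenceDB, retained_ids) -> ReferenceDB:
    """Restrict a DB to the retained ids (taxonomy carried over)."""
    retained = set(retained_ids)
    unknown = retained - set(db.ids)
    if unknown:
        raise ValueError(f"unknown ids: {sorted(unknown)[:5]}")
    if not retained:
        raise ValueError("refusing to build an empty reference DB")
    records = [r for r in db.records if r.id in retained]
    taxonomy = {r.id: db.taxonomy[r.id] for r in records}
    return ReferenceDB(records=records, taxonomy=taxonomy)
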