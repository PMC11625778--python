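"""Ground-truthed synthetic 16S communities.

Emulates the structure of a pooled full-length amplicon study: an
ultrametric taxon tree, ~1.5 kb sequences evolved along it under a
Jukes-Cantor substitution model with conserved blocks (primer landing
sites and four further constant regions, mimicking the alternation of
conserved and variable regions in the 16S gene), a 7-rank taxonomy read
off the tree at fixed depths, per-sample lognormal abundance vectors,
and matched full-length / V3-V4 short reads with known source taxa.

Everything is driven by explicit seeds; truth tables (read -> taxon,
duplicate -> parent) let downstream modules be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .formats import RANKS, ReferenceDB, SequenceRecord, Taxonomy

#: default primer landing windows on the reference coordinate system
#: (0-based half-open); the V3-V4 amplicon spans fw[0]..rv[1].
PRIMER_WINDOWS = ((340, 360), (780, 805))
#: additional conserved blocks outside the amplicon
CONSERVED_BLOCKS = ((0, 30), (950, 990), (1180, 1210), (1450, 1480))

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def jc_p(d: float) -> float:
    """Expected mismatch fraction after evolving distance d under JC69."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def _mutate(arr: np.ndarray, p: float, rng, allowed: np.ndarray | None = None) -> np.ndarray:
    """JC-substitute each (allowed) site with probability p."""
    hit = rng.random(arr.size) < p
    if allowed is not None:
        hit &= allowed
    out = arr.copy()
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = (out[hit] + shifts) % 4
    return out


def simulate_tree(
    n_taxa: int,
    birth_death_params: dict | None = None,
    seed: int | None = None,
) -> TreeNode:
    """Random ultrametric taxon tree (Yule splitting process).

    Branch lengths are in substitutions/site; the root-to-tip depth is
    rescaled to ``birth_death_params['depth']`` (default 0.15, a
    within-domain 16S divergence scale).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    params = {"rate": 1.0, "depth": 0.15}
    params.update(birth_death_params or {})
    rate, depth = float(params["rate"]), float(params["depth"])
    rng = np.random.default_rng(seed)

    root = TreeNode(length=None)
    open_tips: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode(length=None)
        root.append(child)
        open_tips.append((child, 0.0))
    t = 0.0
    while len(open_tips) < n_taxa:
        t += rng.exponential(1.0 / (rate * len(open_tips)))
        i = int(rng.integers(len(open_tips)))
        node, birth = open_tips.pop(i)
        node.length = t - birth
        for _ in range(2):
            child = TreeNode(length=None)
            node.append(child)
            open_tips.append((child, t))
    t_final = t + rng.exponential(1.0 / (rate * n_taxa))
    width = len(str(n_taxa))
    for j, (node, birth) in enumerate(open_tips):
        node.length = t_final - birth
        node.name = f"t{j + 1:0{width}d}"
    scale = depth / t_final
    for node in root.traverse(include_self=False):
        node.length *= scale
    root.length = None
    return root


def taxonomy_from_tree(
    tree: TreeNode, cut_depths: list[float] | None = None
) -> dict[str, Taxonomy]:
    """Derive a nested 7-rank taxonomy by cutting the tree at fixed depths.

    The deepest cut from the tips (closest to the root) defines phyla,
    the shallowest defines species; the domain is constant.  This is a
    modeling stand-in for real taxonomy: labels carry no biological
    meaning beyond the nesting.
    """
    depths: dict[int, float] = {}
    for node in tree.preorder(include_self=True):
        parent_d = depths.get(id(node.parent), 0.0) if node.parent is not None else 0.0
        depths[id(node)] = parent_d + (node.length or 0.0)
    tip_depth = max(depths[id(t)] for t in tree.tips())
    if cut_depths is None:
        cut_depths = [
            0.25 * tip_depth, 0.40 * tip_depth, 0.55 * tip_depth,
            0.70 * tip_depth, tip_depth - 0.03, tip_depth - 0.012,
        ]
        cut_depths = sorted(max(c, 1e-9) for c in cut_depths)
    if len(cut_depths) != 6:
        raise ValueError("need 6 cut depths (phylum..species)")

    short = ("Phy", "Cla", "Ord", "Fam", "Gen", "Sp")
    cluster_labels: list[dict[int, str]] = [dict() for _ in cut_depths]
    out: dict[str, Taxonomy] = {}
    for tip in tree.tips():
        path = list(tip.ancestors())[::-1][1:] + [tip]  # root's child .. tip
        labels = ["Bacteria"]
        for ci, cut in enumerate(cut_depths):
            crossing = next(
                (n for n in path if depths[id(n)] >= cut), tip
            )
            key = id(crossing)
            if key not in cluster_labels[ci]:
                cluster_labels[ci][key] = (
                    f"{short[ci]}{len(cluster_labels[ci]) + 1:02d}"
                )
            labels.append(cluster_labels[ci][key])
        out[tip.name] = Taxonomy(tuple(labels))
    return out


def evolve_sequences(
    tree: TreeNode,
    root_length: int = 1500,
    seed: int | None = None,
    primer_windows=PRIMER_WINDOWS,
    conserved_blocks=CONSERVED_BLOCKS,
) -> tuple[dict[str, str], dict[str, Taxonomy]]:
    """Evolve taxon sequences along the tree under JC69.

    Sites inside primer windows and conserved blocks never substitute,
    so primer landing sites are identical across taxa and every taxon's
    V3-V4 excision has the same coordinates.  Returns (sequences,
    taxonomy-by-tree-depth).
    """
    rng = np.random.default_rng(seed)
    allowed = np.ones(root_length, dtype=bool)
    for s, e in tuple(primer_windows) + tuple(conserved_blocks):
        allowed[s:e] = False
    root_seq = rng.integers(0, 4, size=root_length).astype(np.uint8)

    seqs: dict[str, str] = {}

    def descend(node: TreeNode, arr: np.ndarray) -> None:
        for child in node.children:
            child_arr = _mutate(arr, jc_p(child.length or 0.0), rng, allowed)
            if child.is_tip():
                seqs[child.name] = _decode(child_arr)
            else:
                descend(child, child_arr)

    descend(tree, root_seq)
    return seqs, taxonomy_from_tree(tree)


@dataclass
class SyntheticWorld:
    """A complete simulated study: tree, sequences, taxonomy, abundances."""

    tree: TreeNode
    sequences: dict[str, str]
    taxonomy: dict[str, Taxonomy]
    abundances: dict[str, dict[str, float]]  # sample -> taxon -> rel. abundance
    primer_windows: tuple = PRIMER_WINDOWS
    conserved_blocks: tuple = CONSERVED_BLOCKS
    seed: int | None = None

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def amplicon(self) -> tuple[int, int]:
        """V3-V4 amplicon span (primer-to-primer, inclusive of primers)."""
        return (self.primer_windows[0][0], self.primer_windows[1][1])

    def v3v4(self, taxon: str) -> str:
        s, e = self.amplicon
        return self.sequences[taxon][s:e]

    def reference_db(self, taxa=None, prevalence: dict[str, int] | None = None) -> ReferenceDB:
        taxa = list(taxa) if taxa is not None else self.taxa
        prevalence = prevalence or {}
        records = [
            SequenceRecord(id=t, seq=self.sequences[t],
                           prevalence=prevalence.get(t, 0))
            for t in taxa
        ]
        return ReferenceDB(records=records,
                           taxonomy={t: self.taxonomy[t] for t in taxa})

    def per_sample_asvs(self) -> dict[str, list[SequenceRecord]]:
        """Each sample's ASV set: the full-length sequences of its taxa."""
        return {
            sample: [SequenceRecord(id=t, seq=self.sequences[t])
                     for t in sorted(ab)]
            for sample, ab in self.abundances.items()
        }

    def prevalence(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ab in self.abundances.values():
            for t in ab:
                out[t] = out.get(t, 0) + 1
        return out


def simulate_samples(
    taxa: list[str],
    n_samples: int,
    taxa_per_sample: int,
    lognormal_sigma: float = 1.0,
    seed: int | None = None,
) -> dict[str, dict[str, float]]:
    """Per-sample taxon subsets with lognormal relative abundances."""
    if taxa_per_sample > len(taxa):
        raise ValueError("taxa_per_sample exceeds number of taxa")
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, float]] = {}
    width = len(str(n_samples))
    for i in range(n_samples):
        chosen = rng.choice(len(taxa), size=taxa_per_sample, replace=False)
        weights = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=taxa_per_sample)
        weights /= weights.sum()
        out[f"S{i + 1:0{width}d}"] = {
            taxa[j]: float(w) for j, w in zip(sorted(chosen), weights)
        }
    return out


def make_world(
    n_taxa: int = 40,
    n_samples: int = 8,
    taxa_per_sample: int | None = None,
    lognormal_sigma: float = 1.0,
    depth: float = 0.15,
    root_length: int = 1500,
    seed: int | None = None,
) -> SyntheticWorld:
    """Build a full synthetic study under one master seed."""
    rng = np.random.default_rng(seed)
    s_tree, s_seq, s_ab = (int(rng.integers(2**31)) for _ in range(3))
    tree = simulate_tree(n_taxa, {"depth": depth}, seed=s_tree)
    seqs, tax = evolve_sequences(tree, root_length=root_length, seed=s_seq)
    taxa_per_sample = taxa_per_sample or max(2, n_taxa // 2)
    abund = simulate_samples(
        list(seqs), n_samples, taxa_per_sample, lognormal_sigma, seed=s_ab
    )
    return SyntheticWorld(
        tree=tree, sequences=seqs, taxonomy=tax, abundances=abund, seed=seed
    )


def simulate_reads(
    world: SyntheticWorld,
    sample: str,
    platform: str = "v3v4",
    depth: int = 100,
    error_rate: float | None = None,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Reads from one sample plus the read -> source-taxon truth table.

    ``full_length`` reads are whole taxon sequences (default error rate
    0.001, the HiFi scale); ``v3v4`` reads are the primer-window excision
    (default error 0.005), emitted on a random strand.  Errors are iid
    substitutions; no indels.
    """
    if platform not in ("full_length", "v3v4"):
        raise ValueError(f"unknown platform {platform!r}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if error_rate is None:
        error_rate = 0.001 if platform == "full_length" else 0.005
    rng = np.random.default_rng(seed)
    ab = world.abundances[sample]
    taxa = sorted(ab)
    probs = np.array([ab[t] for t in taxa])
    probs = probs / probs.sum()
    sources = rng.choice(len(taxa), size=depth, p=probs)
    reads: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    from .identity import reverse_complement

    for i, si in enumerate(sources):
        taxon = taxa[int(si)]
        base = world.sequences[taxon] if platform == "full_length" else world.v3v4(taxon)
        arr = _encode(base)
        arr = _mutate(arr, error_rate, rng)
        seq = _decode(arr)
        if platform == "v3v4" and rng.random() < 0.5:
            seq = reverse_complement(seq)
        rid = f"{sample}_{platform}_{i + 1:05d}"
        reads.append(SequenceRecord(id=rid, seq=seq))
        truth[rid] = taxon
    return reads, truth


def plant_redundancy(
    world: SyntheticWorld,
    duplicates_per_taxon: int,
    divergence: float,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Add near-duplicate ASVs around every taxon (trimming benchmark).

    Each duplicate carries exactly ``round(divergence * n_unmasked)``
    substitutions (at least 1) at random unmasked sites, so every
    duplicate sits at the stated divergence from its parent rather than
    at a Poisson draw around it — the benchmark's within/between scale
    separation is then guaranteed, not merely expected.  Returns the
    augmented ASV set (originals first) and the truth map
    asv id -> parent taxon (originals map to themselves).
    """
    rng = np.random.default_rng(seed)
    allowed = np.ones(len(next(iter(world.sequences.values()))), dtype=bool)
    for s, e in tuple(world.primer_windows) + tuple(world.conserved_blocks):
        allowed[s:e] = False
    allowed_idx = np.flatnonzero(allowed)
    n_subs = max(1, int(round(jc_p(divergence) * allowed_idx.size)))
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    for taxon in world.taxa:
        records.append(SequenceRecord(id=taxon, seq=world.sequences[taxon]))
        truth[taxon] = taxon
        parent = _encode(world.sequences[taxon])
        for d in range(duplicates_per_taxon):
            arr = parent.copy()
            sites = rng.choice(allowed_idx, size=n_subs, replace=False)
            arr[sites] = (arr[sites] + rng.integers(1, 4, size=n_subs)) % 4
            rid = f"{taxon}_dup{d + 1}"
            records.append(SequenceRecord(id=rid, seq=_decode(arr)))
            truth[rid] = taxon
    return records, truth
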