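import numpy as np
import pytest
from skbio import TreeNode

import refforge as rf


@pytest.fixture(scope="session")
def small_world():
    """A 20-taxon, 6-sample synthetic community shared across tests."""
    return rf.make_world(n_taxa=20, n_samples=6, taxa_per_sample=10, seed=11)


@pytest.fixture(scope="session")
def clade_world():
    """A world whose tree contains a well-separated 5-taxon clade.

    Background: 15 simulated taxa; a 5-tip clade on a long stem is
    grafted at the root so every clade member is far (>5% divergence)
    from every background taxon while clade members stay close to each
    other.  Used for complementary-selection and augmentation benchmarks.
    """
    from refforge import synthetic as syn

    tree = syn.simulate_tree(15, {"depth": 0.12}, seed=5)
    clade = TreeNode(length=0.08)
    inner = TreeNode(length=0.004)
    for i in range(3):
        inner.append(TreeNode(name=f"c{i + 1}", length=0.008))
    clade.append(inner)
    for i in range(3, 5):
        clade.append(TreeNode(name=f"c{i + 1}", length=0.012))
    tree.append(clade)
    seqs, tax = syn.evolve_sequences(tree, root_length=900, seed=6)
    abund = syn.simulate_samples(list(seqs), n_samples=4, taxa_per_sample=12,
                                 lognormal_sigma=0.8, seed=7)
    return syn.SyntheticWorld(
        tree=tree, sequences=seqs, taxonomy=tax, abundances=abund, seed=5
    )


@pytest.fixture(scope="session")
def clade_ids(clade_world):
    return [t for t in clade_world.taxa if t.startswith("c")]


def grouped_reads(world, per_taxon: int, error_rate: float, seed: int, taxa=None):
    """Error-controlled V3-V4 reads, ``per_taxon`` from each taxon."""
    from refforge.synthetic import _decode, _encode, _mutate
    from refforge.identity import reverse_complement

    rng = np.random.default_rng(seed)
    reads, truth = [], {}
    for taxon in taxa if taxa is not None else world.taxa:
        base = world.v3v4(taxon)
        for i in range(per_taxon):
            arr = _mutate(_encode(base), error_rate, rng)
            seq = _decode(arr)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            rid = f"{taxon}_r{i}"
            reads.append(rf.SequenceRecord(id=rid, seq=seq))
            truth[rid] = taxon
    return reads, truth
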