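"""Pooling per-sample ASV sets into reference candidates.

Full-length amplicon sequence variants (ASVs) from single samples cover
only a slice of a community; pooling k randomly chosen samples and merging
identical sequences yields a candidate reference whose richness grows with
k.  Accumulation curves over k and classical rarefaction over read depth
quantify that coverage.

ASV identity across samples is exact sequence equality: the inputs are
already denoised, so no re-clustering is applied.  Randomness follows a
strict contract — same seed and same input order give identical subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .formats import SequenceRecord


@dataclass
class AccumulationCurve:
    """Expected distinct-ASV count (with spread) along a pooling/depth axis."""

    x: list[int]
    mean_richness: list[float]
    sd: list[float]

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.mean_richness) == len(self.sd)):
            raise ValueError("curve fields must have equal length")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"x": self.x, "mean_richness": self.mean_richness, "sd": self.sd}
        )


def _merge(chosen: dict[str, list[SequenceRecord]]) -> list[SequenceRecord]:
    """Merge identical sequences across samples, accumulating prevalence."""
    by_seq: dict[str, SequenceRecord] = {}
    for _, records in chosen.items():
        sample_seqs = {r.seq for r in records}
        for rec in records:
            if rec.seq not in by_seq:
                by_seq[rec.seq] = SequenceRecord(
                    id=rec.id, seq=rec.seq, prevalence=0, description=rec.description
                )
        for seq in sample_seqs:
            by_seq[seq].prevalence += 1
    return list(by_seq.values())


def combine_samples(
    per_sample_asvs: dict[str, list[SequenceRecord]], k: int, seed: int | None = None
) -> list[SequenceRecord]:
    """Pool k randomly chosen samples into one merged ASV set.

    Identical sequences collapse into a single record whose ``prevalence``
    is the number of chosen samples containing that sequence; the id of
    the first occurrence (in input order) is kept.
    """
    samples = list(per_sample_asvs)
    if not 1 <= k <= len(samples):
        raise ValueError(f"k={k} out of range [1, {len(samples)}]")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(samples), size=k, replace=False)
    chosen = {samples[i]: per_sample_asvs[samples[i]] for i in sorted(idx)}
    return _merge(chosen)


def sample_accumulation(
    per_sample_asvs: dict[str, list[SequenceRecord]],
    ks: list[int],
    replicates: int = 10,
    seed: int | None = None,
) -> AccumulationCurve:
    """Mean/sd distinct-ASV richness over random k-sample subsets."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for k in ks:
        richness = [
            len(combine_samples(per_sample_asvs, k, seed=int(rng.integers(2**31))))
            for _ in range(replicates)
        ]
        means.append(float(np.mean(richness)))
        sds.append(float(np.std(richness, ddof=0)))
    return AccumulationCurve(x=list(ks), mean_richness=means, sd=sds)


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_expected(counts, depth: int) -> float:
    """Expected richness in a random subsample of ``depth`` reads.

    Hypergeometric closed form: E[S] = S - sum_i C(N - N_i, n) / C(N, n),
    evaluated with log-binomials so large counts do not overflow.
    """
    counts = np.asarray(list(counts), dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("all-zero abundance vector")
    total = counts.sum()
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {int(total)}")
    denom = _log_comb(total, depth)
    absent = np.zeros_like(counts)
    feasible = total - counts >= depth
    absent[feasible] = np.exp(_log_comb(total - counts[feasible], depth) - denom)
    return float(counts.size - absent.sum())
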