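"""End-to-end workflow: pool -> tree -> trim sweep -> evaluate -> select.

``optimize_db`` operationalizes the reference-optimization recipe: build
a tree over pooled ASVs, trim pendant branches at a sweep of thresholds,
score each trimmed DB by the fraction of short reads whose top hit
reaches the species band (>=97% identity), and keep the largest
threshold whose fraction stays within a tolerance of the untrimmed DB.

``compare_dbs`` produces the comparison report: identity profiles,
rank-resolution fractions, alpha diversity of the resulting assignment
tables, and LEfSe significant sets with their intersections.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import classifier as clf
from . import diversity as dv
from . import identity as idn
from . import lefse as lf
from . import phylo
from .formats import RANKS, ReferenceDB, SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_TRIM_SWEEP = (0.0005, 0.001, 0.002)


@dataclass
class RunConfig:
    """Validated parameters for a full run."""

    identity_high: float = 97.0
    identity_low: float = 90.0
    trim_sweep: tuple[float, ...] = DEFAULT_TRIM_SWEEP
    trim_tolerance: float = 2.0  # percentage points of the >=97% fraction
    kw_alpha: float = 0.05
    lda_cutoff: float = 3.0
    confidence_cutoff: float = 0.8
    word_size: int = 11
    classifier_k: int = 8
    bootstraps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.identity_low < self.identity_high <= 100:
            raise ValueError("identity thresholds must satisfy 0 < low < high <= 100")
        if any(t < 0 for t in self.trim_sweep):
            raise ValueError("trim thresholds must be >= 0")
        if not 0 < self.kw_alpha < 1 or not 0 < self.confidence_cutoff <= 1:
            raise ValueError("alpha and confidence cutoff must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "trim_sweep" in data:
            data["trim_sweep"] = tuple(data["trim_sweep"])
        return cls(**data)


@dataclass
class OptimizeResult:
    """Outcome of the trim-sweep optimization."""

    db: ReferenceDB
    trim: phylo.TrimResult | None
    chosen_threshold: float
    sweep: list[dict]  # per threshold: n_asvs, high-identity fraction
    untrimmed_fraction: float


def _high_fraction(
    reads: list[SequenceRecord], db: ReferenceDB, config: RunConfig
) -> float:
    hits = idn.search_all(reads, db, k=config.word_size)
    profile = idn.stratify(hits, [config.identity_high, config.identity_low])
    return profile.fraction(f">={config.identity_high:g}%")


def optimize_db(
    asvs: ReferenceDB,
    reads: list[SequenceRecord],
    config: RunConfig = RunConfig(),
    tree=None,
    prevalence: dict[str, int] | None = None,
) -> OptimizeResult:
    """Trim-sweep a pooled ASV DB and keep the largest acceptable threshold.

    ``tree`` may be an externally built newick tree over the same tips;
    otherwise a neighbor-joining tree is built from pairwise JC distances.
    The chosen threshold is the largest in the sweep whose >=97% identity
    fraction lies within ``config.trim_tolerance`` percentage points of
    the untrimmed DB's; if none qualifies the DB is left untrimmed.
    """
    if tree is None:
        ids, dm = phylo.distance_matrix(asvs.records)
        tree = phylo.nj_tree(ids, dm)
    prevalence = prevalence or {r.id: r.prevalence for r in asvs.records}
    seq_length = {r.id: len(r.seq) for r in asvs.records}

    base_fraction = _high_fraction(reads, asvs, config)
    sweep_rows = []
    best: tuple[float, phylo.TrimResult, ReferenceDB] | None = None
    for threshold in sorted(config.trim_sweep):
        trim = phylo.trim_tree(tree, threshold, prevalence, seq_length)
        trimmed_db = phylo.subset_db(asvs, trim.retained_ids)
        frac = _high_fraction(reads, trimmed_db, config)
        drop = (base_fraction - frac) * 100.0
        sweep_rows.append(
            {
                "threshold": threshold,
                "n_asvs": len(trimmed_db),
                "high_identity_fraction": frac,
                "drop_points": drop,
            }
        )
        logger.info(
            "trim threshold %g: %d ASVs, >=%g%% fraction %.3f (drop %.2f pts)",
            threshold, len(trimmed_db), config.identity_high, frac, drop,
        )
        if drop <= config.trim_tolerance:
            if best is None or threshold > best[0]:
                best = (threshold, trim, trimmed_db)
    if best is None:
        return OptimizeResult(
            db=asvs, trim=None, chosen_threshold=0.0,
            sweep=sweep_rows, untrimmed_fraction=base_fraction,
        )
    return OptimizeResult(
        db=best[2], trim=best[1], chosen_threshold=best[0],
        sweep=sweep_rows, untrimmed_fraction=base_fraction,
    )


@dataclass
class ComparisonReport:
    """Side-by-side evaluation of named reference DBs on the same reads."""

    profiles: dict[str, idn.IdentityProfile]
    rank_fractions: dict[str, dict[str, float]]  # db -> rank -> assigned frac
    diversity: dict[str, dict[str, dict[str, float]]]  # db -> sample -> metric
    lefse_significant: dict[str, set[str]]
    intersections: dict[tuple[str, ...], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = sorted(self.lefse_significant)
        inter: dict[tuple[str, ...], set[str]] = {}
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter[(a, b)] = self.lefse_significant[a] & self.lefse_significant[b]
        if len(names) > 2:
            inter[tuple(names)] = set.intersection(
                *(self.lefse_significant[n] for n in names)
            )
        self.intersections = inter

    def unique_sets(self) -> dict[str, set[str]]:
        out = {}
        for name, sig in self.lefse_significant.items():
            others = set().union(
                *(s for n, s in self.lefse_significant.items() if n != name)
            ) if len(self.lefse_significant) > 1 else set()
            out[name] = sig - others
        return out


def compare_dbs(
    dbs: dict[str, ReferenceDB],
    reads_per_sample: dict[str, list[SequenceRecord]],
    classes: dict[str, str],
    config: RunConfig = RunConfig(),
    rank: str = "species",
) -> ComparisonReport:
    """Evaluate >= 2 DBs on the same reads: identity, resolution, LEfSe."""
    if len(dbs) < 2:
        raise ValueError("need at least 2 reference DBs to compare")
    missing = set(reads_per_sample) - set(classes)
    if missing:
        raise ValueError(f"samples without class metadata: {sorted(missing)[:5]}")
    all_reads = [r for reads in reads_per_sample.values() for r in reads]
    rank_idx = RANKS.index(rank)

    profiles, rank_fractions, diversity_out, lefse_sig = {}, {}, {}, {}
    rng = np.random.default_rng(config.seed)
    for name, db in dbs.items():
        hits = idn.search_all(all_reads, db, k=config.word_size)
        profiles[name] = idn.stratify(
            hits, [config.identity_high, config.identity_low]
        )
        model = clf.train(db, k=config.classifier_k)
        tables, _ = clf.assign_table(
            reads_per_sample, model,
            bootstraps=config.bootstraps,
            confidence_cutoff=config.confidence_cutoff,
            seed=int(rng.integers(2**31)),
        )
        rank_fractions[name] = {
            rk: clf.assigned_fraction(tables[rk]) for rk in RANKS
        }
        table = tables[rank]
        diversity_out[name] = {
            s: {
                "chao1": dv.chao1(table.counts[i]),
                "shannon": dv.shannon(table.counts[i]),
            }
            for i, s in enumerate(table.sample_ids)
        }
        class_vec = [classes[s] for s in table.sample_ids]
        if len(set(class_vec)) >= 2:
            results = lf.run_lefse(
                table.counts, class_vec, feature_ids=table.asv_ids,
                alpha=config.kw_alpha, score_cutoff=config.lda_cutoff,
                seed=int(rng.integers(2**31)),
            )
            lefse_sig[name] = {
                r.feature for r in results
                if r.significant and not r.feature.endswith("unassigned")
            }
        else:
            lefse_sig[name] = set()
    return ComparisonReport(
        profiles=profiles,
        rank_fractions=rank_fractions,
        diversity=diversity_out,
        lefse_significant=lefse_sig,
    )


def write_manifest(path, stage: str, inputs: dict[str, str], params: dict) -> None:
    """Record a stage's input checksums and parameters for auditability."""
    digests = {}
    for name, p in inputs.items():
        p = Path(p)
        digests[name] = (
            hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
        )
    Path(path).write_text(
        json.dumps(
            {"stage": stage, "inputs": digests, "params": params}, indent=2,
            default=str,
        )
    )
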