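"""LEfSe-style differential-abundance biomarker discovery.

Two stages on a per-sample-sum-1e6 scaled feature table: a Kruskal-Wallis
screen at ``alpha``, then a bootstrapped linear-discriminant effect size
for the survivors.  Per bootstrap a fraction of samples per class is
subsampled, a Fisher LDA is fitted (one-vs-rest with the max taken for
more than two classes), and a feature's effect is the average of its
share of the projected class separation and its raw class-mean
difference; the reported score is log10(1 + mean bootstrap effect).
Features with score above the cutoff (3.0 here) are called significant.

No subclass (pairwise Wilcoxon) stage is applied: the procedure assumes
flat class structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

TSS_TOTAL = 1e6


@dataclass
class LefseResult:
    """Per-feature outcome: screen p-value, effect size, enrichment call."""

    feature: str
    kw_p: float
    lda_score: float
    enriched_class: str
    significant: bool


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-squared p-value.

    Degenerate all-identical input returns (0, 1) rather than erroring.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >= 2 classes with >= 1 observation each")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def tss_scale(table: np.ndarray, total: float = TSS_TOTAL) -> np.ndarray:
    """Scale each sample (row) to sum to ``total``."""
    table = np.asarray(table, dtype=float)
    sums = table.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise ValueError("sample with zero total abundance")
    return table / sums * total


def _fisher_w(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Unit-norm Fisher discriminant direction for two classes."""
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    sw = np.cov(x1, rowvar=False) * (len(x1) - 1) + np.cov(x2, rowvar=False) * (
        len(x2) - 1
    )
    sw = np.atleast_2d(sw)
    ridge = 1e-6 * max(np.trace(sw) / sw.shape[0], 1.0)
    w = np.linalg.solve(sw + ridge * np.eye(sw.shape[0]), mu1 - mu2)
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros_like(w)
    return w / norm


def _pair_effect(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    w = _fisher_w(x1, x2)
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    delta = abs(float(w @ (mu1 - mu2)))
    return (np.abs(w) * delta + np.abs(mu1 - mu2)) / 2.0


def lda_effect_size(
    scaled: np.ndarray,
    classes: list[str],
    bootstraps: int = 30,
    subsample_fraction: float = 2.0 / 3.0,
    seed: int | None = None,
) -> np.ndarray:
    """Per-feature LDA effect score log10(1 + mean bootstrap effect).

    ``scaled`` must already be per-sample TSS-scaled (sum 1e6).  Classes
    with fewer than 2 samples after subsampling trigger a redraw (at most
    10, then an error).
    """
    scaled = np.asarray(scaled, dtype=float)
    classes = np.asarray(classes)
    labels = sorted(set(classes.tolist()))
    if len(labels) < 2:
        raise ValueError("need >= 2 classes")
    rng = np.random.default_rng(seed)
    idx_by_class = {c: np.flatnonzero(classes == c) for c in labels}
    effects = np.zeros((bootstraps, scaled.shape[1]))
    for b in range(bootstraps):
        for attempt in range(10):
            sub_idx = {}
            ok = True
            for c in labels:
                idx = idx_by_class[c]
                m = max(1, int(round(subsample_fraction * len(idx))))
                chosen = rng.choice(idx, size=m, replace=False)
                if len(chosen) < 2:
                    ok = False
                sub_idx[c] = chosen
            if ok:
                break
        else:
            raise ValueError("a class has too few samples to subsample")
        if len(labels) == 2:
            eff = _pair_effect(scaled[sub_idx[labels[0]]], scaled[sub_idx[labels[1]]])
        else:
            # one-vs-rest, max over rests
            per = []
            for c in labels:
                rest = np.concatenate([sub_idx[o] for o in labels if o != c])
                per.append(_pair_effect(scaled[sub_idx[c]], scaled[rest]))
            eff = np.max(per, axis=0)
        effects[b] = eff
    return np.log10(1.0 + effects.mean(axis=0))


def run_lefse(
    table: np.ndarray,
    classes: list[str],
    feature_ids: list[str] | None = None,
    alpha: float = 0.05,
    score_cutoff: float = 3.0,
    bootstraps: int = 30,
    seed: int | None = None,
) -> list[LefseResult]:
    """Full screen-then-score procedure; results sorted by score.

    ``table`` is samples x features raw abundance; it is TSS-scaled to
    1e6 internally.  A feature is significant iff its Kruskal-Wallis p is
    below ``alpha`` and its LDA score exceeds ``score_cutoff``.
    """
    table = np.asarray(table, dtype=float)
    classes = list(classes)
    if table.shape[0] != len(classes):
        raise ValueError("table rows and class vector must align")
    if len(set(classes)) < 2:
        raise ValueError("need >= 2 classes")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(table.shape[1])]
    scaled = tss_scale(table)
    class_arr = np.asarray(classes)
    labels = sorted(set(classes))

    kw_p = np.ones(table.shape[1])
    for j in range(table.shape[1]):
        groups = [scaled[class_arr == c, j] for c in labels]
        _, kw_p[j] = kruskal_wallis(groups)
    survivors = np.flatnonzero(kw_p < alpha)

    scores = np.zeros(table.shape[1])
    if survivors.size:
        scores[survivors] = lda_effect_size(
            scaled[:, survivors], classes, bootstraps=bootstraps, seed=seed
        )

    results = []
    for j in range(table.shape[1]):
        means = {c: float(scaled[class_arr == c, j].mean()) for c in labels}
        enriched = max(means, key=lambda c: (means[c], c))
        results.append(
            LefseResult(
                feature=feature_ids[j],
                kw_p=float(kw_p[j]),
                lda_score=float(scores[j]),
                enriched_class=enriched,
                significant=bool(kw_p[j] < alpha and scores[j] > score_cutoff),
            )
        )
    results.sort(key=lambda r: -r.lda_score)
    return results
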