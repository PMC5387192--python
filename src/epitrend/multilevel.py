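"""Detection of multilevel (spawn-linked) gene expression.

A multilevel gene is expressed at two or three discrete levels that
persist across the whole developmental window, with the level an embryo
sits on largely determined by its spawn.  Detection: (1) keep genes with
log2 profile variance above -0.1; (2) cluster the 1-D intensity values
by k-means (k = 2, and k = 3 when the 2-cluster solution leaves clear
tri-modal structure); (3) require the within- to between-cluster
sum-of-squares ratio to be below 0.3; (4) require every level to span
more than a third of the developmental range; (5) reject calls whose
levels separate in time rather than coexist - a single rank threshold
classifying the levels at >= 95% purity marks a temporal trend, not a
multilevel gene.  Spawn linkage is quantified by the adjusted Rand index
between level assignment and spawn partition with a permutation null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score


@dataclass
class MultilevelParams:
    var_cutoff: float = -0.1  # log2 variance below which a gene cannot be multilevel
    ratio_cutoff: float = 0.3  # WSS/BSS must fall below this
    span_cutoff: float = 1.0 / 3.0  # every level must span more of the range than this
    k_values: tuple[int, ...] = (2, 3)
    restarts: int = 25
    purity_cutoff: float = 0.95  # rank-separability at/above this is a temporal artifact
    # a 2-means ratio above this marks genuinely unimodal structure, in which
    # case the 3-level route is not attempted (noiseless three equal levels
    # give 1/3; a single Gaussian gives ~0.57)
    trimodal_guard: float = 0.45


@dataclass
class MultilevelCall:
    gene: str | None
    n_levels: int | None  # 2 or 3; None = not multilevel
    assignments: np.ndarray | None
    wss_bss_ratio: float
    level_spans: tuple[float, ...] = ()
    temporal_artifact: bool = False
    log2_variance: float = float("nan")
    spawn_ari: float | None = None
    spawn_p: float | None = None

    @property
    def is_multilevel(self) -> bool:
        return self.n_levels is not None


def kmeans_1d(values: Sequence[float], k: int, restarts: int = 25,
              seed: int = 0) -> tuple[np.ndarray, float, float]:
    """Best-of-``restarts`` k-means on 1-D values.

    Returns (labels, WSS, BSS) with labels renumbered by ascending
    cluster mean; BSS is the total sum of squares minus WSS.
    """
    x = np.asarray(values, dtype=float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(x).size < k:
        raise ValueError(f"k={k} exceeds the number of distinct values")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(x.reshape(-1, 1))
    labels = km.labels_
    wss = float(km.inertia_)
    tss = float(np.sum((x - x.mean()) ** 2))
    bss = tss - wss
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[labels], wss, bss


def _level_spans(labels: np.ndarray) -> tuple[float, ...]:
    """Per level, the fraction of the rank range its members cover."""
    n = labels.size
    spans = []
    for lv in np.unique(labels):
        idx = np.nonzero(labels == lv)[0]
        spans.append((idx.max() - idx.min()) / (n - 1) if n > 1 else 0.0)
    return tuple(spans)


def _pairwise_rank_purity(labels: np.ndarray) -> float:
    """Max over level pairs of the best single-rank-threshold accuracy
    separating the two levels; 1.0 means perfectly time-separated."""
    best = 0.0
    levels = np.unique(labels)
    for i in range(levels.size):
        for j in range(i + 1, levels.size):
            idx = np.nonzero((labels == levels[i]) | (labels == levels[j]))[0]
            is_i = (labels[idx] == levels[i]).astype(int)
            n = idx.size
            # cumulative count of level-i members below each threshold
            cum = np.concatenate([[0], np.cumsum(is_i)])
            total_i = cum[-1]
            thresholds = np.arange(n + 1)
            # level i before the threshold, level j after - or the reverse
            acc_fwd = (cum + (n - total_i) - (thresholds - cum)) / n
            acc_rev = ((total_i - cum) + (thresholds - cum)) / n
            best = max(best, float(acc_fwd.max()), float(acc_rev.max()))
    return best


def call_multilevel(profile: Sequence[float], params: MultilevelParams | None = None,
                    seed: int = 0, gene: str | None = None) -> MultilevelCall:
    """Decide whether an ordered expression profile is multilevel.

    The 2-cluster solution is evaluated first; the 3-cluster solution is
    consulted when 2-means either succeeds but leaves strong residual
    structure or fails with a ratio still far below the unimodal regime
    (``trimodal_guard``), which is how three genuine levels present to a
    2-means fit.
    """
    params = params or MultilevelParams()
    y = np.asarray(profile, dtype=float)
    var = float(np.var(y, ddof=1))
    logvar = math.log2(var) if var > 0 else -math.inf
    base = MultilevelCall(gene=gene, n_levels=None, assignments=None,
                          wss_bss_ratio=float("inf"), log2_variance=logvar)
    if logvar <= params.var_cutoff:
        return base

    def _evaluate(k: int) -> MultilevelCall | None:
        if np.unique(y).size <= k:
            return None
        labels, wss, bss = kmeans_1d(y, k, params.restarts, seed)
        ratio = wss / bss if bss > 0 else float("inf")
        spans = _level_spans(labels)
        purity = _pairwise_rank_purity(labels)
        call = MultilevelCall(
            gene=gene, n_levels=k, assignments=labels, wss_bss_ratio=ratio,
            level_spans=spans, temporal_artifact=purity >= params.purity_cutoff,
            log2_variance=logvar,
        )
        ok = (ratio < params.ratio_cutoff and all(s > params.span_cutoff for s in spans)
              and not call.temporal_artifact)
        return call if ok else None

    k_values = sorted(params.k_values)
    call2 = _evaluate(2) if 2 in k_values else None
    call3 = None
    if 3 in k_values:
        try:
            labels2, wss2, bss2 = kmeans_1d(y, 2, params.restarts, seed)
            ratio2 = wss2 / bss2 if bss2 > 0 else float("inf")
        except ValueError:
            ratio2 = float("inf")
        if ratio2 < params.trimodal_guard:
            try:
                labels3, wss3, _ = kmeans_1d(y, 3, params.restarts, seed)
                strong_gain = wss2 > 0 and wss3 / wss2 < 0.3
            except ValueError:
                strong_gain = False
            if strong_gain or call2 is None:
                call3 = _evaluate(3)

    if call3 is not None and (call2 is None or call3.wss_bss_ratio < call2.wss_bss_ratio):
        return call3
    if call2 is not None:
        return call2
    # record why the gene was rejected (ratio/artifact of the k=2 attempt)
    if np.unique(y).size > 2:
        labels, wss, bss = kmeans_1d(y, 2, params.restarts, seed)
        base.wss_bss_ratio = wss / bss if bss > 0 else float("inf")
        base.level_spans = _level_spans(labels)
        base.temporal_artifact = _pairwise_rank_purity(labels) >= params.purity_cutoff
    return base


def plot_multilevel_gene(profile: Sequence[float], spawn_labels: Sequence[int],
                         assignments: Sequence[int] | None = None,
                         gene: str | None = None, ax_pair=None):
    """Paired panels for one gene: expression by developmental order, and
    the same embryos regrouped spawn-by-spawn (each spawn's embryos kept
    in developmental order).  The regrouped panel makes spawn-linked
    levels visually obvious.  Returns the two axes."""
    import matplotlib.pyplot as plt

    y = np.asarray(profile, dtype=float)
    s = np.asarray(spawn_labels)
    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(9, 3), sharey=True)
    left, right = ax_pair
    colors = assignments if assignments is not None else s
    left.scatter(np.arange(1, y.size + 1), y, c=colors, s=8, cmap="viridis")
    left.set_xlabel("developmental rank")
    left.set_ylabel("log2 intensity")
    regroup = np.argsort(s, kind="stable")
    right.scatter(np.arange(1, y.size + 1), y[regroup],
                  c=np.asarray(colors)[regroup], s=8, cmap="viridis")
    right.set_xlabel("embryos grouped by spawn")
    if gene:
        left.set_title(f"{gene} by order")
        right.set_title(f"{gene} by spawn, then order")
    return ax_pair


def spawn_association(assignments: Sequence[int], spawn_labels: Sequence[int],
                      n_permutations: int = 999, seed: int = 0) -> tuple[float, float]:
    """Adjusted Rand index between a level assignment and the spawn
    partition, with a permutation p-value (spawn labels shuffled)."""
    a = np.asarray(assignments)
    s = np.asarray(spawn_labels)
    if a.size != s.size:
        raise ValueError("assignments and spawn_labels differ in length")
    ari = float(adjusted_rand_score(s, a))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if adjusted_rand_score(rng.permutation(s), a) >= ari:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return ari, float(p)
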