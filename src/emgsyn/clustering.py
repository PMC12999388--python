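"""Group-level synergy templates and cross-group matching.

Weight vectors from all subjects of one intervention condition are pooled
and clustered with K-means (squared-Euclidean objective, many random
restarts, best within-cluster sum of squares kept).  The cluster count is
chosen by the Gap statistic with the one-standard-error rule, reference
sets drawn uniformly over the per-dimension data range.  Cross-condition
comparison matches candidate templates to a reference set greedily by
descending Pearson correlation, one-to-one, with r >= 0.6 required; the
leftovers are flagged condition-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .synergy import SynergySet


@dataclass
class TemplateSet:
    group: str
    templates: np.ndarray          # (k x M), rows max-normalized
    k: int
    assignments: np.ndarray        # per pooled vector, in 0..k-1
    gap_curve: list[dict[str, float]] = field(default_factory=list)
    inertia: float = 0.0


@dataclass
class MatchResult:
    pairs: list[tuple[int, int, float]]   # (reference id, candidate id, r)
    unmatched: list[int]                  # candidate ids flagged group-specific
    threshold: float = 0.6


def _fit_kmeans(vectors: np.ndarray, k: int, n_reps: int,
                seed: int) -> KMeans:
    km = KMeans(n_clusters=k, init="random", n_init=n_reps,
                algorithm="lloyd", random_state=seed % (2 ** 31))
    km.fit(vectors)
    return km


def kmeans_fit(vectors: np.ndarray, k: int, n_reps: int = 1000,
               seed: int = 0, group: str = "") -> TemplateSet:
    """Best-of-``n_reps`` Lloyd K-means with squared-Euclidean objective."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.shape[0] < k:
        raise ValueError(f"{vectors.shape[0]} vectors cannot form {k} clusters")
    km = _fit_kmeans(vectors, k, n_reps, seed)
    return TemplateSet(group=group, templates=km.cluster_centers_.copy(),
                       k=k, assignments=km.labels_.copy(),
                       inertia=float(km.inertia_))


def _wcss(vectors: np.ndarray, k: int, n_reps: int, seed: int) -> float:
    return float(_fit_kmeans(vectors, k, n_reps, seed).inertia_)


def gap_select_k(vectors: np.ndarray, k_min: int = 1, k_max: int = 8,
                 n_refs: int = 50, seed: int = 0,
                 n_reps: int = 5) -> tuple[int, list[dict[str, float]]]:
    """Gap-statistic cluster count with the one-standard-error rule.

    Gap(k) = mean_b log(WCSS_ref_b(k)) - log(WCSS_data(k)); the chosen k is
    the smallest with Gap(k) >= Gap(k+1) - s(k+1), where s carries the
    sqrt(1 + 1/B) simulation-error factor.  Reference sets are uniform over
    each dimension's observed range.
    """
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    k_max = min(k_max, n)
    if np.ptp(vectors, axis=0).max() == 0.0:
        return 1, [{"k": 1, "gap": 0.0, "s": 0.0}]
    rng = np.random.default_rng(seed)
    lo, hi = vectors.min(axis=0), vectors.max(axis=0)
    refs = [rng.uniform(lo, hi, size=vectors.shape) for _ in range(n_refs)]

    tiny = np.finfo(float).tiny
    curve: list[dict[str, float]] = []
    for k in range(k_min, k_max + 1):
        log_w = np.log(max(_wcss(vectors, k, n_reps,
                                 int(rng.integers(2 ** 31))), tiny))
        log_w_refs = np.array([
            np.log(max(_wcss(r, k, n_reps, int(rng.integers(2 ** 31))), tiny))
            for r in refs])
        gap = float(log_w_refs.mean() - log_w)
        s = float(log_w_refs.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_refs))
        curve.append({"k": k, "gap": gap, "s": s})

    for a, b in zip(curve, curve[1:]):
        if a["gap"] >= b["gap"] - b["s"]:
            return int(a["k"]), curve
    return int(curve[-1]["k"]), curve


def build_templates(group_synergy_sets: Sequence[SynergySet], seed: int = 0,
                    group: str = "", k_max: int = 8, n_refs: int = 50,
                    n_reps: int = 1000, gap_reps: int = 5) -> TemplateSet:
    """Pool weight rows across subjects, pick k by Gap, fit templates.

    The pool is sorted canonically before clustering so the result does not
    depend on input order.
    """
    if not group_synergy_sets:
        raise ValueError("empty pool of synergy sets")
    pool = np.vstack([s.weights for s in group_synergy_sets])
    order = np.lexsort(pool.T[::-1])
    pool = pool[order]
    k, curve = gap_select_k(pool, k_max=min(k_max, pool.shape[0]),
                            n_refs=n_refs, seed=seed, n_reps=gap_reps)
    ts = kmeans_fit(pool, k, n_reps=n_reps, seed=seed, group=group)
    scale = ts.templates.max(axis=1)
    scale[scale == 0] = 1.0
    ts.templates = ts.templates / scale[:, None]
    ts.gap_curve = curve
    return ts


def _pearson_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between rows of A and rows of B (NaN if a row is
    constant)."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (A @ B.T) / np.outer(na, nb)
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def match_templates(reference: TemplateSet, candidate: TemplateSet,
                    r_threshold: float = 0.6,
                    method: str = "greedy") -> MatchResult:
    """One-to-one template matching by Pearson correlation of weight rows.

    ``greedy`` repeatedly takes the highest-r unmatched pair with
    r >= threshold; ``hungarian`` solves the optimal assignment first and
    then applies the threshold.  Candidates left unmatched are flagged
    condition-specific.
    """
    if reference.templates.shape[1] != candidate.templates.shape[1]:
        raise ValueError("muscle dimensions differ between template sets")
    r = _pearson_matrix(reference.templates, candidate.templates)
    pairs: list[tuple[int, int, float]] = []
    if method == "hungarian":
        cost = np.where(np.isnan(r), -2.0, r)
        ri, ci = linear_sum_assignment(-cost)
        for i, j in zip(ri, ci):
            if cost[i, j] >= r_threshold:
                pairs.append((int(i), int(j), float(r[i, j])))
    elif method == "greedy":
        avail = np.where(np.isnan(r), -np.inf, r).copy()
        while True:
            i, j = np.unravel_index(np.argmax(avail), avail.shape)
            if avail[i, j] < r_threshold:
                break
            pairs.append((int(i), int(j), float(r[i, j])))
            avail[i, :] = -np.inf
            avail[:, j] = -np.inf
    else:
        raise ValueError(f"unknown matching method {method!r}")
    matched_c = {j for _, j, _ in pairs}
    unmatched = [j for j in range(candidate.k) if j not in matched_c]
    return MatchResult(pairs=sorted(pairs), unmatched=unmatched,
                       threshold=r_threshold)
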