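"""Muscle-synergy extraction by non-negative matrix factorization.

The envelope matrix D (muscles x time) is approximated as D ~ sum_i of
outer(W_i, C_i): time-invariant muscle weight vectors W_i scaled by
time-varying activation coefficients C_i(t).  Factors are fit with
multiplicative updates minimizing the Frobenius reconstruction error,
restarted from many random initializations (best variance-accounted-for
kept), and the model order is the smallest synergy count whose VAF exceeds
90%.

VAF is uncentered: VAF = 1 - SSE/SST with SST = sum(D^2), so perfect
reconstruction gives 1 and the zero reconstruction gives 0 (the convention
of the muscle-synergy literature; a centered variant is available via
``centered=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass
class SynergySet:
    """Result of model-order selection on one envelope matrix.

    ``weights`` is (nsyn x muscles) with each row max-normalized to 1 (the
    scale folded into ``activations``); ``vaf_curve[k-1]`` is the best-of-
    restarts VAF at k synergies for k = 1..len(vaf_curve).
    """

    weights: np.ndarray
    activations: np.ndarray
    nsyn: int
    vaf: float
    vaf_curve: list[float]
    n_runs: int
    seed: int
    selected: bool = True
    child_seeds: list[int] = field(default_factory=list)

    def reconstruction(self) -> np.ndarray:
        return self.weights.T @ self.activations


def compute_vaf(D: np.ndarray, W: np.ndarray, C: np.ndarray,
                centered: bool = False) -> float:
    """Variance accounted for by the reconstruction W.T @ C.

    ``W`` is (k x muscles), ``C`` is (k x time), matching ``SynergySet``.
    """
    D = np.asarray(D, dtype=float)
    recon = np.asarray(W, dtype=float).T @ np.asarray(C, dtype=float)
    if recon.shape != D.shape:
        raise ValueError(f"reconstruction {recon.shape} != data {D.shape}")
    sse = float(((D - recon) ** 2).sum())
    if centered:
        sst = float(((D - D.mean()) ** 2).sum())
    else:
        sst = float((D ** 2).sum())
    if sst == 0.0:
        raise ValueError("SST is zero (all-zero data): VAF undefined")
    return 1.0 - sse / sst


def _normalize_output(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # rows of W to unit max; scale folded into C so W.T @ C is unchanged
    scale = W.max(axis=1)
    scale[scale == 0] = 1.0
    return W / scale[:, None], C * scale[:, None]


def nmf_once(D: np.ndarray, k: int, seed: int, max_iter: int = 1000,
             tol: float = 1e-6, objective_history: list[float] | None = None,
             ) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update factorization from a seeded random start.

    Factors are initialized Uniform(0, max(D)).  The Frobenius objective is
    non-increasing across iterations; iteration stops when its relative
    change drops below ``tol``.  Returns (weights (k x muscles),
    activations (k x time), vaf).
    """
    D = np.asarray(D, dtype=float)
    if (D < 0).any():
        raise ValueError("NMF input must be non-negative")
    m, t = D.shape
    if not 1 <= k <= min(m, t):
        raise ValueError(f"k={k} out of range for {D.shape} matrix")
    rng = np.random.default_rng(seed)
    hi = float(D.max())
    if hi == 0.0:
        raise ValueError("all-zero matrix cannot be factorized")
    W = rng.uniform(0.0, hi, size=(m, k))
    C = rng.uniform(0.0, hi, size=(k, t))

    obj = float(((D - W @ C) ** 2).sum())
    if objective_history is not None:
        objective_history.append(obj)
    for _ in range(max_iter):
        C *= (W.T @ D) / (W.T @ W @ C + _EPS)
        W *= (D @ C.T) / (W @ C @ C.T + _EPS)
        new_obj = float(((D - W @ C) ** 2).sum())
        if objective_history is not None:
            objective_history.append(new_obj)
        if abs(obj - new_obj) <= tol * max(obj, _EPS):
            obj = new_obj
            break
        obj = new_obj

    Wk, Ck = _normalize_output(W.T, C)
    return Wk, Ck, compute_vaf(D, Wk, Ck)


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds for restarts (recorded for replay)."""
    return [(seed * 1_000_003 + 7919 * i + 1) % (2 ** 31 - 1)
            for i in range(n)]


def nmf_best_of(D: np.ndarray, k: int, n_runs: int = 50, seed: int = 0,
                max_iter: int = 1000, tol: float = 1e-6,
                ) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-VAF solution over ``n_runs`` seeded restarts (ties -> lowest run)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for s in spawn_seeds(seed, n_runs):
        W, C, vaf = nmf_once(D, k, s, max_iter=max_iter, tol=tol)
        if best is None or vaf > best[2]:
            best = (W, C, vaf)
    assert best is not None
    return best


def select_nsyn(D: np.ndarray, k_min: int = 1, k_max: int = 14,
                vaf_threshold: float = 0.9, n_runs: int = 50, seed: int = 0,
                max_iter: int = 1000, tol: float = 1e-6,
                full_curve: bool = False) -> SynergySet:
    """Smallest synergy count whose best-of-restarts VAF exceeds threshold.

    Extraction runs k = k_min..k_max, by default stopping at the first k
    that passes (``full_curve=True`` evaluates every k and still selects the
    smallest passing one).  If no k passes, the k_max solution is returned
    flagged ``selected=False``.
    """
    D = np.asarray(D, dtype=float)
    k_max = min(k_max, *D.shape)
    vaf_curve: list[float] = []
    solutions: list[tuple[np.ndarray, np.ndarray, float]] = []
    chosen: int | None = None
    for k in range(k_min, k_max + 1):
        W, C, vaf = nmf_best_of(D, k, n_runs=n_runs, seed=seed,
                                max_iter=max_iter, tol=tol)
        vaf_curve.append(vaf)
        solutions.append((W, C, vaf))
        if chosen is None and vaf > vaf_threshold:
            chosen = k
            if not full_curve:
                break
    selected = chosen is not None
    k_sel = chosen if selected else k_max
    W, C, vaf = solutions[k_sel - k_min]
    return SynergySet(weights=W, activations=C, nsyn=k_sel, vaf=vaf,
                      vaf_curve=vaf_curve, n_runs=n_runs, seed=seed,
                      selected=selected,
                      child_seeds=spawn_seeds(seed, n_runs))
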