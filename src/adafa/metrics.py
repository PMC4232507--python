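"""Protein model quality scores for matched C-alpha traces.

All scores compare two equal-length, residue-aligned coordinate sets and are
invariant to rigid motions of either structure:

* **RMSD** after optimal least-squares superposition (Kabsch algorithm,
  proper rotations only).
* **TM-Score**: length-normalized similarity in (0, 1],
  ``max over superpositions of (1/L) * sum_i 1 / (1 + (d_i/d0)^2)`` with
  ``d0 = 1.24 * (L - 15)**(1/3) - 1.8`` clamped to at least 0.5 A (the
  small-protein convention; relevant for chains of ~15 residues or fewer).
  The maximization uses the standard iterative seed-superpose-extend search
  over contiguous fragments.
* **GDT-TS / GDT-HA**: mean over distance cutoffs ({1,2,4,8} A and
  {0.5,1,2,4} A respectively) of the maximal percentage of residues that can
  be superposed within the cutoff, on a 0-100 scale.  The per-cutoff
  maximization uses the community sliding-window seed plus iterative
  extension heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScoreSet",
    "kabsch",
    "superpose_rmsd",
    "tm_score",
    "gdt_scores",
    "score_traces",
]


@dataclass
class ScoreSet:
    rmsd: float
    tm: float
    gdt_ts: float
    gdt_ha: float


def _coords(x) -> np.ndarray:
    c = np.asarray(getattr(x, "coords", x), dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    return c


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation R and translation t minimizing ||R P + t - Q||.

    Returns ``(R, t)`` such that ``P @ R.T + t`` best fits ``Q`` in the
    least-squares sense.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    return R, t


def superpose_rmsd(a, b, return_transform: bool = False):
    """Minimal RMSD between two traces over all rigid motions (proper only)."""
    A, B = _coords(a), _coords(b)
    if A.shape != B.shape:
        raise ValueError("traces must have equal length")
    if A.shape[0] < 3:
        raise ValueError("superposition requires at least 3 atoms")
    R, t = kabsch(A, B)
    fitted = A @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - B) ** 2, axis=1))))
    if return_transform:
        return rmsd, R, t
    return rmsd


def _fit_on_subset(model: np.ndarray, ref: np.ndarray, idx: np.ndarray) -> np.ndarray:
    R, t = kabsch(model[idx], ref[idx])
    d = np.linalg.norm(model @ R.T + t - ref, axis=1)
    return d


def _seed_windows(n: int, min_len: int = 4) -> list[np.ndarray]:
    idx = np.arange(n)
    seeds = [idx]
    if n <= 24:
        lengths = range(min_len, n)          # exhaustive windows on small chains
        step_of = lambda L: 1
    else:
        lengths = {max(min_len, n // 2), max(min_len, n // 4), min_len}
        step_of = lambda L: max(1, L // 2)
    for L in lengths:
        if L >= n:
            continue
        for s in range(0, n - L + 1, step_of(L)):
            seeds.append(idx[s:s + L])
    return seeds


def tm_score(model, ref) -> float:
    """TM-Score of ``model`` against ``ref`` (1 for identical structures)."""
    M, Rf = _coords(model), _coords(ref)
    if M.shape != Rf.shape:
        raise ValueError("traces must have equal length")
    n = M.shape[0]
    d0 = max(1.24 * (n - 15) ** (1.0 / 3.0) - 1.8, 0.5) if n > 15 else 0.5
    best = 0.0
    for seed in _seed_windows(n):
        idx = seed
        for _ in range(20):
            d = _fit_on_subset(M, Rf, idx)
            score = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
            best = max(best, score)
            new_idx = np.where(d < d0)[0]
            if new_idx.size < 3 or np.array_equal(new_idx, idx):
                break
            idx = new_idx
    return best


def _max_fraction_within(model: np.ndarray, ref: np.ndarray, cutoff: float) -> float:
    """Largest fraction of residues superposable within ``cutoff`` Angstroms.

    Exact (exhaustive over subsets) for chains of up to 10 residues, where
    that is affordable; otherwise window seeds plus iterative extension,
    complemented by a greedy shrink pass (drop the worst-fitting residue,
    refit) that handles outlier-contaminated sets the extension cannot
    reach.
    """
    import itertools

    n = model.shape[0]
    best = 0
    if n <= 10:
        for size in range(3, n + 1):
            for subset in itertools.combinations(range(n), size):
                d = _fit_on_subset(model, ref, np.array(subset))
                best = max(best, int(np.sum(d <= cutoff)))
        return best / n
    for seed in _seed_windows(n, min_len=3):
        idx = seed
        for _ in range(20):
            d = _fit_on_subset(model, ref, idx)
            within = np.where(d <= cutoff)[0]
            best = max(best, within.size)
            if within.size < 3 or np.array_equal(within, idx):
                break
            idx = within
    idx = np.arange(n)
    while idx.size >= 3:
        d = _fit_on_subset(model, ref, idx)
        best = max(best, int(np.sum(d <= cutoff)))
        if idx.size == 3:
            break
        idx = np.delete(idx, int(np.argmax(d[idx])))
    return best / n


def gdt_scores(model, ref) -> tuple[float, float]:
    """(GDT-TS, GDT-HA) on the 0-100 scale."""
    M, Rf = _coords(model), _coords(ref)
    if M.shape != Rf.shape:
        raise ValueError("traces must have equal length")
    cutoffs = (0.5, 1.0, 2.0, 4.0, 8.0)
    fracs = {}
    run = 0.0  # any set superposable within c is superposable within c' > c
    for c in cutoffs:
        run = max(run, _max_fraction_within(M, Rf, c))
        fracs[c] = run
    ts = 100.0 * np.mean([fracs[c] for c in (1.0, 2.0, 4.0, 8.0)])
    ha = 100.0 * np.mean([fracs[c] for c in (0.5, 1.0, 2.0, 4.0)])
    return float(ts), float(ha)


def score_traces(model, ref) -> ScoreSet:
    """All four quality scores of a model against its reference."""
    ts, ha = gdt_scores(model, ref)
    return ScoreSet(
        rmsd=superpose_rmsd(model, ref),
        tm=tm_score(model, ref),
        gdt_ts=ts,
        gdt_ha=ha,
    )
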