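"""Independent brute-force oracles used to cross-check the implementations.

These are deliberately naive and share no code with the package.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

_STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(seq: str, min_len: int = 3, all_starts: bool = False):
    """Every (start, end) pair with ATG at start, in-frame stop at end-3,
    no earlier in-frame stop, length >= max(min_len, 6).

    Returns sorted list of (start, end). With ``all_starts=False`` only the
    5'-most ATG per (frame, stop) is kept.
    """
    seq = seq.upper()
    n = len(seq)
    pairs = []
    for i in range(n - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= n:
            codon = seq[j : j + 3]
            if codon in _STOPS:
                end = j + 3
                if end - i >= max(min_len, 6):
                    pairs.append((i, end))
                break
            j += 3
    if not all_starts:
        best: dict[tuple[int, int], int] = {}
        for start, end in pairs:
            key = (start % 3, end)
            if key not in best or start < best[key]:
                best[key] = start
        pairs = [(s, e) for (_, e), s in best.items()]
    return sorted(pairs)


def exact_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct summation."""
    if k <= 0:
        return 1.0
    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1)) / total


def logrank_chi2_oracle(days: np.ndarray, died: np.ndarray, in_a: np.ndarray) -> float:
    """Plain-loop Mantel-Cox chi-square (no shared code with the package)."""
    death_times = sorted(set(days[died]))
    num = 0.0
    var = 0.0
    for t in death_times:
        at_risk = days >= t
        n = at_risk.sum()
        n_a = (at_risk & in_a).sum()
        dead = died & (days == t)
        d = dead.sum()
        d_a = (dead & in_a).sum()
        num += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return 0.0 if var == 0 else num**2 / var


def permutation_logrank_p(days: np.ndarray, died: np.ndarray, n_a: int) -> float:
    """Exhaustive permutation p for the log-rank chi-square over all
    relabelings assigning n_a subjects to group A."""
    idx = np.arange(len(days))
    obs_in_a = np.zeros(len(days), dtype=bool)
    obs_in_a[:n_a] = True
    observed = logrank_chi2_oracle(days, died, obs_in_a)
    count = 0
    total = 0
    for combo in itertools.combinations(idx, n_a):
        in_a = np.zeros(len(days), dtype=bool)
        in_a[list(combo)] = True
        if logrank_chi2_oracle(days, died, in_a) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def permutation_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive two-sided permutation p for the rank-sum statistic."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    obs = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        s = ranks[list(combo)].sum()
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
        total += 1
    return count / total
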