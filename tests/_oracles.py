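"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with naive algorithms (exhaustive
DP, enumeration, direct arithmetic) and must stay independent of the
package implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np

PAIRABLE = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def smith_waterman(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> tuple[float, int]:
    """Affine-gap local alignment; returns (best score, identities on
    one best path)."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(
                0.0, max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            )
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    best = float(max(M.max(), 0.0))
    # traceback from one best cell through explicit state decisions
    i, j = np.unravel_index(np.argmax(M), M.shape)
    identities = 0
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] == 0:
                break
            s = match if a[i - 1] == b[j - 1] else mismatch
            identities += int(a[i - 1] == b[j - 1])
            prev = M[i, j] - s
            if np.isclose(prev, M[i - 1, j - 1]):
                state = "M"
            elif np.isclose(prev, X[i - 1, j - 1]):
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            state = "M" if np.isclose(X[i, j], M[i - 1, j] + gap_open) else "X"
            i -= 1
        else:
            state = "M" if np.isclose(Y[i, j], M[i, j - 1] + gap_open) else "Y"
            j -= 1
    return best, identities


def nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum number of nested base pairs (Nussinov DP)."""
    seq = seq.upper()
    n = len(seq)
    dp = np.zeros((n, n), dtype=int)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]
            for k in range(i, j - min_loop):
                if (seq[k], seq[j]) in PAIRABLE:
                    left = dp[i, k - 1] if k > i else 0
                    best = max(best, left + 1 + dp[k + 1, j - 1])
            dp[i, j] = best
    return int(dp[0, n - 1])


def exact_loo_bootstrap(values: list[float], index: int) -> float:
    """Exact leave-one-out probability by enumerating every resample."""
    held = values[index]
    remaining = [v for k, v in enumerate(values) if k != index]
    r = len(remaining)
    total = 0
    below = 0
    for combo in itertools.product(remaining, repeat=r):
        total += 1
        below += int(np.mean(combo) < held)
    return below / total


def naive_seed_scan(
    matures: dict[str, str],
    utrs: dict[str, str],
    end_exclusion: int = 15,
) -> set[tuple[str, str, int, str]]:
    """Independent sliding-window seed-site scan with class assignment."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def rc(s: str) -> str:
        return "".join(comp[c] for c in reversed(s))

    out = set()
    for mid, mature in matures.items():
        mature = mature.upper().replace("U", "T")
        seed = mature[1:7]
        probe = rc(seed)
        for tid, utr in utrs.items():
            utr = utr.upper().replace("U", "T")
            for i in range(len(utr) - 5):
                if utr[i : i + 6] != probe:
                    continue
                pos = i + 1
                if pos < end_exclusion:
                    continue
                m8 = (
                    i > 0
                    and len(mature) >= 8
                    and utr[i - 1] == comp[mature[7]]
                )
                a1 = i + 6 < len(utr) and utr[i + 6] == "A"
                if m8 and a1:
                    cls = "8mer"
                elif m8:
                    cls = "7mer-m8"
                elif a1:
                    cls = "7mer-1A"
                else:
                    cls = "6mer"
                out.add((mid, tid, pos, cls))
    return out


def union_find_components(
    nodes: list[str], edges: list[tuple[str, str]]
) -> list[frozenset[str]]:
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return [frozenset(c) for c in comps.values()]


def naive_quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Two-pass reference implementation (no ties in test inputs)."""
    out = np.empty_like(matrix, dtype=float)
    reference = np.sort(matrix, axis=0).mean(axis=1)
    for j in range(matrix.shape[1]):
        ranks = np.argsort(np.argsort(matrix[:, j]))
        out[:, j] = reference[ranks]
    return out
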