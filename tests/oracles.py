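"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a quantity by a route deliberately different from the
implementation it checks: hypergeometric tail by direct enumeration,
quadruplex classification by recursive tract placement (no regex), interval
merging by union-find and by sweep, coverage by naive stabbing, OLS by the
normal equations, and the Alexander-Govern statistic from its published
formula.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Exact one-sided 2x2 tail by hypergeometric enumeration
# ---------------------------------------------------------------------------


def hypergeom_tail(sK: int, nK: int, sLi: int, nLi: int) -> float:
    """P(X >= sK) for X ~ Hypergeom(N=nK+nLi, K=sK+sLi, n=nK), by direct
    summation of binomial-coefficient terms."""
    N = nK + nLi
    K = sK + sLi
    denom = math.comb(N, nK)
    lo = max(0, K - nLi)
    hi = min(K, nK)
    total = 0
    for x in range(sK, hi + 1):
        if x < lo:
            continue
        total += math.comb(K, x) * math.comb(N - K, nK - x)
    return total / denom


# ---------------------------------------------------------------------------
# Quadruplex class by recursive tract placement (no regex)
# ---------------------------------------------------------------------------


def _match_segments(seq: str, end: int, segments: list[tuple]) -> bool:
    """Can ``segments`` (5'->3' order) tile ``seq`` ending exactly at ``end``
    (exclusive), starting anywhere?  Each segment is one of
    ('G', gmin), ('L', lo, hi) or ('B', bulge_lo, bulge_hi)."""

    def rec(pos: int, idx: int) -> bool:
        # match segments from the 3' end backwards; pos = exclusive end
        if idx < 0:
            return True
        seg = segments[idx]
        if seg[0] == "G":
            gmin = seg[1]
            g = 0
            while pos - g - 1 >= 0 and seq[pos - g - 1] == "G":
                g += 1
            for take in range(gmin, g + 1):
                if rec(pos - take, idx - 1):
                    return True
            return False
        if seg[0] == "L":
            lo, hi = seg[1], seg[2]
            for take in range(lo, hi + 1):
                if pos - take < 0:
                    break
                if rec(pos - take, idx - 1):
                    return True
            return False
        if seg[0] == "B":
            lo, hi = seg[1], seg[2]
            # bulged tract: g1 Gs + non-G bulge + g2 Gs, g1+g2 >= 3,
            # each part 1..2 Gs
            for g2 in (1, 2):
                for blen in range(lo, hi + 1):
                    for g1 in (1, 2):
                        if g1 + g2 < 3:
                            continue
                        total = g1 + blen + g2
                        if pos - total < 0:
                            continue
                        s = seq[pos - total : pos]
                        if (
                            s[:g1] == "G" * g1
                            and s[g1 + blen :] == "G" * g2
                            and all(c in "ACT" for c in s[g1 : g1 + blen])
                            and rec(pos - total, idx - 1)
                        ):
                            return True
            return False
        raise AssertionError(seg)

    return rec(end, len(segments) - 1)


def brute_force_class(seq: str, anchor: int) -> str | None:
    """Highest-priority quadruplex/triplex class whose pattern's 3' end lies
    at ``anchor`` (inclusive), window and parameters at their defaults."""
    if anchor < 0 or anchor >= len(seq) or seq[anchor] != "G":
        return None
    lo = max(0, anchor - 50 + 1)
    window = seq[lo : anchor + 1]
    end = len(window)
    G3, L, LL, B = ("G", 3), ("L", 1, 7), ("L", 8, 12), ("B", 1, 7)
    G2 = ("G", 2)
    if _match_segments(window, end, [G3, L, G3, L, G3, L, G3]):
        return "canonical"
    for j in range(3):
        loops = [LL if i == j else L for i in range(3)]
        if _match_segments(window, end, [G3, loops[0], G3, loops[1], G3, loops[2], G3]):
            return "long_loop"
    for j in range(4):
        segs: list[tuple] = []
        for i in range(4):
            segs.append(B if i == j else G3)
            if i < 3:
                segs.append(L)
        if _match_segments(window, end, segs):
            return "bulge"
    if _match_segments(window, end, [G2, L, G2, L, G2, L, G2]):
        return "two_quartet"
    if _match_segments(window, end, [G3, L, G3, L, G3]):
        return "g_triplex"
    return None


# ---------------------------------------------------------------------------
# Interval oracles
# ---------------------------------------------------------------------------


def union_find_merge(positions: Sequence[int], gap: int) -> list[list[int]]:
    """Group positions whose pairwise chain distance is <= gap, by union-find."""
    pos = sorted(set(positions))
    parent = list(range(len(pos)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            if pos[j] - pos[i] <= gap:
                parent[find(j)] = find(i)
    groups: dict[int, list[int]] = {}
    for i, p in enumerate(pos):
        groups.setdefault(find(i), []).append(p)
    return sorted(groups.values())


def sweep_merge(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/bookended half-open intervals by sweep."""
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def naive_coverage(reads: Sequence[tuple[int, int]], length: int) -> np.ndarray:
    """O(n*L) interval stabbing count."""
    cov = np.zeros(length, dtype=int)
    for s, e in reads:
        for i in range(s, e):
            cov[i] += 1
    return cov


# ---------------------------------------------------------------------------
# Regression and Alexander-Govern
# ---------------------------------------------------------------------------


def ols_normal_equations(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and intercept by solving X'X b = X'y directly."""
    X = np.column_stack([np.ones_like(x), x])
    b = np.linalg.solve(X.T @ X, X.T @ y)
    return float(b[1]), float(b[0])


def alexander_govern_stat(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Alexander-Govern statistic and chi-square p from the published
    normalising transformation of one-sample t values."""
    from scipy.stats import chi2

    means = [np.mean(g) for g in groups]
    ses = [np.std(g, ddof=1) / math.sqrt(len(g)) for g in groups]
    w = np.array([1 / s**2 for s in ses])
    w = w / w.sum()
    grand = float(np.sum(w * np.array(means)))
    A = 0.0
    for g, m, se in zip(groups, means, ses):
        t = (m - grand) / se
        nu = len(g) - 1
        a = nu - 0.5
        b = 48 * a**2
        c = math.sqrt(a * math.log(1 + t * t / nu))
        z = c + (c**3 + 3 * c) / b - (
            4 * c**7 + 33 * c**5 + 240 * c**3 + 855 * c
        ) / (10 * b**2 + 8 * b * c**4 + 1000 * b)
        A += z * z
    p = float(chi2.sf(A, len(groups) - 1))
    return float(A), p
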