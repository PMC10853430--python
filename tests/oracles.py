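"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: the enumeration
oracles walk the full (C, H, O, N, S) lattice directly instead of solving
for H, and the Spearman oracle evaluates the permutation null by direct
enumeration of rank pairings.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# Same physical constants; the *algorithm* is what must be independent.
MC, MH, MO, MN, MS = 12.0, 1.00782503207, 15.99491461956, 14.0030740048, 31.97207100


def valid_slow(c: int, h: int, o: int, n: int, s: int) -> bool:
    if c < 1 or h < 1:
        return False
    if h / c >= 2.4 or o / c >= 1.2:
        return False
    d = 1.0 + c - h / 2.0 + n / 2.0
    if d < 0 or d != math.floor(d):
        return False
    return h <= 2 * c + n + 2


def enumerate_slow(
    neutral_mass: float,
    tol_ppm: float = 1.0,
    max_c: int = 60,
    max_h: int = 122,
    max_o: int = 40,
    max_n: int = 3,
    max_s: int = 1,
) -> set[tuple[int, int, int, int, int]]:
    """Pure-Python quintuple loop; only usable at small bounds."""
    tol = neutral_mass * tol_ppm * 1e-6
    out = set()
    for c in range(1, max_c + 1):
        for h in range(1, max_h + 1):
            for o in range(0, max_o + 1):
                for n in range(0, max_n + 1):
                    for s in range(0, max_s + 1):
                        m = c * MC + h * MH + o * MO + n * MN + s * MS
                        if abs(m - neutral_mass) <= tol and valid_slow(c, h, o, n, s):
                            out.add((c, h, o, n, s))
    return out


class GridOracle:
    """Exhaustive vectorized lattice: every (C,H,O,N,S) tuple tabulated once.

    Unlike the implementation, H is a full grid axis — no solving, no
    searching; a query is a plain |mass - M| <= tol scan over ~2.3e6
    pre-validated tuples.
    """

    def __init__(self, max_c=60, max_h=122, max_o=40, max_n=3, max_s=1):
        c, h, o, n, s = np.meshgrid(
            np.arange(1, max_c + 1, dtype=np.int32),
            np.arange(1, max_h + 1, dtype=np.int32),
            np.arange(0, max_o + 1, dtype=np.int32),
            np.arange(0, max_n + 1, dtype=np.int32),
            np.arange(0, max_s + 1, dtype=np.int32),
            indexing="ij",
        )
        c, h, o, n, s = (a.ravel() for a in (c, h, o, n, s))
        d = 1.0 + c - h / 2.0 + n / 2.0
        ok = (
            (h / c < 2.4)
            & (o / c < 1.2)
            & (d >= 0)
            & (d == np.floor(d))
            & (h <= 2 * c + n + 2)
        )
        self.c, self.h, self.o, self.n, self.s = c[ok], h[ok], o[ok], n[ok], s[ok]
        self.mass = (
            self.c * MC + self.h * MH + self.o * MO + self.n * MN + self.s * MS
        )

    def query(self, neutral_mass: float, tol_ppm: float = 1.0) -> set[tuple]:
        tol = neutral_mass * tol_ppm * 1e-6
        hit = np.abs(self.mass - neutral_mass) <= tol
        return {
            (int(a), int(b), int(cc), int(d), int(e))
            for a, b, cc, d, e in zip(
                self.c[hit], self.h[hit], self.o[hit], self.n[hit], self.s[hit]
            )
        }


def spearman_exact_oracle(x, y) -> tuple[float, float]:
    """Spearman rho and exact two-sided permutation p by direct enumeration."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b) / math.sqrt(float(a @ a) * float(b @ b))

    rho = corr(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(corr(rx, np.array(perm))) >= abs(rho) - 1e-12:
            count += 1
    return rho, count / total
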