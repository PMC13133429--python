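"""Shared fixtures: synthetic chains and independent test oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ssesym import FixtureSpec, make_chain

# six alternating elements with distinct lengths -> distinct tokens,
# equal-residue halves when cut at SSE index 3 (36 + 36 residues)
EQUAL_HALF_ELEMENTS = [
    ("helix", 10), ("strand", 5), ("helix", 9),
    ("strand", 9), ("helix", 10), ("strand", 9),
]


@pytest.fixture
def equal_half_chain():
    return make_chain(FixtureSpec(seed=11, elements=EQUAL_HALF_ELEMENTS, linker_length=4))


@pytest.fixture
def helix12():
    return make_chain(FixtureSpec(seed=2, elements=[("helix", 12)], linker_length=0))


@pytest.fixture
def strand8():
    return make_chain(FixtureSpec(seed=2, elements=[("strand", 8)], linker_length=0))


def sw_oracle_enumerate(q, t, matrix) -> float:
    """Best local-alignment score by exhaustive enumeration of every
    monotone match/gap-run path (independent of the DP implementation).

    Alignments start and end with a match; gap runs are charged
    open-for-first plus extend-for-each-subsequent skipped token, using the
    per-class penalty of each skipped token.
    """
    n, m = len(q), len(t)
    best = 0.0

    def gap_cost(tokens, a, g):
        # skip tokens[a .. a+g-1]
        o0, _ = matrix.gap_for(tokens[a])
        cost = o0
        for x in range(1, g):
            _, e = matrix.gap_for(tokens[a + x])
            cost += e
        return cost

    def rec(i, j, score):
        nonlocal best
        best = max(best, score)
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, score + matrix.score(q[i + 1], t[j + 1]))
        # skip g query tokens, then match
        for g in range(1, n - i - 1):
            if j + 1 < m:
                rec(
                    i + g + 1,
                    j + 1,
                    score
                    + gap_cost(q, i + 1, g)
                    + matrix.score(q[i + g + 1], t[j + 1]),
                )
        # skip g target tokens, then match
        for g in range(1, m - j - 1):
            if i + 1 < n:
                rec(
                    i + 1,
                    j + g + 1,
                    score
                    + gap_cost(t, j + 1, g)
                    + matrix.score(q[i + 1], t[j + g + 1]),
                )

    for i0 in range(n):
        for j0 in range(m):
            rec(i0, j0, matrix.score(q[i0], t[j0]))
    return best


def quaternion_superpose_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-superposition RMSD via the quaternion eigenvalue method
    (Kearsley), independent of the SVD-based Kabsch implementation."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    xm, ym, zm = (b - a).T
    xp, yp, zp = (b + a).T
    k = np.empty((4, 4))
    k[0, 0] = np.sum(xm**2 + ym**2 + zm**2)
    k[0, 1] = k[1, 0] = np.sum(yp * zm - ym * zp)
    k[0, 2] = k[2, 0] = np.sum(xm * zp - xp * zm)
    k[0, 3] = k[3, 0] = np.sum(xp * ym - xm * yp)
    k[1, 1] = np.sum(yp**2 + zp**2 + xm**2)
    k[1, 2] = k[2, 1] = np.sum(xm * ym - xp * yp)
    k[1, 3] = k[3, 1] = np.sum(xm * zm - xp * zp)
    k[2, 2] = np.sum(xp**2 + zp**2 + ym**2)
    k[2, 3] = k[3, 2] = np.sum(ym * zm - yp * zp)
    k[3, 3] = np.sum(xp**2 + yp**2 + zm**2)
    lam = np.linalg.eigvalsh(k)[0]
    return float(np.sqrt(max(lam, 0.0) / len(a)))
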