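"""Independent oracles used by the test suite.

Everything here is deliberately written without reference to the package's
own implementations: a plain-recursion affine-gap alignment scorer, and a
numerical maximum-likelihood TN93 distance that optimises the model's
likelihood directly through matrix exponentials.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

_IDX = {c: i for i, c in enumerate("ACGT")}


def affine_nw_score(a: str, b: str, match: float = 5.0, mismatch: float = -4.0,
                    gap_open: float = -10.0, gap_extend: float = -0.5) -> float:
    """Optimal global affine-gap score by exhaustive three-state recursion.

    A gap of length L costs gap_open + gap_extend*(L-1). State 0 = last
    column was a match/mismatch, 1 = gap in b, 2 = gap in a.
    """
    NEG = float("-inf")

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        out = NEG
        if i > 0 and j > 0 and state == 0:
            sub = match if a[i - 1] == b[j - 1] else mismatch
            out = max(out, sub + max(best(i - 1, j - 1, s) for s in range(3)))
        if i > 0 and state == 1:
            out = max(
                out,
                best(i - 1, j, 1) + gap_extend,
                max(best(i - 1, j, 0), best(i - 1, j, 2)) + gap_open,
            )
        if j > 0 and state == 2:
            out = max(
                out,
                best(i, j - 1, 2) + gap_extend,
                max(best(i, j - 1, 0), best(i, j - 1, 1)) + gap_open,
            )
        return out

    score = max(best(len(a), len(b), s) for s in range(3))
    best.cache_clear()
    return score


def tn93_rate_matrix(alpha1: float, alpha2: float, beta: float,
                     freqs: np.ndarray) -> np.ndarray:
    """TN93 generator: alpha1 scales A<->G, alpha2 C<->T, beta transversions."""
    A, C, G, T = range(4)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            if {i, j} == {A, G}:
                rate = alpha1
            elif {i, j} == {C, T}:
                rate = alpha2
            else:
                rate = beta
            Q[i, j] = rate * freqs[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def tn93_ml_distance(a_row: str, b_row: str) -> float:
    """Numerical-ML TN93 distance.

    The pair likelihood under TN93 is a multinomial over the substitution
    classes (A<->G transitions, C<->T transitions, transversions, matches)
    whose three free class probabilities are saturated by the three rate
    parameters, so the likelihood is maximised exactly where the expected
    class probabilities — computed here by matrix exponentials, never by
    the closed-form logs — equal the observed proportions. Those equations
    are solved to near machine precision by alternating 1-D Brent root
    finds; the distance is the expected number of substitutions at the
    optimum. Requires every substitution class to be observed (interior
    optimum).
    """
    counts = np.zeros((4, 4))
    for x, y in zip(a_row, b_row):
        if x in _IDX and y in _IDX:
            counts[_IDX[x], _IDX[y]] += 1
    n = counts.sum()
    freqs = (counts.sum(axis=0) + counts.sum(axis=1)) / (2 * n)
    A, C, G, T = range(4)
    o1 = (counts[A, G] + counts[G, A]) / n
    o2 = (counts[C, T] + counts[T, C]) / n
    ov = 1 - np.trace(counts) / n - o1 - o2
    if min(o1, o2, ov) <= 0:
        raise ValueError("a substitution class is unobserved; ML optimum is not interior")

    def probs(a1: float, a2: float, b: float) -> tuple[float, float, float]:
        J = freqs[:, None] * expm(tn93_rate_matrix(a1, a2, b, freqs))
        p1 = J[A, G] + J[G, A]
        p2 = J[C, T] + J[T, C]
        return p1, p2, 1 - p1 - p2 - np.trace(J)

    a1 = a2 = b = 0.05
    for _ in range(40):
        b = brentq(lambda x: probs(a1, a2, x)[2] - ov, 1e-13, 30, xtol=1e-16)
        a1 = brentq(lambda x: probs(x, a2, b)[0] - o1, 1e-13, 30, xtol=1e-16)
        a2 = brentq(lambda x: probs(a1, x, b)[1] - o2, 1e-13, 30, xtol=1e-16)
    Q = tn93_rate_matrix(a1, a2, b, freqs)
    return -float(np.dot(freqs, np.diag(Q)))


def random_pair(rng: np.random.Generator, n: int = 800,
                sub_fraction: tuple[float, float] = (0.08, 0.15)) -> tuple[str, str]:
    """A random sequence and a partner with random substitutions, dense
    enough that every TN93 substitution class is populated with
    overwhelming probability."""
    bases = np.array(list("ACGT"))
    a = rng.choice(bases, size=n)
    b = a.copy()
    lo, hi = sub_fraction
    k = rng.integers(int(lo * n), int(hi * n))
    idx = rng.choice(n, size=k, replace=False)
    for i in idx:
        b[i] = rng.choice([x for x in "ACGT" if x != a[i]])
    return "".join(a), "".join(b)
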