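"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: Bayes factors and
posteriors are computed with 200-digit ``decimal`` arithmetic and
explicit configuration enumeration; hypergeometric tails with exact
``fractions`` sums. They exist so the fast log-space implementations can
be checked against slow, transparent arithmetic.
"""

from __future__ import annotations

import math
from decimal import Decimal, getcontext
from fractions import Fraction

getcontext().prec = 200


def dec_log_abf(beta: float, se: float, W: float) -> Decimal:
    """Wakefield log approximate Bayes factor in 200-digit arithmetic."""
    V = Decimal(se) ** 2
    W2 = Decimal(W) ** 2
    z2 = (Decimal(beta) / Decimal(se)) ** 2
    return (Decimal(0.5)) * ((V / (V + W2)).ln() + z2 * W2 / (V + W2))


def dec_credible_set(betas, ses, W) -> list[float]:
    """Single-causal posteriors by direct exponentiation and normalisation."""
    bfs = [dec_log_abf(b, s, W).exp() for b, s in zip(betas, ses)]
    total = sum(bfs)
    return [float(bf / total) for bf in bfs]


def dec_coloc(betas1, ses1, betas2, ses2, p1, p2, p12, W1, W2) -> list[float]:
    """Five-hypothesis posterior by brute-force configuration enumeration.

    Enumerates every single-causal configuration of both traits over the
    shared variants: H1/H2 sum each trait's Bayes factors, H3 sums the
    explicit (i, j), i != j pairs, H4 the diagonal.
    """
    bf1 = [dec_log_abf(b, s, W1).exp() for b, s in zip(betas1, ses1)]
    bf2 = [dec_log_abf(b, s, W2).exp() for b, s in zip(betas2, ses2)]
    P1, P2, P12 = Decimal(p1), Decimal(p2), Decimal(p12)
    m = len(bf1)
    L0 = Decimal(1)
    L1 = P1 * sum(bf1)
    L2 = P2 * sum(bf2)
    L3 = P1 * P2 * sum(bf1[i] * bf2[j] for i in range(m) for j in range(m) if i != j)
    L4 = P12 * sum(bf1[j] * bf2[j] for j in range(m))
    total = L0 + L1 + L2 + L3 + L4
    return [float(L / total) for L in (L0, L1, L2, L3, L4)]


def pics_oracle(S: float, rs) -> list[float]:
    """Independent transcription of the PICS weighting."""
    weights = []
    for r in rs:
        mu = r * r * S
        sigma = max(1e-4, math.sqrt(1.0 - abs(r) ** 3.2) * math.sqrt(S) / 2.0)
        weights.append(math.exp(-((S - mu) ** 2) / (2 * sigma * sigma)) / sigma)
    total = sum(weights)
    return [w / total for w in weights]


def hypergeom_upper_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact P(X >= a) for the 2x2 table's hypergeometric null."""
    N, K, n = a + b + c + d, a + b, a + c
    denom = math.comb(N, n)
    total = Fraction(0)
    for x in range(a, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return total


def enrichment_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) for hypergeometric gene-set enrichment."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return total


def bh_stepup(pvalues) -> list[float]:
    """Hand step-up Benjamini-Hochberg with monotonicity enforcement."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvalues[i] * m / rank_from_top)
        adj[i] = running_min
    return adj
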