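"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the library's own code paths: exact-fraction
hypergeometric enumeration for the two-sided Fisher test, a literal
step-up loop for Benjamini-Hochberg, a pooled-count binomial LRT, and an
exhaustive substring-pair enumerator for inverted repeats.
"""

import math
from fractions import Fraction
from math import comb

from scipy import stats as sps

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq.upper().replace("U", "T")))


def fisher_enumeration_p(table):
    """Two-sided Fisher p by enumerating all tables with fixed margins and
    summing exact hypergeometric probabilities <= that of the observed."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    probs = []
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs.append((x, Fraction(comb(r1, x) * comb(r2, c1 - x), denom)))
    p_obs = dict(probs)[a]
    return float(sum(p for _, p in probs if p <= p_obs))


def bh_bruteforce(p):
    """Literal step-up definition of BH adjusted p-values."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return [min(1.0, a) for a in adj]


def binomial_lrt_p(group_a, group_b):
    """Binomial likelihood-ratio test on pooled (variant, ref) counts."""
    ka = sum(v for v, _ in group_a); na = sum(v + r for v, r in group_a)
    kb = sum(v for v, _ in group_b); nb = sum(v + r for v, r in group_b)

    def ll(k, n, p):
        if p <= 0 or p >= 1:
            return 0.0 if k in (0, n) else -math.inf
        return k * math.log(p) + (n - k) * math.log(1 - p)

    p0 = (ka + kb) / (na + nb)
    stat = 2 * (ll(ka, na, ka / na) + ll(kb, nb, kb / nb)
                - ll(ka, na, p0) - ll(kb, nb, p0))
    return float(sps.chi2.sf(max(stat, 0.0), 1))


def brute_force_max_arm(seq, min_arm=3, max_arm=10):
    """Exhaustive enumeration of every (left, right) substring pair with the
    left arm fully 5' of the center, the right arm fully 3' of it, and
    right = revcomp(left); returns the maximal arm length (0 if none)."""
    seq = seq.upper().replace("U", "T")
    c = len(seq) // 2
    best = 0
    for arm in range(min_arm, max_arm + 1):
        for i in range(0, len(seq)):
            left = seq[i:i + arm]
            if len(left) < arm or i + arm - 1 > c - 1:
                continue
            for j in range(c + 1, len(seq)):
                right = seq[j:j + arm]
                if len(right) < arm:
                    continue
                if right == oracle_revcomp(left):
                    best = max(best, arm)
    return best
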