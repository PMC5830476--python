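"""Independent brute-force oracles used only by the test suite."""

from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_tail_p(k_pos: int, n_pos: int, k_neg: int, n_neg: int) -> Fraction:
    """Exact one-sided Fisher p by hypergeometric tail summation.

    P(X >= k_pos) for X ~ Hypergeom(N=n_pos+n_neg, K=k_pos+k_neg, n=n_pos),
    as an exact rational number.
    """
    n_total = n_pos + n_neg
    k_total = k_pos + k_neg
    denom = comb(n_total, n_pos)
    tail = sum(
        comb(k_total, x) * comb(n_total - k_total, n_pos - x)
        for x in range(k_pos, min(k_total, n_pos) + 1)
    )
    return Fraction(tail, denom)


def concordance_auc(scores, labels) -> float:
    """O(n²) pairwise concordance with 0.5 tie credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
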