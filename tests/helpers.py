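"""Independent oracles used by the test suite.

Each oracle re-derives an expected result by a route independent of the
implementation it checks: exhaustive enumeration for clumping, weighted
least squares via a generic linear solver for IVW, plain-space summation
for colocalization, and exact conditional (noncentral hypergeometric)
estimation for 2x2 odds ratios.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def clump_oracle(pvals, positions, ids, r2_matrix, clump_r2):
    """Lexicographically-first maximal independent set under the p ordering.

    Enumerates every subset of variants, keeps those whose retained pairs all
    have r-squared below the threshold and that are maximal (no variant can
    be added without violating the threshold), and returns the one whose
    tuple of p-ranks is lexicographically smallest.  This is the defining
    property of greedy p-ordered clumping, derived without running it.
    """
    n = len(pvals)
    order = sorted(range(n), key=lambda i: (pvals[i], positions[i], ids[i]))
    rank = {v: k for k, v in enumerate(order)}
    conflict = np.asarray(r2_matrix) >= clump_r2
    np.fill_diagonal(conflict, False)

    valid = []
    for size in range(n + 1):
        for subset in itertools.combinations(range(n), size):
            ok = all(
                not conflict[i, j] for i, j in itertools.combinations(subset, 2)
            )
            if ok:
                valid.append(frozenset(subset))
    valid_set = set(valid)
    maximal = [
        s
        for s in valid
        if not any((s | {v}) in valid_set for v in range(n) if v not in s)
    ]
    best = min(maximal, key=lambda s: tuple(sorted(rank[v] for v in s)))
    return sorted(best, key=lambda v: rank[v])


def wls_origin_oracle(bx, by, sy):
    """Slope of the SE-weighted zero-intercept regression of by on bx,
    via a generic least-squares solve rather than the IVW closed form."""
    w = 1.0 / np.asarray(sy)
    design = (np.asarray(bx) * w)[:, None]
    target = np.asarray(by) * w
    slope, *_ = np.linalg.lstsq(design, target, rcond=None)
    return float(slope[0])


def coloc_enum_oracle(b1, s1, b2, s2, w1, w2, priors):
    """Posterior hypothesis probabilities by direct plain-space enumeration
    of every causal-variant configuration (feasible for small z, few SNPs)."""
    p1, p2, p12 = priors

    def abf(b, s, w):
        k = w / (w + s**2)
        z = b / s
        return np.sqrt(1.0 - k) * np.exp(k * z**2 / 2.0)

    a1 = np.array([abf(b, s, w1) for b, s in zip(b1, s1)])
    a2 = np.array([abf(b, s, w2) for b, s in zip(b2, s2)])
    n = len(a1)
    terms = {
        "H0": 1.0,
        "H1": p1 * a1.sum(),
        "H2": p2 * a2.sum(),
        "H3": p1 * p2 * sum(a1[i] * a2[j] for i in range(n) for j in range(n) if i != j),
        "H4": p12 * float(np.sum(a1 * a2)),
    }
    total = sum(terms.values())
    return {h: v / total for h, v in terms.items()}


def exact_conditional(table):
    """Exact conditional (noncentral hypergeometric) odds-ratio estimate and
    95% CI of a 2x2 table, via scipy's Fisher conditional machinery.

    The conditional MLE is degenerate (0 or inf) when a cell is zero, but
    the exact CI stays informative, so the check against the corrected
    Woolf estimate is containment plus sign agreement.
    """
    res = stats.contingency.odds_ratio(np.asarray(table, dtype=int), kind="conditional")
    ci = res.confidence_interval(0.95)
    return res.statistic, (ci.low, ci.high)


def woolf_se(table):
    """Analytic Woolf SE of a 2x2 log odds ratio."""
    cells = np.asarray(table, dtype=float).ravel()
    return float(np.sqrt(np.sum(1.0 / cells)))
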