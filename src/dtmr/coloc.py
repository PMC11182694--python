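"""Single-causal-variant Bayesian colocalization of two traits over a region.

Tests whether two association signals in the same gene region are consistent
with a single shared causal variant.  Per-variant evidence is the Wakefield
approximate Bayes factor computed from each trait's beta/SE; hypothesis
posteriors are accumulated in log space:

* H0 — no association with either trait
* H1 / H2 — association with trait 1 / trait 2 only
* H3 — both traits associated, distinct causal variants (LD confounding)
* H4 — both traits associated, one shared causal variant

Priors default to the field-standard p1 = p2 = 1e-4 (a variant is causal for
one trait) and p12 = 1e-5 (causal for both); the Gaussian effect prior
variance W defaults to 0.15^2 for quantitative traits and 0.2^2 on the
log-OR scale for binary traits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .instruments import GeneRegion
from .sumstats import AssociationRecord

logger = logging.getLogger(__name__)

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)
W_QUANTITATIVE = 0.15**2
W_BINARY = 0.2**2


@dataclass(frozen=True)
class ColocResult:
    pp: dict[str, float]
    n_variants: int
    priors: tuple[float, float, float]
    h4_variant_weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")
        if any(p < 0 for p in self.pp.values()):
            raise ValueError("negative posterior probability")

    @property
    def argmax(self) -> str:
        return max(self.pp, key=self.pp.get)

    def summary_row(self) -> dict:
        row = {"n_variants": self.n_variants}
        row.update({f"PP.{h}": self.pp[h] for h in HYPOTHESES})
        row["argmax"] = self.argmax
        return row


def log_abf(beta: float | np.ndarray, se: float | np.ndarray, w: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor for association vs null.

    ``ABF = sqrt(1 - K) * exp(K z^2 / 2)`` with shrinkage ``K = W/(W + se^2)``
    and ``z = beta/se``; evaluated in logs for numerical range.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    k = w / (w + se**2)
    z = beta / se
    return 0.5 * (np.log1p(-k) + k * z**2)


def _log_diff_exp(log_a: float, log_b: float) -> float:
    """log(exp(log_a) - exp(log_b)) for log_a >= log_b, -inf if equal."""
    if log_b == -math.inf:
        return log_a
    d = log_b - log_a
    if d >= 0:
        return -math.inf
    return log_a + math.log1p(-math.exp(d))


def colocalize(
    trait1: Iterable[AssociationRecord],
    trait2: Iterable[AssociationRecord],
    region: GeneRegion | None = None,
    priors: tuple[float, float, float] = DEFAULT_PRIORS,
    w1: float = W_QUANTITATIVE,
    w2: float = W_QUANTITATIVE,
) -> ColocResult:
    """Colocalize two traits' summary statistics over a padded gene region.

    Restricts to variants shared between the traits (and inside the region's
    colocalization window, when given), drops rows with non-positive SE with
    a log entry, computes per-variant log-ABFs for each trait, and returns
    normalized posteriors over H0..H4 together with the per-variant posterior
    weight of being the shared causal variant under H4.
    """
    p1, p2, p12 = priors
    if min(p1, p2, p12) <= 0:
        raise ValueError("coloc priors must be positive")

    def usable(recs):
        out = {}
        for r in recs:
            v = r.variant
            if region is not None and not region.contains(v.chrom, v.pos, pad="coloc"):
                continue
            if r.se <= 0:
                logger.warning("coloc: %s dropped (se <= 0)", v.id)
                continue
            out[v.id] = r
        return out

    d1, d2 = usable(trait1), usable(trait2)
    shared = [vid for vid in d1 if vid in d2]
    if not shared:
        raise ValueError("colocalize: zero shared variants in the region")

    b1 = np.array([d1[v].beta for v in shared])
    s1 = np.array([d1[v].se for v in shared])
    b2 = np.array([d2[v].beta for v in shared])
    s2 = np.array([d2[v].se for v in shared])

    l1 = log_abf(b1, s1, w1)
    l2 = log_abf(b2, s2, w2)

    sum1 = float(logsumexp(l1))            # sum_i ABF1_i
    sum2 = float(logsumexp(l2))            # sum_j ABF2_j
    sum12 = float(logsumexp(l1 + l2))      # sum_i ABF1_i ABF2_i
    # H3 excludes the shared-variant diagonal: sum_{i != j} ABF1_i ABF2_j
    sum3 = _log_diff_exp(sum1 + sum2, sum12)

    log_weights = np.array(
        [
            0.0,
            math.log(p1) + sum1,
            math.log(p2) + sum2,
            math.log(p1) + math.log(p2) + sum3,
            math.log(p12) + sum12,
        ]
    )
    log_norm = logsumexp(log_weights)
    pp = np.exp(log_weights - log_norm)
    pp = pp / pp.sum()

    h4_logw = l1 + l2
    h4_w = np.exp(h4_logw - logsumexp(h4_logw))
    return ColocResult(
        pp={h: float(p) for h, p in zip(HYPOTHESES, pp)},
        n_variants=len(shared),
        priors=(p1, p2, p12),
        h4_variant_weights={v: float(w) for v, w in zip(shared, h4_w)},
    )
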