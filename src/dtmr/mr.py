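"""Mendelian randomization estimators.

Implements the single-variant Wald ratio, fixed- and random-effects
inverse-variance weighted (IVW) estimation, and the generalized-least-squares
IVW (GLS-IVW) that corrects for linkage-disequilibrium correlation between
cis instruments, plus the effect-rescaling utilities used to translate
per-exposure-unit odds ratios.

Conventions
-----------
* The causal estimate is in outcome units per exposure unit (log odds ratio
  per unit for binary outcomes); ``MRResult.odds_ratio`` re-exponentiates.
* The Wald SE is first order, ``se_outcome / |beta_exposure|``, ignoring
  exposure-side uncertainty: standard practice and conservative for the
  strong instruments that pass genome-wide significance.
* GLS uses the outcome-SE-only covariance ``Omega_ij = sy_i sy_j r_ij``
  (exposure effects treated as fixed) — the standard correlated-instrument
  IVW weighting.
* Random-effects IVW applies multiplicative overdispersion: the fixed SE is
  scaled by ``max(1, sqrt(Q / (k - 1)))`` and never shrinks below fixed.
* When a Bonferroni multiplicity divisor ``m`` is attached, confidence
  intervals are reported at level ``1 - 0.05/m``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MAX_CONDITION_NUMBER = 1e8


@dataclass(frozen=True)
class MRResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    method: str
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    multiplicity_m: int = 1
    condition_number: float | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("MRResult se must be > 0")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("MRResult CI must bracket the estimate")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)

    def summary_row(self) -> dict:
        return {
            "method": self.method,
            "n_snps": self.n_snps,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci[0],
            "or_ci_high": self.or_ci[1],
            "pvalue": self.pvalue,
            "q_stat": self.q_stat,
            "q_pvalue": self.q_pvalue,
            "multiplicity_m": self.multiplicity_m,
        }


def _finish(estimate: float, se: float, *, n_snps: int, method: str, m: int = 1, **kw) -> MRResult:
    z = estimate / se
    pvalue = float(min(1.0, max(np.nextafter(0, 1), 2.0 * stats.norm.sf(abs(z)))))
    crit = stats.norm.ppf(1.0 - 0.05 / (2.0 * m))
    return MRResult(
        estimate=float(estimate),
        se=float(se),
        ci_low=float(estimate - crit * se),
        ci_high=float(estimate + crit * se),
        pvalue=pvalue,
        n_snps=n_snps,
        method=method,
        multiplicity_m=m,
        **kw,
    )


def wald_ratio(bx: float, sx: float, by: float, sy: float, *, m: int = 1) -> MRResult:
    """Single-instrument causal estimate ``by / bx`` with first-order SE.

    ``sx`` is accepted for interface completeness but does not enter the
    first-order SE.
    """
    if bx == 0:
        raise ValueError("wald_ratio: exposure beta is zero (weak/undefined instrument)")
    if sy <= 0:
        raise ValueError("wald_ratio: outcome se must be > 0")
    return _finish(by / bx, sy / abs(bx), n_snps=1, method="wald_ratio", m=m)


def _extract_arrays(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Accept an InstrumentSet or a (bx, sx, by, sy) tuple of arrays."""
    if hasattr(instruments, "exposure_beta"):
        bx = np.asarray(instruments.exposure_beta, dtype=float)
        sx = np.asarray(instruments.exposure_se, dtype=float)
        by = np.asarray(instruments.outcome_beta, dtype=float)
        sy = np.asarray(instruments.outcome_se, dtype=float)
    else:
        bx, sx, by, sy = (np.asarray(a, dtype=float) for a in instruments)
    if by is None or np.isnan(by).any():
        raise ValueError("instruments carry no outcome effects; harmonize first")
    if bx.shape != by.shape or bx.shape != sy.shape:
        raise ValueError("instrument arrays must share a common length")
    if bx.size == 0:
        raise ValueError("no instruments")
    if (sy <= 0).any():
        raise ValueError("outcome se must be > 0")
    if (bx == 0).any():
        raise ValueError("exposure beta of zero among instruments")
    return bx, sx, by, sy


def ivw(instruments, effects_model: str = "fixed", *, m: int = 1) -> MRResult:
    """Inverse-variance weighted estimator over uncorrelated instruments.

    Equivalent to the zero-intercept regression of outcome on exposure
    effects weighted by ``1/sy^2``.  ``effects_model="random"`` applies
    multiplicative overdispersion from Cochran's Q; with a single instrument
    it falls back to fixed with a warning.
    """
    if effects_model not in ("fixed", "random"):
        raise ValueError(f"unknown effects model '{effects_model}'")
    bx, sx, by, sy = _extract_arrays(instruments)
    k = bx.size
    w = bx**2 / sy**2
    estimate = float(np.sum(bx * by / sy**2) / np.sum(w))
    se_fixed = float(np.sqrt(1.0 / np.sum(w)))
    theta_i = by / bx
    q_stat = float(np.sum(w * (theta_i - estimate) ** 2))
    q_df = k - 1
    q_pvalue = float(stats.chi2.sf(q_stat, q_df)) if q_df > 0 else None

    method = f"ivw_{effects_model}"
    se = se_fixed
    if effects_model == "random":
        if k < 2:
            warnings.warn("random-effects IVW with one instrument: falling back to fixed")
            method = "ivw_fixed"
        else:
            se = se_fixed * max(1.0, math.sqrt(q_stat / q_df))
    return _finish(
        estimate, se, n_snps=k, method=method, m=m,
        q_stat=q_stat, q_df=q_df, q_pvalue=q_pvalue,
    )


def gls_ivw(instruments, ld=None, *, m: int = 1) -> MRResult:
    """LD-corrected IVW via generalized least squares.

    With exposure effects ``X``, outcome effects ``Y`` and covariance
    ``Omega_ij = sy_i sy_j r_ij`` built from the signed LD matrix, the
    estimate is ``(X' Omega^-1 X)^-1 X' Omega^-1 Y`` with SE
    ``sqrt((X' Omega^-1 X)^-1)``.  Combines the independent information of
    correlated cis instruments while keeping the SE honest about their
    LD-related correlation.  An ill-conditioned Omega (condition number
    above 1e8) raises, advising stricter clumping.
    """
    if ld is None:
        ld_obj = getattr(instruments, "ld", None)
        if ld_obj is None:
            raise ValueError("gls_ivw requires an LD matrix")
        r = ld_obj.r if hasattr(ld_obj, "r") else np.asarray(ld_obj, dtype=float)
    else:
        r = ld.r if hasattr(ld, "r") else np.asarray(ld, dtype=float)
    bx, sx, by, sy = _extract_arrays(instruments)
    k = bx.size
    if r.shape != (k, k):
        raise ValueError(f"LD matrix shape {r.shape} does not match {k} instruments")

    omega = np.outer(sy, sy) * r
    cond = float(np.linalg.cond(omega))
    logger.debug("GLS-IVW Omega condition number: %.3g", cond)
    if cond > MAX_CONDITION_NUMBER:
        raise ValueError(
            f"GLS covariance condition number {cond:.2g} > {MAX_CONDITION_NUMBER:.0e}: "
            "instruments too correlated; clump at a stricter r2 threshold"
        )
    oi_x = np.linalg.solve(omega, bx)
    oi_y = np.linalg.solve(omega, by)
    xt_oi_x = float(bx @ oi_x)
    estimate = float(bx @ oi_y) / xt_oi_x
    se = math.sqrt(1.0 / xt_oi_x)

    resid = by - estimate * bx
    q_stat = float(resid @ np.linalg.solve(omega, resid))
    q_df = k - 1
    q_pvalue = float(stats.chi2.sf(q_stat, q_df)) if q_df > 0 else None
    return _finish(
        estimate, se, n_snps=k, method="gls_ivw", m=m,
        q_stat=q_stat, q_df=q_df, q_pvalue=q_pvalue, condition_number=cond,
    )


def rescale_log_or(result: MRResult, factor: float) -> MRResult:
    """Rescale a log-OR-per-exposure-unit result to a different exposure dose.

    Multiplies the estimate, SE and CI bounds by ``factor`` on the log scale
    (the odds ratio is re-exponentiated by the ``odds_ratio`` property), e.g.
    converting an OR per mmol/L triglyceride to the OR for a given achieved
    mmol/L reduction.  Composes multiplicatively:
    ``rescale(r, a*b) == rescale(rescale(r, a), b)``.
    """
    if not factor > 0:
        raise ValueError("rescale factor must be > 0")
    return replace(
        result,
        estimate=result.estimate * factor,
        se=result.se * factor,
        ci_low=result.ci_low * factor,
        ci_high=result.ci_high * factor,
        method=f"{result.method}_rescaled",
    )


def orient_to_lowering(result: MRResult, flip: bool = True) -> MRResult:
    """Report effects per unit *lowered* exposure by negating the estimate.

    Negates the estimate and swaps/negates the CI bounds so that, e.g., a
    harmful effect of higher protein level reads as protective per s.d.
    lowered protein.  Applying the flip twice is the identity.
    """
    if not flip:
        return result
    return replace(
        result,
        estimate=-result.estimate,
        ci_low=-result.ci_high,
        ci_high=-result.ci_low,
    )
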