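"""Genetic-mimicry concordance and protein-truncating-variant meta-analysis.

Mimicry regresses a gene's protein-truncating-variant (PTV, "collapsing")
multi-trait effect profile on the common-variant MR effect profile across a
metabolite panel and reports the coefficient of determination R^2: high R^2
means the common variants mimic profound genetic inactivation and are valid
instruments for a modest knock-down of the gene.

The PTV meta-analysis pools per-study carrier log odds ratios on CAD with
fixed-effect inverse-variance weights, either per truncating allele or per
mmol/L of the allele's triglyceride effect; heterogeneity is summarized by
Cochran's Q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MimicryResult:
    r2: float
    slope: float
    intercept: float
    n_traits: int
    scale_factor: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"R^2 {self.r2} outside [0, 1]")
        if self.n_traits < 3:
            raise ValueError("mimicry needs at least 3 traits")


@dataclass(frozen=True)
class MetaStudyRecord:
    """One study's contribution to the PTV meta-analysis."""

    study: str
    log_or_per_allele: float
    se: float
    ancestry: str = "European"
    tg_effect_per_allele: float | None = None  # mmol/L per truncating allele
    tg_se: float | None = None
    genotyping: str = "sequencing"  # "sequencing" | "array"
    ncase: int | None = None
    ncontrol: int | None = None

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.study}: se must be > 0")


@dataclass(frozen=True)
class MetaResult:
    estimate: float  # pooled log-OR
    se: float
    pvalue: float
    scale: str  # "per_allele" | "per_mmol_tg"
    q_stat: float
    q_df: int
    q_pvalue: float | None
    n_studies: int
    tg_denominator_used: float | None = None
    i2: float | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.estimate)

    @property
    def ci(self) -> tuple[float, float]:
        crit = stats.norm.ppf(0.975)
        return self.estimate - crit * self.se, self.estimate + crit * self.se

    def summary_row(self) -> dict:
        lo, hi = self.ci
        return {
            "scale": self.scale,
            "n_studies": self.n_studies,
            "log_or": self.estimate,
            "se": self.se,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": math.exp(lo),
            "or_ci_high": math.exp(hi),
            "pvalue": self.pvalue,
            "q_stat": self.q_stat,
            "q_pvalue": self.q_pvalue,
            "i2": self.i2,
            "tg_denominator": self.tg_denominator_used,
        }


def mimicry(
    cv_effects: Sequence[float],
    ptv_effects: Sequence[float],
    tg_sd_effect: float = 1.0,
) -> MimicryResult:
    """Concordance R^2 between common-variant and PTV effect profiles.

    The PTV (collapsing) vector is first divided by ``tg_sd_effect`` — its
    1-s.d. effect on plasma triglycerides — to put both profiles on a
    comparable scale, then regressed on the common-variant vector by
    ordinary least squares with intercept.  The R^2 (and hence the result)
    is invariant to rescaling both vectors by a common positive constant.
    """
    cv = np.asarray(cv_effects, dtype=float)
    ptv = np.asarray(ptv_effects, dtype=float) / float(tg_sd_effect)
    if cv.shape != ptv.shape:
        raise ValueError("effect vectors must have equal length")
    n = cv.size
    if n < 3:
        raise ValueError("mimicry needs at least 3 traits")
    if np.ptp(cv) == 0:
        raise ValueError("common-variant effect vector has zero variance")
    fit = stats.linregress(cv, ptv)
    return MimicryResult(
        r2=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_traits=n,
        scale_factor=float(tg_sd_effect),
    )


def carrier_log_or(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Woolf log odds ratio and SE from a carriers/non-carriers x case/control
    2x2 table, with the Haldane–Anscombe 0.5 correction when any cell is 0.

    ``table = [[carrier_cases, carrier_controls], [noncarrier_cases,
    noncarrier_controls]]``.  A zero margin (no carriers at all, or no cases
    at all) is an error.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 count table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    if (t == 0).any():
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return log_or, se


def _ivw_pool(est: np.ndarray, se: np.ndarray) -> tuple[float, float]:
    w = 1.0 / se**2
    pooled = float(np.sum(w * est) / np.sum(w))
    return pooled, float(math.sqrt(1.0 / np.sum(w)))


def meta_fixed(
    studies: Iterable[MetaStudyRecord],
    scale: str = "per_allele",
    sequencing_only: bool = True,
) -> MetaResult:
    """Fixed-effect IVW pooling of per-study carrier log-ORs.

    ``scale="per_mmol_tg"`` first divides each study's log-OR (and SE) by
    the absolute per-allele TG effect; a study lacking its own TG effect
    uses the pooled IVW TG estimate across the studies that have one as the
    denominator.  Denominator uncertainty is ignored (first-order), so the
    per-TG SE is the per-allele SE divided by the same constant.  The
    ``sequencing_only`` filter drops array-genotyped studies before pooling,
    guarding against rare-variant genotyping error.
    """
    studies = list(studies)
    if sequencing_only:
        studies = [s for s in studies if s.genotyping == "sequencing"]
    if not studies:
        raise ValueError("no studies left to pool")
    if scale not in ("per_allele", "per_mmol_tg"):
        raise ValueError(f"unknown scale '{scale}'")

    est = np.array([s.log_or_per_allele for s in studies])
    se = np.array([s.se for s in studies])
    tg_denominator = None
    if scale == "per_mmol_tg":
        with_tg = [s for s in studies if s.tg_effect_per_allele is not None]
        if not with_tg:
            raise ValueError("per_mmol_tg scale requires at least one study with a TG effect")
        tg_est = np.array([abs(s.tg_effect_per_allele) for s in with_tg])
        tg_se = np.array(
            [s.tg_se if s.tg_se is not None else 1.0 for s in with_tg], dtype=float
        )
        tg_denominator, _ = _ivw_pool(tg_est, tg_se)
        denom = np.array(
            [
                abs(s.tg_effect_per_allele) if s.tg_effect_per_allele is not None else tg_denominator
                for s in studies
            ]
        )
        est = est / denom
        se = se / denom

    pooled, pooled_se = _ivw_pool(est, se)
    q_stat = float(np.sum((est - pooled) ** 2 / se**2))
    q_df = len(studies) - 1
    q_pvalue = float(stats.chi2.sf(q_stat, q_df)) if q_df > 0 else None
    i2 = max(0.0, (q_stat - q_df) / q_stat) if q_stat > 0 and q_df > 0 else 0.0
    z = pooled / pooled_se
    return MetaResult(
        estimate=pooled,
        se=pooled_se,
        pvalue=float(min(1.0, 2.0 * stats.norm.sf(abs(z)))),
        scale=scale,
        q_stat=q_stat,
        q_df=q_df,
        q_pvalue=q_pvalue,
        n_studies=len(studies),
        tg_denominator_used=tg_denominator,
        i2=i2,
    )
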