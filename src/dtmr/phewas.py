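"""Phenome-wide single-variant MR scanning and Bonferroni multiplicity schemes.

A phenome-wide scan runs the Wald ratio of one exposure instrument against
many disease outcomes and applies an analysis-family Bonferroni correction:
each family's divisor m is the number of outcomes times the number of
exposure genes (plus any extra models), and a row passes at p <= alpha/m.
Outcomes in which the instrument variant is absent are reported as "not
testable" rather than null, so zero-SNP rows stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from . import mr
from .sumstats import AssociationRecord


@dataclass(frozen=True)
class MultiplicityScheme:
    name: str
    n_outcomes: int
    n_exposures: int
    extra_models: int = 0

    @property
    def m(self) -> int:
        return self.n_outcomes * self.n_exposures + self.extra_models


# Analysis families and their Bonferroni divisors:
#   primary_disease: 5 disease outcomes x 3 protein exposures + 5 x 4 TG gene
#     exposures + 5 genome-wide TG models = 40
#   risk_factor: 15 x 3 = 45;  imaging: 11 x 3 = 33;  blood_chemistry: 43 x 3 = 129
#   phenome_wide: 694 x 3 = 2082;  none: uncorrected (m = 1), used for the
#     lymphadenopathy safety outcomes where false negatives are costlier.
_SCHEMES: dict[str, MultiplicityScheme] = {
    "primary_disease": MultiplicityScheme("primary_disease", 5, 3, extra_models=5 * 4 + 5),
    "risk_factor": MultiplicityScheme("risk_factor", 15, 3),
    "imaging": MultiplicityScheme("imaging", 11, 3),
    "blood_chemistry": MultiplicityScheme("blood_chemistry", 43, 3),
    "phenome_wide": MultiplicityScheme("phenome_wide", 694, 3),
    "none": MultiplicityScheme("none", 1, 1),
}


def build_scheme(name: str) -> MultiplicityScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ValueError(
            f"unknown multiplicity scheme '{name}' (choose from {sorted(_SCHEMES)})"
        ) from None


@dataclass(frozen=True)
class PhewasRow:
    phenotype_code: str
    phenotype_label: str
    cohort: str
    estimate: float
    se: float
    pvalue: float
    m: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.phenotype_code}: pvalue outside (0, 1]")
        if not self.se > 0:
            raise ValueError(f"{self.phenotype_code}: se must be > 0")

    @property
    def pass_threshold(self) -> bool:
        return self.pvalue <= self.alpha / self.m

    def summary_row(self) -> dict:
        return {
            "phenotype_code": self.phenotype_code,
            "phenotype_label": self.phenotype_label,
            "cohort": self.cohort,
            "estimate": self.estimate,
            "se": self.se,
            "pvalue": self.pvalue,
            "m": self.m,
            "pass": self.pass_threshold,
        }


def phewas_scan(
    variant_record: AssociationRecord,
    outcomes: Mapping[str, tuple[str, str, Sequence[AssociationRecord]]],
    scheme: MultiplicityScheme,
    alpha: float = 0.05,
) -> tuple[list[PhewasRow], list[str]]:
    """Wald-ratio MR of one exposure instrument against many outcomes.

    ``outcomes`` maps phenotype code -> (label, cohort, outcome records).
    Returns rows sorted by ascending p together with the list of phenotype
    codes where the instrument variant was absent ("not testable").
    """
    vid = variant_record.variant.id
    rows: list[PhewasRow] = []
    not_testable: list[str] = []
    for code, (label, cohort, records) in outcomes.items():
        hit = next((r for r in records if r.variant.id == vid), None)
        if hit is None:
            not_testable.append(code)
            continue
        res = mr.wald_ratio(variant_record.beta, variant_record.se, hit.beta, hit.se)
        rows.append(
            PhewasRow(
                phenotype_code=code,
                phenotype_label=label,
                cohort=cohort,
                estimate=res.estimate,
                se=res.se,
                pvalue=res.pvalue,
                m=scheme.m,
                alpha=alpha,
            )
        )
    rows.sort(key=lambda r: r.pvalue)
    return rows, not_testable


def two_cohort_meta(row_a: PhewasRow, row_b: PhewasRow) -> PhewasRow:
    """Fixed-effect IVW pooling of the same phenotype across two cohorts."""
    if row_a.phenotype_code != row_b.phenotype_code:
        raise ValueError(
            f"phenotype codes differ: {row_a.phenotype_code} vs {row_b.phenotype_code}"
        )
    wa, wb = 1.0 / row_a.se**2, 1.0 / row_b.se**2
    est = (wa * row_a.estimate + wb * row_b.estimate) / (wa + wb)
    se = (wa + wb) ** -0.5
    z = est / se
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return PhewasRow(
        phenotype_code=row_a.phenotype_code,
        phenotype_label=row_a.phenotype_label,
        cohort="meta",
        estimate=float(est),
        se=float(se),
        pvalue=max(p, 5e-324),
        m=row_a.m,
        alpha=row_a.alpha,
    )
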