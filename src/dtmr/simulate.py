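"""Synthetic GWAS summary statistics with known ground truth.

Emulates the statistical structure of the real inputs to a drug-target MR
study without any individual-level data:

* a cis region of LD-correlated variants (AR(1) decay, or two independent
  blocks for the distinct-signal colocalization scenario) in which one
  causal variant lowers the plasma protein level;
* a downstream binary outcome affected through the protein, so that under
  no pleiotropy every variant's true outcome effect is ``theta`` times its
  true exposure effect;
* sampling noise that is *correlated across variants according to LD*, as it
  is in real summary statistics from a single cohort — the property the GLS
  estimator exists to handle;
* rare protein-truncating-variant carrier studies with 2x2 outcome tables;
* a metabolite panel with correlated common-variant and collapsing effect
  profiles for the mimicry analysis.

All simulation is at the summary level: binary-outcome betas are drawn
directly on the log-OR scale with Gaussian noise, which keeps every oracle
analytic, and exposure and outcome samples are independent (two-sample
design, no overlap).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .concordance import MetaStudyRecord, carrier_log_or
from .instruments import GeneRegion
from .sumstats import AssociationRecord, LDMatrix, Variant, write_ld, write_sumstats

_MIN_P = 5e-324  # smallest positive float: keeps pvalue in (0, 1]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cis region.

    ``beta_protein`` is the causal variant's per-allele effect on the
    protein in s.d. units; ``theta`` the causal effect of the protein on
    the outcome (log-OR per s.d. protein for binary outcomes).  Defaults
    mirror a large pQTL discovery cohort feeding a very large binary-outcome
    GWAS (sample sizes of order 3.5e4 and 1e6 with ~16% cases).
    """

    n_variants: int = 30
    ld_decay: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_index: int | str | None = "middle"  # "middle" resolves to n_variants // 2
    beta_protein: float = 0.3
    theta: float = -0.5
    n_exposure: int = 35_000
    n_outcome: int = 1_000_000
    case_fraction: float = 0.16
    seed: int = 0
    platform_noise_sd: float = 0.05
    ld_structure: str = "ar1"  # "ar1" | "two_block"
    outcome_causal_index: int | None = None  # distinct outcome signal (coloc H3)
    chrom: str = "1"
    start_pos: int = 1_000_000
    spacing_bp: int = 150
    gene: str = "GENE1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if min(self.n_exposure, self.n_outcome) < 100:
            raise ValueError("sample sizes must be >= 100")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.n_variants < 1:
            raise ValueError("need at least one variant")
        if self.causal_index == "middle":
            object.__setattr__(self, "causal_index", self.n_variants // 2)
        for idx in (self.causal_index, self.outcome_causal_index):
            if idx is not None and not 0 <= idx < self.n_variants:
                raise ValueError(f"causal index {idx} out of range")
        if self.ld_structure not in ("ar1", "two_block"):
            raise ValueError(f"unknown ld_structure '{self.ld_structure}'")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("causal_index", "outcome_causal_index"):
            if d.get(key) == "none":
                d[key] = None
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)

    def region(self) -> GeneRegion:
        return GeneRegion(
            gene=self.gene,
            chrom=self.chrom,
            start=self.start_pos,
            end=self.start_pos + self.spacing_bp * (self.n_variants - 1),
        )


@dataclass
class SyntheticTruth:
    """The generator's hidden parameters, for recovery tests."""

    config: SimConfig
    mafs: np.ndarray
    true_beta_exposure: np.ndarray  # per-allele, s.d. protein
    true_beta_outcome: np.ndarray  # per-allele, log-OR
    causal_index: int | None
    outcome_causal_index: int | None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "mafs": self.mafs.tolist(),
            "true_beta_exposure": self.true_beta_exposure.tolist(),
            "true_beta_outcome": self.true_beta_outcome.tolist(),
            "causal_index": self.causal_index,
            "outcome_causal_index": self.outcome_causal_index,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def ld_correlation(config: SimConfig) -> np.ndarray:
    """Signed LD correlation: AR(1) decay, or two independent AR(1) blocks."""
    n, rho = config.n_variants, config.ld_decay
    idx = np.arange(n)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    if config.ld_structure == "two_block":
        half = n // 2
        block = np.zeros((n, n), dtype=bool)
        block[:half, :half] = True
        block[half:, half:] = True
        r = np.where(block, r, 0.0)
        np.fill_diagonal(r, 1.0)
    return r


def _marginal_per_allele(
    r: np.ndarray, mafs: np.ndarray, causal: int | None, per_allele_effect: float
) -> np.ndarray:
    """Propagate a causal per-allele effect to marginal per-allele betas.

    On the standardized-genotype scale the causal effect is
    ``b_std = b * sqrt(2 p q)`` and the marginal standardized effect of
    variant i is ``r_ic * b_std``; de-standardizing by each variant's own
    frequency gives the per-allele marginal beta.
    """
    if causal is None or per_allele_effect == 0.0:
        return np.zeros(len(mafs))
    sd_g = np.sqrt(2.0 * mafs * (1.0 - mafs))
    b_std = per_allele_effect * sd_g[causal]
    return r[:, causal] * b_std / sd_g


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), _MIN_P, 1.0)


def _records(
    config: SimConfig,
    beta: np.ndarray,
    se: np.ndarray,
    mafs: np.ndarray,
    trait: str,
    n: int,
    unit: str,
    ncase: int | None = None,
) -> list[AssociationRecord]:
    pvals = _pvalues(beta, se)
    out = []
    for i in range(config.n_variants):
        cons, sift, poly = "intron_variant", "", ""
        if i == config.causal_index:
            cons, sift, poly = "missense_variant", "deleterious", "probably_damaging"
        out.append(
            AssociationRecord(
                variant=Variant(
                    id=f"rs{1000 + i}",
                    chrom=config.chrom,
                    pos=config.start_pos + config.spacing_bp * i,
                    effect_allele="A",
                    other_allele="G",
                    eaf=float(mafs[i]),
                    consequence=cons,
                    sift=sift,
                    polyphen=poly,
                ),
                trait=trait,
                beta=float(beta[i]),
                se=float(se[i]),
                pvalue=float(pvals[i]),
                n=n,
                ncase=ncase,
                ncontrol=None if ncase is None else n - ncase,
                unit=unit,
            )
        )
    return out


def simulate_region(
    config: SimConfig,
) -> tuple[list[AssociationRecord], list[AssociationRecord], LDMatrix, SyntheticTruth]:
    """Simulate one cis region's exposure and outcome summary statistics.

    The exposure is plasma protein level (s.d. units); the outcome is binary
    on the log-OR scale.  Marginal true betas are the causal effect
    propagated through LD; sampling noise is multivariate normal with
    per-variant SEs from the analytic approximation
    ``se = sd / sqrt(2 n maf (1 - maf))`` (times ``1/sqrt(cf (1 - cf))`` for
    the binary outcome) and correlation equal to the LD matrix.  Identical
    seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    r = ld_correlation(config)
    mafs = rng.uniform(*config.maf_range, size=n)
    het = 2.0 * mafs * (1.0 - mafs)

    true_bx = _marginal_per_allele(r, mafs, config.causal_index, config.beta_protein)
    if config.outcome_causal_index is None:
        true_by = config.theta * true_bx
    else:
        # distinct outcome signal: theta is the outcome causal variant's
        # per-allele log-OR, propagated through LD independently of the exposure
        true_by = _marginal_per_allele(r, mafs, config.outcome_causal_index, config.theta)

    se_x = 1.0 / np.sqrt(config.n_exposure * het)
    cf = config.case_fraction
    se_y = 1.0 / np.sqrt(config.n_outcome * het * cf * (1.0 - cf))

    chol = np.linalg.cholesky(r + 1e-10 * np.eye(n))
    bx = true_bx + se_x * (chol @ rng.standard_normal(n))
    by = true_by + se_y * (chol @ rng.standard_normal(n))

    exposure = _records(config, bx, se_x, mafs, "protein", config.n_exposure, "sd_protein")
    ncase = int(round(cf * config.n_outcome))
    outcome = _records(
        config, by, se_y, mafs, "outcome", config.n_outcome, "log_or", ncase=ncase
    )
    ld = LDMatrix([f"rs{1000 + i}" for i in range(n)], r, condition=False)
    truth = SyntheticTruth(
        config=config,
        mafs=mafs,
        true_beta_exposure=true_bx,
        true_beta_outcome=true_by,
        causal_index=config.causal_index,
        outcome_causal_index=config.outcome_causal_index,
    )
    return exposure, outcome, ld, truth


def simulate_platform_replicate(
    records: Sequence[AssociationRecord],
    platform_noise_sd: float,
    seed: int,
    trait: str = "protein_alt_platform",
) -> list[AssociationRecord]:
    """A second protein-measurement assay: the same signals plus independent
    between-platform discrepancy noise on each beta."""
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        beta = rec.beta + rng.normal(0.0, platform_noise_sd)
        p = float(np.clip(2.0 * stats.norm.sf(abs(beta / rec.se)), _MIN_P, 1.0))
        out.append(replace(rec, trait=trait, beta=beta, pvalue=p))
    return out


@dataclass
class PTVStudySim:
    """One simulated sequencing study of PTV carriers vs non-carriers."""

    record: MetaStudyRecord
    table: list[list[int]]  # [[carrier cases, carrier controls], [noncarrier ...]]
    low_count_warning: bool
    true_log_or: float
    true_tg_shift: float


def simulate_ptv_study(
    n_carriers: int,
    n_noncarriers: int,
    tg_shift: float,
    or_per_allele: float,
    seed: int,
    baseline_risk: float = 0.10,
    tg_sd: float = 1.0,
    study: str = "SIM",
) -> PTVStudySim:
    """Simulate a carrier-based case/control study with a TG co-phenotype.

    Heterozygous carriers (one truncating allele) have their odds of disease
    multiplied by ``or_per_allele`` over a ``baseline_risk`` in
    non-carriers; case counts are binomial draws.  The observed TG mean
    difference is drawn around ``tg_shift`` (mmol/L) with the two-sample SE
    implied by ``tg_sd``.  Studies whose expected minimum cell count is
    below 1 carry a warning flag.
    """
    if n_carriers < 10:
        raise ValueError("need at least 10 carriers")
    if not 0.0 < baseline_risk < 1.0:
        raise ValueError("baseline_risk must be in (0, 1)")
    rng = np.random.default_rng(seed)
    odds0 = baseline_risk / (1.0 - baseline_risk)
    odds1 = odds0 * or_per_allele
    p1 = odds1 / (1.0 + odds1)

    a = int(rng.binomial(n_carriers, p1))
    c = int(rng.binomial(n_noncarriers, baseline_risk))
    table = [[a, n_carriers - a], [c, n_noncarriers - c]]

    expected_min = min(
        n_carriers * p1, n_carriers * (1 - p1),
        n_noncarriers * baseline_risk, n_noncarriers * (1 - baseline_risk),
    )
    log_or, se = carrier_log_or(table)

    tg_se = tg_sd * math.sqrt(1.0 / n_carriers + 1.0 / n_noncarriers)
    tg_est = float(rng.normal(tg_shift, tg_se))
    record = MetaStudyRecord(
        study=study,
        log_or_per_allele=log_or,
        se=se,
        tg_effect_per_allele=tg_est,
        tg_se=tg_se,
        genotyping="sequencing",
        ncase=a + c,
        ncontrol=n_carriers + n_noncarriers - a - c,
    )
    return PTVStudySim(
        record=record,
        table=table,
        low_count_warning=expected_min < 1.0,
        true_log_or=math.log(or_per_allele),
        true_tg_shift=tg_shift,
    )


@dataclass
class MetabolitePanel:
    """Paired common-variant and PTV effect profiles over a trait panel."""

    cv_effects: np.ndarray
    cv_se: np.ndarray
    ptv_effects: np.ndarray
    ptv_se: np.ndarray
    concordance_rho: float
    trait_names: list[str] = field(default_factory=list)


def simulate_metabolite_panel(
    n_traits: int,
    concordance_rho: float,
    seed: int,
    effect_sd: float = 0.25,
    noise_sd: float = 0.01,
) -> MetabolitePanel:
    """Simulate a metabolite panel for the mimicry analysis.

    Per-trait latent true effects for the common-variant and PTV profiles
    are bivariate normal with correlation ``concordance_rho`` and scale
    ``effect_sd`` (s.d. units on the common-variant MR scale); independent
    measurement noise of ``noise_sd`` is added to each observed vector.
    The default panel size in the pipeline is 167 traits.
    """
    if n_traits < 3:
        raise ValueError("panel needs at least 3 traits")
    if abs(concordance_rho) > 1.0:
        raise ValueError("|concordance_rho| must be <= 1")
    rng = np.random.default_rng(seed)
    t1 = rng.normal(0.0, effect_sd, size=n_traits)
    t2 = concordance_rho * t1 + math.sqrt(
        max(0.0, 1.0 - concordance_rho**2)
    ) * rng.normal(0.0, effect_sd, size=n_traits)
    cv = t1 + rng.normal(0.0, noise_sd, size=n_traits) if noise_sd > 0 else t1.copy()
    ptv = t2 + rng.normal(0.0, noise_sd, size=n_traits) if noise_sd > 0 else t2.copy()
    return MetabolitePanel(
        cv_effects=cv,
        cv_se=np.full(n_traits, max(noise_sd, 1e-12)),
        ptv_effects=ptv,
        ptv_se=np.full(n_traits, max(noise_sd, 1e-12)),
        concordance_rho=concordance_rho,
        trait_names=[f"metabolite_{i + 1:03d}" for i in range(n_traits)],
    )


def write_region(
    outdir: str | Path,
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    ld: LDMatrix,
    truth: SyntheticTruth,
) -> dict[str, Path]:
    """Write a simulated region as the standard file formats plus a truth
    sidecar (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "outcome": outdir / "outcome.tsv",
        "ld": outdir / "ld.tsv",
        "truth": outdir / "truth.json",
    }
    write_sumstats(exposure, paths["exposure"])
    write_sumstats(outcome, paths["outcome"])
    write_ld(ld, paths["ld"])
    truth.to_json(paths["truth"])
    return paths
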