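"""Genetic-instrument selection: cis windows, p-value thresholds, LD clumping
and functional-consequence filters.

Two selection modes are supported.  *cis* mode keeps genome-wide-significant
variants inside a padded window around the target gene and greedily clumps
them so that every retained pair has r-squared below the threshold (the
default 0.10 keeps the GLS covariance well conditioned).  *genome-wide* mode
additionally enforces a positional window between accepted index variants on
the same chromosome, as used for polygenic positive-control exposures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .sumstats import AssociationRecord, HarmonizationResult, LDMatrix

PTV_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "frameshift_variant", "splice_donor",
     "splice_donor_variant", "splice_acceptor", "splice_acceptor_variant"}
)

# Consequence classes retained by the functional-variant filter regardless of
# SIFT/PolyPhen (UTR, splice-region and truncating classes).
_FUNCTIONAL_KEEP = (
    "5_prime_utr", "3_prime_utr", "splice_region", "splice_donor",
    "splice_acceptor", "stop_gained", "frameshift",
)

_SIFT_DELETERIOUS = ("deleterious",)
_POLYPHEN_DAMAGING = ("probably_damaging", "possibly_damaging")


@dataclass(frozen=True)
class GeneRegion:
    """A drug-target gene's footprint with analysis-specific padding.

    ``cis_pad`` (default 2.5 kb) bounds instrument selection;
    ``coloc_pad`` (default 250 kb each side, a 500 kb window) bounds
    colocalization.
    """

    gene: str
    chrom: str
    start: int
    end: int
    cis_pad: int = 2_500
    coloc_pad: int = 250_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: region start > end")
        if self.cis_pad < 0 or self.coloc_pad < 0:
            raise ValueError(f"{self.gene}: pads must be >= 0")

    def cis_bounds(self) -> tuple[int, int]:
        return self.start - self.cis_pad, self.end + self.cis_pad

    def coloc_bounds(self) -> tuple[int, int]:
        return self.start - self.coloc_pad, self.end + self.coloc_pad

    def contains(self, chrom: str, pos: int, *, pad: str = "cis") -> bool:
        lo, hi = self.cis_bounds() if pad == "cis" else self.coloc_bounds()
        return chrom == self.chrom and lo <= pos <= hi


@dataclass(frozen=True)
class SelectionParams:
    p_threshold: float = 5e-8
    clump_r2: float = 0.10
    clump_window_bp: int | None = None  # genome-wide mode default 500 kb
    mode: str = "cis"

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if not 0 < self.clump_r2 <= 1:
            raise ValueError("clump_r2 must be in (0, 1]")
        if self.mode not in ("cis", "genome_wide"):
            raise ValueError(f"unknown selection mode '{self.mode}'")

    @property
    def window_bp(self) -> int | None:
        if self.clump_window_bp is not None:
            return self.clump_window_bp
        return 500_000 if self.mode == "genome_wide" else None


GENOME_WIDE_PARAMS = SelectionParams(
    p_threshold=5e-8, clump_r2=0.001, clump_window_bp=500_000, mode="genome_wide"
)


@dataclass
class InstrumentSet:
    """Selected instruments with exposure (and, once attached, outcome) effects.

    ``empty`` marks the typed "no instruments" outcome: selection that finds
    nothing returns an empty set rather than raising, so report tables can
    show "Zero SNPs" rows.
    """

    exposure_trait: str
    records: list[AssociationRecord]
    ld: LDMatrix | None
    params: SelectionParams
    provenance: list[str] = field(default_factory=list)
    outcome_records: list[AssociationRecord] | None = None

    @property
    def empty(self) -> bool:
        return len(self.records) == 0

    @property
    def n_snps(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant.id for r in self.records]

    @property
    def exposure_beta(self) -> np.ndarray:
        return np.array([r.beta for r in self.records])

    @property
    def exposure_se(self) -> np.ndarray:
        return np.array([r.se for r in self.records])

    @property
    def outcome_beta(self) -> np.ndarray:
        if self.outcome_records is None:
            raise ValueError("no outcome effects attached; call attach_outcome first")
        return np.array([r.beta for r in self.outcome_records])

    @property
    def outcome_se(self) -> np.ndarray:
        if self.outcome_records is None:
            raise ValueError("no outcome effects attached; call attach_outcome first")
        return np.array([r.se for r in self.outcome_records])

    def attach_outcome(self, harmonized: HarmonizationResult) -> "InstrumentSet":
        """Restrict to variants present in a harmonized pairing and attach
        the aligned outcome effects (exposure ids absent from the pairing are
        dropped with a provenance entry)."""
        out_by_id = {p.exposure.variant.id: p.outcome for p in harmonized.pairs}
        kept, out = [], []
        prov = list(self.provenance)
        for rec in self.records:
            vid = rec.variant.id
            if vid in out_by_id:
                kept.append(rec)
                out.append(out_by_id[vid])
            else:
                prov.append(f"{vid}: absent from harmonized outcome -> dropped")
        ld = self.ld.subset([r.variant.id for r in kept]) if (self.ld and kept) else None
        return InstrumentSet(
            exposure_trait=self.exposure_trait,
            records=kept,
            ld=ld,
            params=self.params,
            provenance=prov,
            outcome_records=out,
        )


def _sort_key(rec: AssociationRecord):
    # ties in p break by ascending position, then lexicographic id
    return (rec.pvalue, rec.variant.pos, rec.variant.id)


def greedy_clump(
    records: Sequence[AssociationRecord],
    ld: LDMatrix | None,
    clump_r2: float,
    window_bp: int | None = None,
    provenance: list[str] | None = None,
) -> list[AssociationRecord]:
    """Greedy p-value-ordered LD clumping.

    Repeatedly accept the most significant remaining variant and discard
    every variant with r-squared at or above ``clump_r2`` with an accepted
    one (pairs absent from the LD matrix are treated as unlinked).  With
    ``window_bp``, candidates within that distance of an accepted variant on
    the same chromosome are also discarded.  The result is independent of
    input ordering.
    """
    prov = provenance if provenance is not None else []
    accepted: list[AssociationRecord] = []
    for rec in sorted(records, key=_sort_key):
        conflict = None
        for acc in accepted:
            r2 = _pair_r2(ld, rec.variant.id, acc.variant.id)
            if r2 is not None and r2 >= clump_r2:
                conflict = f"r2 {r2:.3f} >= {clump_r2} with index {acc.variant.id}"
                break
            if (
                window_bp is not None
                and rec.variant.chrom == acc.variant.chrom
                and abs(rec.variant.pos - acc.variant.pos) <= window_bp
            ):
                conflict = f"within {window_bp} bp of index {acc.variant.id}"
                break
        if conflict is None:
            accepted.append(rec)
        else:
            prov.append(f"{rec.variant.id}: clumped ({conflict})")
    return accepted


def _pair_r2(ld: LDMatrix | None, id_a: str, id_b: str) -> float | None:
    if ld is None:
        return None
    try:
        return ld.pairwise_r(id_a, id_b) ** 2
    except KeyError:
        return None


def select_cis(
    records: Iterable[AssociationRecord],
    region: GeneRegion | None,
    ld: LDMatrix | None,
    params: SelectionParams = SelectionParams(),
) -> InstrumentSet:
    """Select instruments in the padded cis window at the significance
    threshold, then clump.

    ``region=None`` (genome-wide mode) skips the positional filter.  An empty
    result is a typed outcome, not an error.
    """
    records = list(records)
    prov: list[str] = []
    candidates = []
    for rec in records:
        v = rec.variant
        if region is not None and not region.contains(v.chrom, v.pos):
            prov.append(f"{v.id}: outside cis window -> dropped")
            continue
        if rec.pvalue > params.p_threshold:
            prov.append(f"{v.id}: p {rec.pvalue:.3g} > {params.p_threshold:g} -> dropped")
            continue
        candidates.append(rec)

    kept = greedy_clump(candidates, ld, params.clump_r2, params.window_bp, prov)
    trait = kept[0].trait if kept else (records[0].trait if records else "")
    sub_ld = None
    if ld is not None and kept:
        ids = [r.variant.id for r in kept]
        try:
            sub_ld = ld.subset(ids)
        except KeyError:
            sub_ld = None
    if not kept:
        prov.append("no instruments passed selection (Zero SNPs)")
    return InstrumentSet(
        exposure_trait=trait, records=kept, ld=sub_ld, params=params, provenance=prov
    )


def _norm_label(label: str) -> str:
    return label.strip().lower().replace(" ", "_").replace("'", "_prime_").replace("__", "_")


def filter_functional_variants(
    records: Iterable[AssociationRecord], p_relaxed: float = 0.01
) -> list[AssociationRecord]:
    """Keep variants with predicted functional impact at a relaxed p cut.

    Retains variants with ``p <= p_relaxed`` whose consequence is UTR,
    splice-site/region or protein-truncating, plus missense variants carrying
    a SIFT "deleterious" or PolyPhen "probably/possibly damaging" annotation.
    Non-coding variants outside those classes, and missense variants lacking
    a damaging annotation, are filtered out.
    """
    records = list(records)
    if records and all(r.variant.consequence == "" for r in records):
        raise ValueError("consequence annotations absent: cannot filter functional variants")
    kept = []
    for rec in records:
        if rec.pvalue > p_relaxed:
            continue
        cons = _norm_label(rec.variant.consequence)
        if any(tag in cons for tag in _FUNCTIONAL_KEEP):
            kept.append(rec)
        elif "missense" in cons:
            sift = _norm_label(rec.variant.sift)
            poly = _norm_label(rec.variant.polyphen)
            if any(s in sift for s in _SIFT_DELETERIOUS) or any(
                p in poly for p in _POLYPHEN_DAMAGING
            ):
                kept.append(rec)
    return kept


def flag_ptv(
    records: Iterable[AssociationRecord], af_max: float = 0.05
) -> list[AssociationRecord]:
    """Set ``is_ptv`` true for protein-truncating consequences below ``af_max``
    effect-allele frequency (stop-gain, frameshift, essential splice)."""
    out = []
    for rec in records:
        cons = _norm_label(rec.variant.consequence)
        is_ptv = (
            any(cons.startswith(c) or cons == c for c in PTV_CONSEQUENCES)
            and not math.isnan(rec.variant.eaf)
            and rec.variant.eaf < af_max
        )
        out.append(replace(rec, variant=replace(rec.variant, is_ptv=is_ptv)))
    return out
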