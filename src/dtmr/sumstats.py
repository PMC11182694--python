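"""Reading, validation and harmonization of GWAS summary statistics and LD matrices.

Summary statistics travel as delimited text (tab or comma on input, tab on
output) with one row per variant.  LD matrices are square delimited text with
variant ids on the first row and column, storing *signed* correlation r; the
sign is needed by the GLS estimator and by colocalization, while clumping
squares it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("id", "effect_allele", "other_allele", "beta", "se", "pvalue")
OPTIONAL_COLUMNS = (
    "chrom",
    "pos",
    "eaf",
    "n",
    "ncase",
    "ncontrol",
    "consequence",
    "sift",
    "polyphen",
    "is_ptv",
    "unit",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class Variant:
    """A genetic variant with optional functional annotation.

    Coordinates are 1-based.  ``eaf`` is the frequency of ``effect_allele``,
    the allele whose dosage the association betas are reported against.
    """

    id: str
    chrom: str = ""
    pos: int = 1
    effect_allele: str = ""
    other_allele: str = ""
    eaf: float = math.nan
    consequence: str = ""
    sift: str = ""
    polyphen: str = ""
    is_ptv: bool = False

    def __post_init__(self) -> None:
        if self.effect_allele and self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: effect and other allele are identical")
        if not math.isnan(self.eaf) and not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"{self.id}: eaf {self.eaf} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be 1-based (got {self.pos})")

    @property
    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


@dataclass(frozen=True)
class AssociationRecord:
    """One variant x trait summary-statistic row: the atom of all MR input."""

    variant: Variant
    trait: str
    beta: float
    se: float
    pvalue: float
    n: int = 0
    ncase: int | None = None
    ncontrol: int | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.variant.id}: se must be > 0 (got {self.se})")
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"{self.variant.id}: pvalue {self.pvalue} outside (0, 1]")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant.id}: beta is not finite")

    @property
    def zscore(self) -> float:
        return self.beta / self.se


class LDMatrix:
    """Signed pairwise correlation r over an ordered variant set.

    The constructor validates symmetry, bounds and unit diagonal; an input
    matrix that is not positive semi-definite is repaired by clipping
    eigenvalues at 1e-8 and re-normalizing the diagonal to 1, so that the
    GLS covariance built from it is always invertible.
    """

    def __init__(self, variant_ids: Sequence[str], r: np.ndarray, *, condition: bool = True):
        r = np.asarray(r, dtype=float)
        ids = list(variant_ids)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("LD matrix must be square")
        if r.shape[0] != len(ids):
            raise ValueError("LD matrix size does not match number of variant ids")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant ids in LD matrix")
        if np.isnan(r).any():
            raise ValueError("LD matrix contains NaN")
        if np.abs(r - r.T).max(initial=0.0) > 1e-8:
            raise ValueError("LD matrix asymmetric beyond 1e-8")
        if np.abs(r).max(initial=0.0) > 1.0 + 1e-8:
            raise ValueError("LD matrix entry with |r| > 1")
        r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        if condition:
            r = _condition_psd(r)
        self.variant_ids: list[str] = ids
        self.r: np.ndarray = r
        self._index = {v: i for i, v in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def subset(self, ids: Iterable[str]) -> "LDMatrix":
        ids = list(ids)
        missing = [v for v in ids if v not in self._index]
        if missing:
            raise KeyError(f"variant ids not in LD matrix: {missing}")
        idx = [self._index[v] for v in ids]
        return LDMatrix(ids, self.r[np.ix_(idx, idx)], condition=False)

    def pairwise_r(self, id_a: str, id_b: str) -> float:
        return float(self.r[self._index[id_a], self._index[id_b]])


def _condition_psd(r: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and re-normalize the diagonal to 1."""
    vals, vecs = np.linalg.eigh(r)
    if vals.min() >= floor:
        return r
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return fixed


# ---------------------------------------------------------------------------
# Summary-statistic files
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a tab- or comma-delimited table, auto-detecting the delimiter."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_sumstats(
    path: str | Path,
    trait: str,
    *,
    report: list[str] | None = None,
) -> list[AssociationRecord]:
    """Parse a summary-statistic file into :class:`AssociationRecord` rows.

    Every input row is either parsed or rejected; rejections are logged with
    their 1-based line number and, if ``report`` is a list, appended to it.
    A missing mandatory column raises immediately, naming the column.
    """
    df = _read_table(path)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: mandatory column '{col}' is missing")

    records: list[AssociationRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        data = dict(zip(df.columns, row))
        try:
            vid = data["id"].strip()
            if vid in seen_ids:
                raise ValueError("duplicate variant id (multi-allelic sites are rejected)")
            variant = Variant(
                id=vid,
                chrom=str(data.get("chrom", "")).strip(),
                pos=int(float(data["pos"])) if data.get("pos", "") != "" else 1,
                effect_allele=data["effect_allele"].strip().upper(),
                other_allele=data["other_allele"].strip().upper(),
                eaf=float(data["eaf"]) if data.get("eaf", "") != "" else math.nan,
                consequence=str(data.get("consequence", "")).strip(),
                sift=str(data.get("sift", "")).strip(),
                polyphen=str(data.get("polyphen", "")).strip(),
                is_ptv=str(data.get("is_ptv", "")).strip().lower() in ("true", "1"),
            )
            record = AssociationRecord(
                variant=variant,
                trait=trait,
                beta=float(data["beta"]),
                se=float(data["se"]),
                pvalue=float(data["pvalue"]),
                n=int(float(data["n"])) if data.get("n", "") != "" else 0,
                ncase=int(float(data["ncase"])) if data.get("ncase", "") != "" else None,
                ncontrol=int(float(data["ncontrol"])) if data.get("ncontrol", "") != "" else None,
                unit=str(data.get("unit", "")).strip(),
            )
        except (ValueError, KeyError) as exc:
            msg = f"{path}:{line_no}: rejected row: {exc}"
            logger.warning(msg)
            if report is not None:
                report.append(msg)
            continue
        seen_ids.add(vid)
        records.append(record)
    return records


def write_sumstats(records: Iterable[AssociationRecord], path: str | Path) -> None:
    """Write records as a tab-delimited file round-tripping numerics to 12 s.d."""
    rows = []
    for rec in records:
        v = rec.variant
        rows.append(
            {
                "id": v.id,
                "chrom": v.chrom,
                "pos": v.pos,
                "effect_allele": v.effect_allele,
                "other_allele": v.other_allele,
                "eaf": _fmt(v.eaf),
                "beta": _fmt(rec.beta),
                "se": _fmt(rec.se),
                "pvalue": _fmt(rec.pvalue),
                "n": rec.n,
                "ncase": "" if rec.ncase is None else rec.ncase,
                "ncontrol": "" if rec.ncontrol is None else rec.ncontrol,
                "consequence": v.consequence,
                "sift": v.sift,
                "polyphen": v.polyphen,
                "is_ptv": v.is_ptv,
                "unit": rec.unit,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _fmt(x: float) -> str:
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.12g}"


def read_ld(path: str | Path) -> LDMatrix:
    """Read an LD matrix keyed by variant id on the first row and column."""
    df = _read_table(path)
    ids = [str(c) for c in df.columns[1:]]
    row_ids = [str(v) for v in df.iloc[:, 0]]
    if row_ids != ids:
        raise ValueError(f"{path}: row ids do not match column ids")
    try:
        r = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric LD cell: {exc}") from None
    return LDMatrix(ids, r)


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ld.r, columns=ld.variant_ids)
    df.insert(0, "id", ld.variant_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


@dataclass
class HarmonizedPair:
    """Exposure and outcome records aligned to the exposure's effect allele."""

    exposure: AssociationRecord
    outcome: AssociationRecord


@dataclass
class HarmonizationResult:
    pairs: list[HarmonizedPair] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def variant_ids(self) -> list[str]:
        return [p.exposure.variant.id for p in self.pairs]


def _flip(record: AssociationRecord) -> AssociationRecord:
    v = record.variant
    flipped = replace(
        v,
        effect_allele=v.other_allele,
        other_allele=v.effect_allele,
        eaf=1.0 - v.eaf if not math.isnan(v.eaf) else math.nan,
    )
    return replace(record, variant=flipped, beta=-record.beta)


def _complemented(v: Variant) -> Variant:
    try:
        return replace(
            v,
            effect_allele=_COMPLEMENT[v.effect_allele],
            other_allele=_COMPLEMENT[v.other_allele],
        )
    except KeyError:
        return v


def harmonize(
    exposure: Iterable[AssociationRecord],
    outcome: Iterable[AssociationRecord],
    palindrome_eaf_window: float = 0.08,
) -> HarmonizationResult:
    """Align outcome effects to the exposure's effect-allele orientation.

    Outcome records with alleles swapped relative to the exposure have their
    beta negated and eaf complemented; strand flips of non-palindromic
    variants are resolved by allele complementation.  Palindromic (A/T, C/G)
    variants whose exposure eaf lies inside ``0.5 +/- palindrome_eaf_window``
    are ambiguous and dropped, as are palindromes with unknown eaf and
    variants with incompatible alleles.  The result logs every action, and
    re-harmonizing an already-harmonized pair is a no-op.
    """
    exp_by_id = {r.variant.id: r for r in exposure}
    out_by_id = {r.variant.id: r for r in outcome}
    shared = [vid for vid in exp_by_id if vid in out_by_id]
    if not shared:
        raise ValueError("harmonize: zero shared variants between exposure and outcome")

    result = HarmonizationResult()
    w = palindrome_eaf_window
    for vid in shared:
        ex, ou = exp_by_id[vid], out_by_id[vid]
        ev, ov = ex.variant, ou.variant
        if ev.is_palindromic:
            if math.isnan(ev.eaf):
                result.log.append(f"{vid}: palindromic with unknown eaf -> dropped")
                continue
            if abs(ev.eaf - 0.5) <= w:
                result.log.append(
                    f"{vid}: palindromic, eaf {ev.eaf:.3f} within [{0.5 - w:.2f}, {0.5 + w:.2f}] -> dropped"
                )
                continue
        aligned = _align_alleles(ex, ou, result.log)
        if aligned is None:
            continue
        result.pairs.append(HarmonizedPair(exposure=ex, outcome=aligned))
    return result


def _align_alleles(
    ex: AssociationRecord, ou: AssociationRecord, log: list[str]
) -> AssociationRecord | None:
    ev, ov = ex.variant, ou.variant
    pair_exp = (ev.effect_allele, ev.other_allele)
    if (ov.effect_allele, ov.other_allele) == pair_exp:
        return ou
    if (ov.other_allele, ov.effect_allele) == pair_exp:
        log.append(f"{ev.id}: outcome alleles swapped -> beta negated, eaf complemented")
        return _flip(ou)
    if not ev.is_palindromic:
        cv = _complemented(ov)
        if (cv.effect_allele, cv.other_allele) == pair_exp:
            log.append(f"{ev.id}: outcome on opposite strand -> complemented")
            return replace(ou, variant=cv)
        if (cv.other_allele, cv.effect_allele) == pair_exp:
            log.append(f"{ev.id}: outcome opposite strand and swapped -> complemented, flipped")
            return _flip(replace(ou, variant=cv))
    log.append(
        f"{ev.id}: incompatible alleles "
        f"({ev.effect_allele}/{ev.other_allele} vs {ov.effect_allele}/{ov.other_allele}) -> dropped"
    )
    return None
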