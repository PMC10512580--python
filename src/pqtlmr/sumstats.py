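"""Reading, validation and allele harmonization of GWAS/pQTL summary statistics.

Every downstream stage consumes :class:`GwasRecord` objects — one SNP's
marginal association with one trait. Two-sample MR requires the exposure
and outcome effects to refer to the same effect allele; :func:`harmonize`
aligns them, flipping signs where the allele labels are swapped and
dropping palindromic SNPs whose strand cannot be resolved from allele
frequency.

Conventions: coordinates are 1-based GRCh37 (metadata only — no liftover);
betas are in SD units for quantitative traits and log-OR for binary traits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
#: allele pairs whose strand flip is indistinguishable from an allele swap
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

QUANTITATIVE = "quantitative"
CASE_CONTROL = "case_control"

MANDATORY_COLUMNS = ("snp", "chr", "pos", "ea", "oa", "beta", "se", "p", "n")
OPTIONAL_COLUMNS = ("eaf", "ncase")


class SumstatsError(ValueError):
    """Fatal configuration or validation problem in a summary-statistics file."""


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's marginal association for one trait.

    Invariants (enforced at construction): ``se > 0``, alleles are single
    distinct upper-case bases, ``eaf`` in [0, 1] when present, ``pval`` in
    (0, 1], and ``case_fraction`` present iff the trait is case/control.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float
    trait_type: str = QUANTITATIVE
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single bases, got "
                f"{self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValueError(f"{self.snp_id}: se must be finite and > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.snp_id}: beta must be finite")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf outside [0, 1]: {self.eaf}")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: pval outside (0, 1]: {self.pval}")
        if self.n <= 0:
            raise ValueError(f"{self.snp_id}: sample size must be positive")
        if self.trait_type not in (QUANTITATIVE, CASE_CONTROL):
            raise ValueError(f"{self.snp_id}: unknown trait_type {self.trait_type!r}")
        if self.trait_type == CASE_CONTROL:
            if self.case_fraction is None or not (0.0 < self.case_fraction < 1.0):
                raise ValueError(
                    f"{self.snp_id}: case_control records need case_fraction in (0, 1)"
                )

    @property
    def z(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        return (self.effect_allele, self.other_allele) in PALINDROMIC_PAIRS


# harmonization actions
ACTION_NONE = "none"
ACTION_FLIPPED = "flipped"
ACTION_DROPPED_PALINDROMIC = "dropped_palindromic"
ACTION_DROPPED_MISMATCH = "dropped_mismatch"


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome records for one SNP, sign-aligned to the exposure's effect allele."""

    snp_id: str
    exposure: GwasRecord
    outcome: GwasRecord
    action_taken: str

    @property
    def kept(self) -> bool:
        return self.action_taken in (ACTION_NONE, ACTION_FLIPPED)


def _normalize_chrom(value: object) -> str:
    text = str(value).strip()
    if text.lower().startswith("chr"):
        text = text[3:]
    return text


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = QUANTITATIVE,
) -> list[GwasRecord]:
    """Read a delimited summary-statistics file into validated records.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row.
    column_map
        Mapping from the standard column names (``snp, chr, pos, ea, oa,
        beta, se, p, n`` plus optional ``eaf, ncase``) to the names used in
        the file. Unmapped names are looked up verbatim.
    trait_type
        ``"quantitative"`` or ``"case_control"``; case/control files must
        carry an ``ncase`` column from which the case fraction is derived.

    Malformed rows (invariant violations) are skipped with a logged count;
    a missing mandatory column or zero valid rows is fatal.
    """
    column_map = dict(column_map or {})
    frame = pd.read_csv(path, sep=None, engine="python")

    def col(name: str) -> str:
        return column_map.get(name, name)

    missing = [name for name in MANDATORY_COLUMNS if col(name) not in frame.columns]
    if trait_type == CASE_CONTROL and col("ncase") not in frame.columns:
        missing.append("ncase")
    if missing:
        raise SumstatsError(
            f"{path}: missing mandatory column(s) {missing}; available: {list(frame.columns)}"
        )
    has_eaf = col("eaf") in frame.columns

    records: list[GwasRecord] = []
    skipped = 0
    for row in frame.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(frame.columns, row))
        try:
            n = float(row[col("n")])
            case_fraction = None
            if trait_type == CASE_CONTROL:
                case_fraction = float(row[col("ncase")]) / n
            eaf = None
            if has_eaf:
                raw = row[col("eaf")]
                eaf = None if pd.isna(raw) else float(raw)
            records.append(
                GwasRecord(
                    snp_id=str(row[col("snp")]),
                    chrom=_normalize_chrom(row[col("chr")]),
                    pos=int(row[col("pos")]),
                    effect_allele=str(row[col("ea")]).upper(),
                    other_allele=str(row[col("oa")]).upper(),
                    eaf=eaf,
                    beta=float(row[col("beta")]),
                    se=float(row[col("se")]),
                    pval=float(row[col("p")]),
                    n=n,
                    trait_type=trait_type,
                    case_fraction=case_fraction,
                )
            )
        except (ValueError, TypeError, ZeroDivisionError):
            skipped += 1
    if skipped:
        logger.info("read_sumstats(%s): skipped %d malformed row(s)", path, skipped)
    if not records:
        raise SumstatsError(f"{path}: no valid rows")
    return records


def _flip(record: GwasRecord) -> GwasRecord:
    """Swap allele labels, negate beta, complement eaf."""
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        beta=-record.beta,
        eaf=None if record.eaf is None else 1.0 - record.eaf,
    )


def harmonize(
    exposure: Sequence[GwasRecord],
    outcome: Sequence[GwasRecord],
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonizedPair]:
    """Align outcome records to the exposure's effect allele, SNP by SNP.

    Swapped allele labels flip the outcome beta sign (and complement its
    eaf). Palindromic SNPs (A/T, C/G) are kept only when both allele
    frequencies fall on the same side of 0.5 and both lie outside
    ``[0.5 - window, 0.5 + window]``; a palindromic SNP with a missing eaf
    on either side is dropped (conservative). Irreconcilable allele sets
    are dropped as mismatches. Dropped SNPs are returned with their
    ``action_taken`` so callers can audit; use :func:`kept_pairs` for the
    analysable subset.
    """
    outcome_by_id: dict[str, GwasRecord] = {}
    for rec in outcome:
        outcome_by_id.setdefault(rec.snp_id, rec)

    pairs: list[HarmonizedPair] = []
    for exp in exposure:
        out = outcome_by_id.get(exp.snp_id)
        if out is None:
            continue
        if (out.effect_allele, out.other_allele) == (exp.effect_allele, exp.other_allele):
            aligned, action = out, ACTION_NONE
        elif (out.effect_allele, out.other_allele) == (exp.other_allele, exp.effect_allele):
            aligned, action = _flip(out), ACTION_FLIPPED
        else:
            pairs.append(HarmonizedPair(exp.snp_id, exp, out, ACTION_DROPPED_MISMATCH))
            continue
        if exp.is_palindromic():
            if not _palindrome_resolvable(exp.eaf, aligned.eaf, palindrome_eaf_window):
                pairs.append(HarmonizedPair(exp.snp_id, exp, out, ACTION_DROPPED_PALINDROMIC))
                continue
        pairs.append(HarmonizedPair(exp.snp_id, exp, aligned, action))
    if not pairs:
        raise SumstatsError(
            "harmonize: no shared SNP ids between exposure and outcome inputs"
        )
    return pairs


def _palindrome_resolvable(eaf_exp: float | None, eaf_out: float | None, window: float) -> bool:
    if eaf_exp is None or eaf_out is None:
        return False
    same_side = (eaf_exp - 0.5) * (eaf_out - 0.5) > 0
    outside = abs(eaf_exp - 0.5) > window and abs(eaf_out - 0.5) > window
    return same_side and outside


def kept_pairs(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    """The harmonized pairs usable for estimation (not dropped)."""
    return [p for p in pairs if p.kept]


def pairs_to_frame(pairs: Iterable[HarmonizedPair]) -> pd.DataFrame:
    """Tabular view of harmonized pairs (one row per SNP, with action)."""
    rows = []
    for p in pairs:
        rows.append(
            {
                "snp": p.snp_id,
                "chr": p.exposure.chrom,
                "pos": p.exposure.pos,
                "ea": p.exposure.effect_allele,
                "oa": p.exposure.other_allele,
                "beta_exposure": p.exposure.beta,
                "se_exposure": p.exposure.se,
                "p_exposure": p.exposure.pval,
                "beta_outcome": p.outcome.beta,
                "se_outcome": p.outcome.se,
                "p_outcome": p.outcome.pval,
                "action_taken": p.action_taken,
            }
        )
    return pd.DataFrame(rows)


def records_to_frame(records: Iterable[GwasRecord]) -> pd.DataFrame:
    """Serialize records in the standard column layout read_sumstats expects."""
    rows = []
    for r in records:
        row = {
            "snp": r.snp_id,
            "chr": r.chrom,
            "pos": r.pos,
            "ea": r.effect_allele,
            "oa": r.other_allele,
            "eaf": r.eaf,
            "beta": r.beta,
            "se": r.se,
            "p": r.pval,
            "n": r.n,
        }
        if r.trait_type == CASE_CONTROL:
            row["ncase"] = r.case_fraction * r.n
        rows.append(row)
    return pd.DataFrame(rows)
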