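"""Causal-direction guards: Steiger filtering and bidirectional MR.

Steiger filtering checks that the instruments explain more variance in
the exposure (protein) than in the outcome (disease): per-SNP r² is
approximated by z²/(z²+n) and summed over instruments, and the two
correlations are compared with a Fisher-z test. Bidirectional MR runs the
reverse analysis — disease on protein — using genome-wide disease
instruments selected by the same criteria (without the cis filter);
a significant reverse effect flags the protein for exclusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from pqtlmr.instruments import InstrumentConfig, InstrumentSet, build_instruments
from pqtlmr.mr import ivw, mr_egger, wald_ratio, _two_sided_p
from pqtlmr.sumstats import GwasRecord, HarmonizedPair, harmonize, kept_pairs


@dataclass
class SteigerResult:
    """Instrument variance explained on each side and the direction verdict."""

    protein_id: str
    outcome_id: str
    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    steiger_z: float
    steiger_p: float


@dataclass
class BidirectionalResult:
    """Reverse-direction (disease → protein) MR summary."""

    protein_id: str
    outcome_id: str
    n_instruments: int
    reverse_beta: float | None
    reverse_p_ivw: float | None
    reverse_p_egger: float | None
    reverse_causal: bool
    reason: str = ""


def _r2_from_record(rec: GwasRecord) -> float:
    z2 = (rec.beta / rec.se) ** 2
    return z2 / (z2 + rec.n)


def steiger_test(
    instruments: InstrumentSet,
    outcome_pairs: Sequence[HarmonizedPair],
    n_exp: float | None = None,
    n_out: float | None = None,
    outcome_id: str = "",
) -> SteigerResult:
    """Compare instrument r² on the exposure vs the outcome side.

    r² per side sums z²/(z²+n) over the instrument SNPs (observed scale on
    both sides). The Fisher-z statistic is
    (atanh r_exp − atanh r_out) / √(1/(n_exp−3) + 1/(n_out−3)) with a
    two-sided normal p. A tie in r² is conservatively *not* the correct
    direction.
    """
    by_id = {p.snp_id: p for p in outcome_pairs if p.kept}
    exp_recs = [r for r in instruments.snps if r.snp_id in by_id]
    if not exp_recs:
        raise ValueError("steiger_test: no instrument SNPs present in outcome pairs")
    out_recs = [by_id[r.snp_id].outcome for r in exp_recs]
    if n_exp is None:
        n_exp = float(np.mean([r.n for r in exp_recs]))
    if n_out is None:
        n_out = float(np.mean([r.n for r in out_recs]))
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("steiger_test: sample size must exceed 3 on both sides")

    r2_exp = min(float(sum(_r2_from_record(r) for r in exp_recs)), 1.0 - 1e-12)
    r2_out = min(float(sum(_r2_from_record(r) for r in out_recs)), 1.0 - 1e-12)
    z = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))) / math.sqrt(
        1.0 / (n_exp - 3.0) + 1.0 / (n_out - 3.0)
    )
    return SteigerResult(
        protein_id=instruments.protein_id,
        outcome_id=outcome_id,
        r2_exposure=r2_exp,
        r2_outcome=r2_out,
        correct_direction=r2_exp > r2_out,
        steiger_z=z,
        steiger_p=_two_sided_p(z),
    )


def bidirectional_mr(
    outcome_gwas: Sequence[GwasRecord],
    protein_gwas: Sequence[GwasRecord],
    instrument_config: InstrumentConfig | None = None,
    alpha: float = 0.05,
    ld: np.ndarray | None = None,
    ld_snp_ids: Sequence[str] | None = None,
    protein_id: str = "",
    outcome_id: str = "",
    primary: str = "ivw",
) -> BidirectionalResult:
    """MR of disease on protein to detect reverse causation.

    Disease instruments are selected with the standard criteria —
    significance, MHC exclusion, clumping, F > 10 — but without the cis
    filter (disease instruments are genome-wide). The reverse effect is
    estimated by Wald ratio (one instrument) or IVW (primary), with
    MR-Egger reported alongside when k ≥ 3; ``reverse_causal`` keys on the
    configured primary p-value at ``alpha``.
    """
    config = instrument_config or InstrumentConfig()
    disease_iv = build_instruments(outcome_gwas, None, ld, ld_snp_ids, config)
    if len(disease_iv) == 0:
        return BidirectionalResult(
            protein_id, outcome_id, 0, None, None, None, False, reason="no_instruments"
        )
    try:
        pairs = kept_pairs(harmonize(disease_iv.snps, protein_gwas))
    except ValueError:
        pairs = []
    if not pairs:
        return BidirectionalResult(
            protein_id, outcome_id, 0, None, None, None, False, reason="no_overlap"
        )

    if len(pairs) == 1:
        fit = wald_ratio(pairs[0], outcome_id, protein_id)
    else:
        fit = ivw(pairs, outcome_id, protein_id)
    p_egger = None
    if len(pairs) >= 3:
        p_egger = mr_egger(pairs, outcome_id, protein_id).pval
    p_primary = p_egger if (primary == "egger" and p_egger is not None) else fit.pval
    return BidirectionalResult(
        protein_id=protein_id,
        outcome_id=outcome_id,
        n_instruments=len(pairs),
        reverse_beta=fit.beta_mr,
        reverse_p_ivw=fit.pval,
        reverse_p_egger=p_egger,
        reverse_causal=bool(p_primary < alpha),
    )
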