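"""Two-sample Mendelian randomization estimators.

A protein instrumented by a single cis SNP is analysed with the Wald
ratio (outcome effect over exposure effect); two or more instruments are
combined by fixed-effect inverse-variance weighting of the per-SNP
ratios, with Cochran's Q for heterogeneity. MR-Egger (weighted regression
with an intercept) screens for directional pleiotropy when at least three
instruments are available. Estimates are log odds ratios per SD increase
in genetically predicted protein level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from pqtlmr.sumstats import HarmonizedPair

#: z for a two-sided 95% interval
Z95 = 1.959964

WALD_RATIO = "wald_ratio"
IVW = "ivw"
MR_EGGER = "mr_egger"

_TINY_P = 5e-324  # keep p-values inside (0, 1] when the normal tail underflows


def _two_sided_p(z: float) -> float:
    return max(2.0 * stats.norm.sf(abs(z)), _TINY_P)


@dataclass
class MrResult:
    """Causal estimate for one protein–outcome pair."""

    protein_id: str
    outcome_id: str
    method: str
    n_snps: int
    snp_ids: list[str]
    beta_mr: float
    se_mr: float
    pval: float
    q_stat: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_p: float | None = None

    @property
    def or_point(self) -> float:
        return math.exp(self.beta_mr)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta_mr - Z95 * self.se_mr)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta_mr + Z95 * self.se_mr)


@dataclass
class MultipleTestDecision:
    """Bonferroni family-wise decision over a set of MR results."""

    n_tests: int
    alpha_family: float
    threshold: float
    significant_ids: list[str] = field(default_factory=list)


@dataclass
class ReplicationOutcome:
    """External-validation verdict for one discovery result."""

    replicated: bool
    strategy_used: str
    beta_rep: float | None = None
    se_rep: float | None = None
    pval_rep: float | None = None
    direction_consistent: bool = False
    n_snps: int = 0
    reason: str = ""


def _ratio(pair: HarmonizedPair, second_order: bool = False) -> tuple[float, float]:
    bx, by = pair.exposure.beta, pair.outcome.beta
    if bx == 0.0:
        raise ZeroDivisionError(
            f"Wald ratio undefined for SNP {pair.snp_id}: exposure beta is 0"
        )
    beta = by / bx
    se = pair.outcome.se / abs(bx)
    if second_order:
        se = math.sqrt(
            pair.outcome.se**2 / bx**2 + by**2 * pair.exposure.se**2 / bx**4
        )
    return beta, se


def wald_ratio(
    pair: HarmonizedPair,
    protein_id: str = "",
    outcome_id: str = "",
    second_order: bool = False,
) -> MrResult:
    """Single-instrument causal estimate β_out/β_exp.

    The default first-order SE, se_out/|β_exp|, ignores exposure-side
    noise — negligible for F > 10 instruments; ``second_order=True`` adds
    the exposure-variance delta-method term.
    """
    beta, se = _ratio(pair, second_order)
    return MrResult(
        protein_id=protein_id,
        outcome_id=outcome_id,
        method=WALD_RATIO,
        n_snps=1,
        snp_ids=[pair.snp_id],
        beta_mr=beta,
        se_mr=se,
        pval=_two_sided_p(beta / se),
    )


def ivw(
    pairs: Sequence[HarmonizedPair],
    protein_id: str = "",
    outcome_id: str = "",
    random_effects: bool = False,
) -> MrResult:
    """Fixed-effect inverse-variance weighted estimate over per-SNP Wald ratios.

    Equivalent to a weighted least-squares regression of outcome on
    exposure betas through the origin with weights 1/se_out². Cochran's Q
    (chi-square, k−1 df) measures ratio heterogeneity; with
    ``random_effects=True`` the SE is inflated by √(max(1, Q/(k−1)))
    (multiplicative random-effects model).
    """
    if len(pairs) < 2:
        raise ValueError("ivw requires ≥ 2 instruments; use wald_ratio for one")
    betas, ses = zip(*(_ratio(p) for p in pairs))
    b = np.asarray(betas)
    w = 1.0 / np.asarray(ses) ** 2
    beta_mr = float(np.sum(w * b) / np.sum(w))
    se_mr = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (b - beta_mr) ** 2))
    k = len(pairs)
    q_pval = float(stats.chi2.sf(q, k - 1))
    if random_effects:
        se_mr *= math.sqrt(max(1.0, q / (k - 1)))
    return MrResult(
        protein_id=protein_id,
        outcome_id=outcome_id,
        method=IVW,
        n_snps=k,
        snp_ids=[p.snp_id for p in pairs],
        beta_mr=beta_mr,
        se_mr=se_mr,
        pval=_two_sided_p(beta_mr / se_mr),
        q_stat=q,
        q_pval=q_pval,
    )


def mr_egger(
    pairs: Sequence[HarmonizedPair],
    protein_id: str = "",
    outcome_id: str = "",
) -> MrResult:
    """Weighted regression of outcome on exposure betas with an intercept.

    SNPs are oriented so every exposure beta is positive before fitting
    (the fit is invariant to re-orientation). The intercept estimates
    average directional pleiotropy; inference is t-based with k−2 df.
    """
    if len(pairs) < 3:
        raise ValueError("mr_egger requires ≥ 3 instruments")
    sign = np.array([1.0 if p.exposure.beta >= 0 else -1.0 for p in pairs])
    x = sign * np.array([p.exposure.beta for p in pairs])
    y = sign * np.array([p.outcome.beta for p in pairs])
    w = 1.0 / np.array([p.outcome.se for p in pairs]) ** 2
    model = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return MrResult(
        protein_id=protein_id,
        outcome_id=outcome_id,
        method=MR_EGGER,
        n_snps=len(pairs),
        snp_ids=[p.snp_id for p in pairs],
        beta_mr=float(model.params[1]),
        se_mr=float(model.bse[1]),
        pval=float(max(model.pvalues[1], _TINY_P)),
        egger_intercept=float(model.params[0]),
        egger_intercept_p=float(max(model.pvalues[0], _TINY_P)),
    )


def bonferroni(
    results: Sequence[MrResult], alpha: float = 0.05, n_tests: int | None = None
) -> MultipleTestDecision:
    """Family-wise correction at threshold alpha/n_tests (strict <).

    ``n_tests`` is the number of proteins attempted — not the number of
    successful fits — so a protein whose fit failed still counts against
    the family.
    """
    if n_tests is None:
        n_tests = len(results)
    if n_tests < 1:
        raise ValueError("n_tests must be ≥ 1")
    threshold = alpha / n_tests
    significant = [r.protein_id for r in results if r.pval < threshold]
    return MultipleTestDecision(n_tests, alpha, threshold, significant)


def replicate(
    discovery: MrResult,
    replication_pairs: Sequence[HarmonizedPair],
    strategy: str = "same_variant",
    alpha: float = 0.05,
    p_significant: float = 5e-8,
) -> ReplicationOutcome:
    """Test a discovery result in an independent exposure/outcome dataset.

    ``same_variant`` re-uses exactly the discovery SNP ids present in the
    replication set; ``significant_variant`` re-selects instruments from
    the replication exposure at the genome-wide threshold. Replication
    requires p < alpha with a direction consistent with discovery.
    """
    usable = [p for p in replication_pairs if p.kept]
    if strategy == "same_variant":
        chosen = [p for p in usable if p.snp_id in set(discovery.snp_ids)]
        if not chosen:
            return ReplicationOutcome(False, strategy, reason="no_overlap")
    elif strategy == "significant_variant":
        chosen = [p for p in usable if p.exposure.pval < p_significant]
        if not chosen:
            return ReplicationOutcome(False, strategy, reason="no_significant_instruments")
    else:
        raise ValueError(f"unknown replication strategy {strategy!r}")

    if len(chosen) == 1:
        fit = wald_ratio(chosen[0], discovery.protein_id, discovery.outcome_id)
    else:
        fit = ivw(chosen, discovery.protein_id, discovery.outcome_id)
    direction_ok = math.copysign(1.0, fit.beta_mr) == math.copysign(1.0, discovery.beta_mr)
    return ReplicationOutcome(
        replicated=bool(fit.pval < alpha and direction_ok),
        strategy_used=strategy,
        beta_rep=fit.beta_mr,
        se_rep=fit.se_mr,
        pval_rep=fit.pval,
        direction_consistent=direction_ok,
        n_snps=fit.n_snps,
    )
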