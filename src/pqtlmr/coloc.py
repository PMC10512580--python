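"""Bayesian colocalization under the single-causal-variant assumption.

For a cis region with summary statistics for two traits (protein level,
quantitative; disease, binary), five hypotheses are compared: H0 no
causal variant for either trait; H1/H2 a causal variant for trait 1/2
only; H3 distinct causal variants; H4 a single shared causal variant.
Per-SNP evidence is the Wakefield approximate Bayes factor
log ABF = ½·(log(1−r) + r·z²) with r = W/(V+W), V = se², W the effect
prior variance (prior SD 0.15·sdY for the quantitative trait, 0.2 on the
log-OR scale for the binary trait). Per-SNP prior probabilities default
to p1 = p2 = 1e-4, p12 = 1e-5. A region colocalizes when PPH4 ≥ 0.8.

All sums run in log space; the H3 term exp(S1+S2) − exp(S12) uses a
stable log-difference floored at −∞ (it is exactly −∞ for a single-SNP
region, where two distinct causal variants are impossible).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
PRIOR_SD_QUANTITATIVE = 0.15
PRIOR_SD_BINARY = 0.2
PPH4_THRESHOLD = 0.8


@dataclass
class RegionData:
    """Aligned per-SNP summary statistics for two traits over one cis region."""

    protein_id: str
    outcome_id: str
    snp_ids: list[str]
    beta1: np.ndarray  # protein (quantitative, SD units)
    se1: np.ndarray
    beta2: np.ndarray  # disease (log-OR)
    se2: np.ndarray
    sdY: float = 1.0
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.se1 = np.asarray(self.se1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.se2 = np.asarray(self.se2, dtype=float)
        m = len(self.snp_ids)
        for name in ("beta1", "se1", "beta2", "se2"):
            if getattr(self, name).shape != (m,):
                raise ValueError(f"RegionData: {name} length does not match snp_ids ({m})")
        if m == 0:
            raise ValueError("RegionData: empty region")
        if np.any(self.se1 <= 0) or np.any(self.se2 <= 0):
            raise ValueError("RegionData: standard errors must be positive")


@dataclass
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    protein_id: str
    outcome_id: str
    n_snps: int
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    priors: tuple[float, float, float] = (DEFAULT_P1, DEFAULT_P2, DEFAULT_P12)

    @property
    def colocalized(self) -> bool:
        return self.pph4 >= PPH4_THRESHOLD

    def as_dict(self) -> dict[str, float]:
        return {
            "pph0": self.pph0,
            "pph1": self.pph1,
            "pph2": self.pph2,
            "pph3": self.pph3,
            "pph4": self.pph4,
        }


def log_abf(beta, se, prior_sd: float):
    """Wakefield log approximate Bayes factor for one SNP (vectorized).

    With z = β/se, V = se² and W = prior_sd²: ½·(log(1−r) + r·z²) where
    r = W/(V+W). Positive values favour association.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("log_abf requires se > 0 and prior_sd > 0")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) − exp(b)), −∞ when a ≤ b (within rounding)."""
    if a <= b:
        return -math.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(
    region: RegionData,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_sd_quant: float = PRIOR_SD_QUANTITATIVE,
    prior_sd_binary: float = PRIOR_SD_BINARY,
) -> ColocResult:
    """Posterior probabilities PPH0–PPH4 for one region.

    Unnormalized log weights: H0 = 0; H1 = log p1 + S1; H2 = log p2 + S2;
    H3 = log p1 + log p2 + log(e^{S1+S2} − e^{S12}); H4 = log p12 + S12,
    where S1, S2, S12 are log-sum-exp of the per-SNP log-ABFs (and their
    per-SNP sums). Posteriors normalize to 1.
    """
    l1 = log_abf(region.beta1, region.se1, prior_sd_quant * region.sdY)
    l2 = log_abf(region.beta2, region.se2, prior_sd_binary)
    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))

    log_w = np.array(
        [
            0.0,
            math.log(p1) + s1,
            math.log(p2) + s2,
            math.log(p1) + math.log(p2) + _log_diff_exp(s1 + s2, s12),
            math.log(p12) + s12,
        ]
    )
    post = np.exp(log_w - logsumexp(log_w))
    post /= post.sum()
    return ColocResult(
        protein_id=region.protein_id,
        outcome_id=region.outcome_id,
        n_snps=len(region.snp_ids),
        pph0=float(post[0]),
        pph1=float(post[1]),
        pph2=float(post[2]),
        pph3=float(post[3]),
        pph4=float(post[4]),
        priors=(p1, p2, p12),
    )


def region_from_records(
    exposure, outcome, protein_id: str = "", outcome_id: str = "", sdY: float = 1.0
) -> RegionData:
    """Build a RegionData from aligned exposure/outcome GwasRecord lists."""
    out_by_id = {r.snp_id: r for r in outcome}
    exp = [r for r in exposure if r.snp_id in out_by_id]
    if not exp:
        raise ValueError("region_from_records: no shared SNPs")
    out = [out_by_id[r.snp_id] for r in exp]
    case_fraction = out[0].case_fraction
    return RegionData(
        protein_id=protein_id or "",
        outcome_id=outcome_id or "",
        snp_ids=[r.snp_id for r in exp],
        beta1=np.array([r.beta for r in exp]),
        se1=np.array([r.se for r in exp]),
        beta2=np.array([r.beta for r in out]),
        se2=np.array([r.se for r in out]),
        sdY=sdY,
        case_fraction=case_fraction,
    )


def coloc_recovery_study(
    template,
    n_reps: int = 200,
    scenarios: Sequence[str] = ("shared_causal", "distinct_causal", "null"),
    seed: int = 0,
) -> pd.DataFrame:
    """Calibration of the PPH4 ≥ 0.8 rule over synthetic scenarios.

    For each scenario, simulates ``n_reps`` independent regions from the
    template configuration and tabulates mean PPH3/PPH4 and the fraction
    of replicates crossing the colocalization threshold.
    """
    from dataclasses import replace as dc_replace

    from pqtlmr.simulate import simulate_region

    rng = np.random.default_rng(seed)
    rows = []
    for scenario in scenarios:
        pph3 = np.empty(n_reps)
        pph4 = np.empty(n_reps)
        for i in range(n_reps):
            cfg = dc_replace(template, scenario=scenario, seed=int(rng.integers(2**31)))
            region = simulate_region(cfg)
            data = region_from_records(
                region.exposure, region.outcome, cfg.protein_id, cfg.outcome_id
            )
            result = coloc_abf(data)
            pph3[i] = result.pph3
            pph4[i] = result.pph4
        rows.append(
            {
                "scenario": scenario,
                "n_reps": n_reps,
                "mean_pph3": float(pph3.mean()),
                "mean_pph4": float(pph4.mean()),
                "frac_pph4_ge_threshold": float(np.mean(pph4 >= PPH4_THRESHOLD)),
            }
        )
    return pd.DataFrame(rows)
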