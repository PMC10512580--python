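"""Synthetic GWAS/pQTL summary statistics with known ground truth.

Regions are simulated directly on the summary level from the standard
multivariate-normal approximation: given per-SNP joint effects γ and an
LD correlation matrix R (AR(1): r_ij = ρ^|i−j|), the observed marginal
effect estimates are drawn as

    β̂ ~ MVN(R·γ, se²·R),

with se = 1/√n on the standardized quantitative scale and
se = 1/√(n·φ(1−φ)) on the log-OR scale for a binary trait with case
fraction φ (constant-information approximation). No individual-level
genotypes are generated — sufficient for every downstream statistic.

Scenarios
---------
* ``shared_causal`` — one cis variant drives the protein (per-allele
  effect b) and, through a causal protein effect θ (log-OR per SD), the
  disease: outcome joint effects are θ·γ.
* ``exposure_only`` — cis pQTL present, no disease effect (θ = 0).
* ``null`` — no signal on either side.
* ``distinct_causal`` — protein and disease have different causal
  variants in the region.
* ``reverse_causation`` — a disease variant in the region (effect d)
  shifts the protein by reverse_theta per unit of disease liability;
  the apparent cis pQTL is really a disease locus.

Each region also carries a panel of genome-wide disease instruments on
other chromosomes (LD-free). Under reverse causation the protein responds
to these (betas = reverse_theta × disease betas); otherwise the protein
side at these loci is pure noise. They feed bidirectional MR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cholesky, toeplitz

from pqtlmr.instruments import GeneAnnotation
from pqtlmr.sumstats import CASE_CONTROL, QUANTITATIVE, GwasRecord

SHARED_CAUSAL = "shared_causal"
DISTINCT_CAUSAL = "distinct_causal"
NULL = "null"
EXPOSURE_ONLY = "exposure_only"
REVERSE_CAUSATION = "reverse_causation"
SCENARIOS = (SHARED_CAUSAL, DISTINCT_CAUSAL, NULL, EXPOSURE_ONLY, REVERSE_CAUSATION)

_TINY_P = 5e-324


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth configuration for one simulated cis region.

    Defaults emulate the study conditions: a protein measured in a pQTL
    GWAS of 10,000 (discovery scale), a cancer GWAS of 100,000 with a
    balanced case fraction, one causal cis variant explaining ~9% of
    protein variance (b = 0.3 per allele, SD units), moderate AR(1) LD
    (ρ = 0.5) over a 100-SNP region, and a causal effect θ = 0.2 log-OR
    per SD of protein.
    """

    m_snps: int = 100
    ld_rho: float = 0.5
    n_exposure: int = 10_000
    n_outcome: int = 100_000
    case_fraction: float = 0.5
    theta: float = 0.2
    scenario: str = SHARED_CAUSAL
    causal_index: int | None = None  # default: middle of the region
    causal_index_2: int | None = None  # distinct_causal second variant
    exposure_effect_b: float = 0.3
    outcome_effect_d: float = 0.3  # per-allele log-OR for distinct/reverse variants
    reverse_theta: float = 0.3  # protein shift per unit disease liability
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int | None = None
    chrom: str = "1"
    tss_pos: int = 50_000_000
    snp_spacing_bp: int = 2_000
    protein_id: str = "PROT1"
    outcome_id: str = "cancer"
    n_disease_instruments: int = 20
    disease_effect_range: tuple[float, float] = (0.05, 0.15)
    #: override for multiple independent exposure causal SNPs (estimator
    #: calibration); the default remains a single causal cis variant
    exposure_causal_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must be in [0, 1) for a positive-definite AR(1) LD "
                             f"matrix, got {self.ld_rho}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.m_snps < 1:
            raise ValueError("m_snps must be ≥ 1")
        for idx in (self.causal_index, self.causal_index_2):
            if idx is not None and not (0 <= idx < self.m_snps):
                raise ValueError(f"causal index {idx} outside region of {self.m_snps} SNPs")
        if self.scenario == DISTINCT_CAUSAL and self.ci1 == self.ci2:
            raise ValueError("distinct_causal requires two distinct causal indices")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 < self.case_fraction < 1.0):
            raise ValueError("case_fraction must be in (0, 1)")

    @property
    def ci1(self) -> int:
        return self.m_snps // 2 if self.causal_index is None else self.causal_index

    @property
    def ci2(self) -> int:
        if self.causal_index_2 is not None:
            return self.causal_index_2
        # default second variant: far enough for AR(1) correlation to vanish
        return self.m_snps // 5 if self.ci1 != self.m_snps // 5 else 0


@dataclass
class SyntheticRegion:
    """One simulated cis region plus genome-wide disease instruments."""

    snp_ids: list[str]
    ld: np.ndarray
    exposure: list[GwasRecord]
    outcome: list[GwasRecord]
    disease_instruments: list[GwasRecord]  # disease GWAS at genome-wide loci
    protein_at_disease_instruments: list[GwasRecord]
    truth: ScenarioConfig

    def __eq__(self, other: object) -> bool:  # byte-identical reproducibility check
        if not isinstance(other, SyntheticRegion):
            return NotImplemented
        return (
            self.snp_ids == other.snp_ids
            and np.array_equal(self.ld, other.ld)
            and self.exposure == other.exposure
            and self.outcome == other.outcome
            and self.disease_instruments == other.disease_instruments
            and self.protein_at_disease_instruments == other.protein_at_disease_instruments
            and self.truth == other.truth
        )


def ar1_ld(m_snps: int, rho: float) -> np.ndarray:
    """AR(1) LD correlation matrix r_ij = ρ^|i−j| (positive definite for ρ < 1)."""
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"AR(1) LD requires 0 ≤ rho < 1, got {rho}")
    return toeplitz(rho ** np.arange(m_snps))


def _pvals(z: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), _TINY_P)


def _joint_effects(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP joint effects (γ exposure, δ outcome) for the scenario."""
    m = config.m_snps
    gamma = np.zeros(m)
    delta = np.zeros(m)
    exposure_indices = (
        config.exposure_causal_indices
        if config.exposure_causal_indices is not None
        else (config.ci1,)
    )
    if config.scenario in (SHARED_CAUSAL, EXPOSURE_ONLY):
        for i in exposure_indices:
            gamma[i] = config.exposure_effect_b
        if config.scenario == SHARED_CAUSAL:
            delta = config.theta * gamma
    elif config.scenario == DISTINCT_CAUSAL:
        for i in exposure_indices:
            gamma[i] = config.exposure_effect_b
        delta[config.ci2] = config.outcome_effect_d
    elif config.scenario == REVERSE_CAUSATION:
        delta[config.ci1] = config.outcome_effect_d
        gamma = config.reverse_theta * delta
    # NULL: both stay zero
    return gamma, delta


def _alt_chroms(chrom: str) -> list[str]:
    """Chromosome labels for genome-wide disease loci: off the cis chromosome and chr6."""
    return [str(c) for c in range(1, 23) if str(c) != chrom and c != 6]


def simulate_region(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> SyntheticRegion:
    """Draw one region of exposure/outcome summary statistics.

    Fully reproducible for a fixed ``config.seed`` (or caller-supplied rng).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.m_snps
    ld = ar1_ld(m, config.ld_rho)
    chol_lower = cholesky(ld, lower=True)

    gamma, delta = _joint_effects(config)
    se_exp = 1.0 / np.sqrt(config.n_exposure)
    phi = config.case_fraction
    se_out = 1.0 / np.sqrt(config.n_outcome * phi * (1.0 - phi))

    beta_exp = ld @ gamma + chol_lower @ rng.standard_normal(m) * se_exp
    beta_out = ld @ delta + chol_lower @ rng.standard_normal(m) * se_out
    eaf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    p_exp = _pvals(beta_exp / se_exp)
    p_out = _pvals(beta_out / se_out)

    snp_ids = [f"rs_{config.protein_id}_{i:04d}" for i in range(m)]
    positions = [config.tss_pos + (i - m // 2) * config.snp_spacing_bp for i in range(m)]

    exposure = [
        GwasRecord(
            snp_ids[i], config.chrom, positions[i], "A", "G", float(eaf[i]),
            float(beta_exp[i]), se_exp, float(p_exp[i]), float(config.n_exposure),
            QUANTITATIVE,
        )
        for i in range(m)
    ]
    outcome = [
        GwasRecord(
            snp_ids[i], config.chrom, positions[i], "A", "G", float(eaf[i]),
            float(beta_out[i]), se_out, float(p_out[i]), float(config.n_outcome),
            CASE_CONTROL, phi,
        )
        for i in range(m)
    ]

    # genome-wide disease instruments on other chromosomes, LD-free
    disease: list[GwasRecord] = []
    protein_side: list[GwasRecord] = []
    chroms = _alt_chroms(config.chrom)
    reverse = config.scenario == REVERSE_CAUSATION
    for j in range(config.n_disease_instruments):
        d_j = rng.uniform(*config.disease_effect_range) * rng.choice([-1.0, 1.0])
        b_dis = d_j + rng.standard_normal() * se_out
        b_prot = (config.reverse_theta * d_j if reverse else 0.0) + (
            rng.standard_normal() * se_exp
        )
        freq = float(rng.uniform(config.maf_range[0], config.maf_range[1]))
        sid = f"rs_{config.protein_id}_gw{j:03d}"
        chrom_j = chroms[j % len(chroms)]
        pos_j = 10_000_000 + j * 1_000_000
        disease.append(
            GwasRecord(sid, chrom_j, pos_j, "A", "G", freq, float(b_dis), se_out,
                       float(_pvals(np.array([b_dis / se_out]))[0]),
                       float(config.n_outcome), CASE_CONTROL, phi)
        )
        protein_side.append(
            GwasRecord(sid, chrom_j, pos_j, "A", "G", freq, float(b_prot), se_exp,
                       float(_pvals(np.array([b_prot / se_exp]))[0]),
                       float(config.n_exposure), QUANTITATIVE)
        )

    return SyntheticRegion(snp_ids, ld, exposure, outcome, disease, protein_side, config)


@dataclass
class ProteinStudy:
    """Discovery and replication data for one simulated protein."""

    protein_id: str
    gene: GeneAnnotation
    discovery: SyntheticRegion
    replication: SyntheticRegion
    theta: float
    scenario: str


@dataclass
class StudyBundle:
    """A desk-scale analog of a proteome-wide MR study with known truth."""

    proteins: list[ProteinStudy]
    outcome_id: str
    seed: int
    ppi_edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["protein_a", "protein_b", "combined_score"])
    )
    drug_map: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["drug", "target", "indication"])
    )
    annotation: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "trait", "p"])
    )

    def truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein": p.protein_id,
                    "scenario": p.scenario,
                    "theta": p.theta,
                    "chrom": p.gene.chrom,
                    "tss": p.gene.tss_pos,
                }
                for p in self.proteins
            ]
        )


def simulate_proteome(
    n_proteins: int,
    fraction_causal: float,
    template: ScenarioConfig | None = None,
    seed: int = 0,
    theta_range: tuple[float, float] = (0.15, 0.35),
    n_reverse: int = 0,
    replication_n_exposure: int = 35_559,
    replication_n_outcome: int = 100_000,
) -> StudyBundle:
    """Generate a full discovery + replication study with ground truth.

    ``fraction_causal`` of the proteins receive a causal effect θ with
    magnitude drawn uniformly from ``theta_range`` and random sign; the
    rest have a cis pQTL but no disease effect (θ = 0). ``n_reverse``
    proteins (taken from the non-causal set) follow the reverse-causation
    scenario instead. The replication copy redraws all noise independently
    with its own sample sizes (defaults sized after a large replication
    pQTL study and biobank outcome GWAS).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be ≥ 1")
    template = template or ScenarioConfig()
    rng = np.random.default_rng(seed)
    n_causal = int(round(n_proteins * fraction_causal))
    roles = [SHARED_CAUSAL] * n_causal + [EXPOSURE_ONLY] * (n_proteins - n_causal)
    for i in range(min(n_reverse, n_proteins - n_causal)):
        roles[n_causal + i] = REVERSE_CAUSATION
    rng.shuffle(roles)

    chroms = [str(c) for c in range(1, 23) if c != 6]
    proteins: list[ProteinStudy] = []
    for i, scenario in enumerate(roles):
        pid = f"P{i:03d}"
        theta = 0.0
        if scenario == SHARED_CAUSAL:
            theta = float(rng.uniform(*theta_range) * rng.choice([-1.0, 1.0]))
        chrom = chroms[i % len(chroms)]
        tss = 50_000_000 + (i // len(chroms)) * 5_000_000
        base = replace(
            template,
            protein_id=pid,
            chrom=chrom,
            tss_pos=tss,
            scenario=scenario,
            theta=theta,
            seed=int(rng.integers(2**31)),
        )
        discovery = simulate_region(base)
        replication_cfg = replace(
            base,
            n_exposure=replication_n_exposure,
            n_outcome=replication_n_outcome,
            seed=int(rng.integers(2**31)),
        )
        replication = simulate_region(replication_cfg)
        gene = GeneAnnotation(f"GENE_{pid}", pid, chrom, tss)
        proteins.append(ProteinStudy(pid, gene, discovery, replication, theta, scenario))
    return StudyBundle(proteins=proteins, outcome_id=template.outcome_id, seed=seed)
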