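"""cis-pQTL instrument selection.

Instruments for each protein are chosen by five sequential criteria:
(I) genome-wide significance (P < 5e-8), (II) exclusion of the MHC region
(chr6, 26–34 Mb — extreme LD and gene density), (IV) cis location (within
±1 Mb of the encoding gene's TSS), (III) LD clumping (pairwise r² < 0.001
within a 10 Mb window, keeping the most significant SNP per clump) and
(V) instrument strength F > 10 to limit weak-instrument bias.

Strength statistics per SNP: PVE = β² / (β² + n·se²) and
F = PVE·(n−2)/(1−PVE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pqtlmr.sumstats import GwasRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    """Location of the gene encoding a protein (for the cis filter)."""

    gene_id: str
    protein_id: str
    chrom: str
    tss_pos: int


@dataclass
class InstrumentConfig:
    """Thresholds for the five selection criteria (defaults as used study-wide)."""

    p_threshold: float = 5e-8
    mhc_chrom: str = "6"
    mhc_start: int = 26_000_000
    mhc_end: int = 34_000_000
    r2_threshold: float = 0.001
    clump_window_bp: int = 10_000_000
    cis_window_bp: int = 1_000_000
    f_min: float = 10.0
    pve_method: str = "se"  # "se": beta²/(beta²+n·se²); "eaf": 2·maf(1−maf)·beta²


@dataclass
class InstrumentSet:
    """Selected instruments for one protein with per-SNP strength statistics.

    ``provenance`` logs the count surviving each filter step.
    """

    protein_id: str
    snps: list[GwasRecord] = field(default_factory=list)
    pve: list[float] = field(default_factory=list)
    f_stat: list[float] = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.snps]


def filter_significant(
    records: Sequence[GwasRecord], threshold: float = 5e-8
) -> list[GwasRecord]:
    """Criterion I: keep SNPs with P strictly below the significance threshold."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"p threshold must be in (0, 1], got {threshold}")
    return [r for r in records if r.pval < threshold]


def filter_mhc(
    records: Sequence[GwasRecord],
    chrom: str = "6",
    start: int = 26_000_000,
    end: int = 34_000_000,
) -> list[GwasRecord]:
    """Criterion II: drop SNPs inside the MHC region (inclusive endpoints)."""
    return [r for r in records if not (r.chrom == chrom and start <= r.pos <= end)]


def filter_cis(
    records: Sequence[GwasRecord],
    gene: GeneAnnotation,
    cis_window_bp: int = 1_000_000,
) -> list[GwasRecord]:
    """Criterion IV: keep SNPs on the gene's chromosome within ±window of the TSS."""
    return [
        r
        for r in records
        if r.chrom == gene.chrom and abs(r.pos - gene.tss_pos) <= cis_window_bp
    ]


def ld_clump(
    records: Sequence[GwasRecord],
    ld: np.ndarray,
    r2_threshold: float = 0.001,
    window_bp: int = 10_000_000,
) -> list[GwasRecord]:
    """Criterion III: greedy LD clumping on a correlation matrix aligned to ``records``.

    SNPs are visited by ascending p-value (ties broken by chromosome,
    position, then id); a SNP is accepted iff its r² with every
    already-accepted SNP within ``window_bp`` on the same chromosome is
    strictly below ``r2_threshold``.
    """
    records = list(records)
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (len(records), len(records)):
        raise ValueError(
            f"LD matrix shape {ld.shape} does not match {len(records)} records"
        )
    order = sorted(
        range(len(records)),
        key=lambda i: (records[i].pval, records[i].chrom, records[i].pos, records[i].snp_id),
    )
    accepted: list[int] = []
    for i in order:
        ok = True
        for j in accepted:
            same_chrom = records[i].chrom == records[j].chrom
            near = abs(records[i].pos - records[j].pos) <= window_bp
            if same_chrom and near and ld[i, j] ** 2 >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(i)
    accepted.sort()
    return [records[i] for i in accepted]


def snp_strength(record: GwasRecord, method: str = "se") -> tuple[float, float]:
    """Proportion of variance explained and F-statistic for one instrument.

    The default se-based PVE, β²/(β² + n·se²), needs no allele frequency.
    The eaf-based alternative 2·maf(1−maf)·β² assumes a standardized trait
    and requires ``record.eaf``.
    """
    if record.n < 3:
        raise ValueError(f"{record.snp_id}: n must be ≥ 3 for strength statistics")
    if method == "se":
        b2 = record.beta**2
        pve = b2 / (b2 + record.n * record.se**2)
    elif method == "eaf":
        if record.eaf is None:
            raise ValueError(f"{record.snp_id}: eaf-based PVE requires eaf")
        maf = min(record.eaf, 1.0 - record.eaf)
        pve = min(2.0 * maf * (1.0 - maf) * record.beta**2, 1.0 - 1e-12)
    else:
        raise ValueError(f"unknown pve method {method!r}")
    f_stat = pve * (record.n - 2) / (1.0 - pve)
    return pve, f_stat


def build_instruments(
    records: Sequence[GwasRecord],
    gene: GeneAnnotation | None,
    ld: np.ndarray | None,
    ld_snp_ids: Sequence[str] | None,
    config: InstrumentConfig | None = None,
) -> InstrumentSet:
    """Compose the five filters in order: significance, MHC, cis, clump, strength.

    ``gene=None`` disables the cis filter (used for genome-wide disease
    instruments in bidirectional MR). ``ld=None`` treats all SNPs as
    independent. Zero survivors is not an error: the protein is simply
    skipped downstream (empty set with full provenance).
    """
    config = config or InstrumentConfig()
    protein_id = gene.protein_id if gene is not None else ""
    provenance = {"input": len(records)}

    kept = filter_significant(records, config.p_threshold)
    provenance["significant"] = len(kept)
    kept = filter_mhc(kept, config.mhc_chrom, config.mhc_start, config.mhc_end)
    provenance["mhc"] = len(kept)
    if gene is not None:
        kept = filter_cis(kept, gene, config.cis_window_bp)
    provenance["cis"] = len(kept)

    if ld is not None and kept:
        if ld_snp_ids is None:
            raise ValueError("ld_snp_ids required when an LD matrix is supplied")
        index = {sid: i for i, sid in enumerate(ld_snp_ids)}
        try:
            rows = [index[r.snp_id] for r in kept]
        except KeyError as exc:
            raise ValueError(f"SNP {exc} missing from LD matrix header") from exc
        sub = np.asarray(ld, dtype=float)[np.ix_(rows, rows)]
    else:
        sub = np.eye(len(kept))
    kept = ld_clump(kept, sub, config.r2_threshold, config.clump_window_bp)
    provenance["clump"] = len(kept)

    final: list[GwasRecord] = []
    pves: list[float] = []
    fs: list[float] = []
    for rec in kept:
        pve, f = snp_strength(rec, config.pve_method)
        if f > config.f_min:  # strict: F exactly at the bound is rejected
            final.append(rec)
            pves.append(pve)
            fs.append(f)
    provenance["strength"] = len(final)

    if not final:
        logger.info("build_instruments(%s): no instruments survive %s", protein_id, provenance)
    return InstrumentSet(protein_id, final, pves, fs, provenance)


def read_ld_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a whitespace-delimited square LD matrix with a first-line SNP-id header."""
    with open(path) as fh:
        header = fh.readline().split()
        matrix = np.loadtxt(fh)
    matrix = np.atleast_2d(matrix)
    if matrix.shape != (len(header), len(header)):
        raise ValueError(
            f"{path}: matrix shape {matrix.shape} does not match header of {len(header)} ids"
        )
    return matrix, header


def write_ld_matrix(path, matrix: np.ndarray, snp_ids: Sequence[str]) -> None:
    matrix = np.asarray(matrix)
    if matrix.shape != (len(snp_ids), len(snp_ids)):
        raise ValueError("matrix shape does not match snp ids")
    with open(path, "w") as fh:
        fh.write(" ".join(snp_ids) + "\n")
        np.savetxt(fh, matrix, fmt="%.6g")
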