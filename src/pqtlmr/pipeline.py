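"""End-to-end discovery → validation → tiering workflow.

Per protein × outcome the pipeline runs: cis instrument selection →
harmonization → Wald-ratio/IVW estimation (+ Cochran's Q) → Bonferroni
family decision → Steiger filtering → bidirectional MR (reverse-causal
proteins are excluded) → Bayesian colocalization → external replication
(same-variant and significant-variant strategies) → phenotype scanning →
PPI drug-target linkage → tier classification. Failures are isolated per
protein (skip-and-log): a proteome-wide run does not die on one
malformed region.

Bidirectional MR selects disease instruments from genome-wide disease
hits *outside* the protein's cis region: a shared cis causal variant
would otherwise drive the reverse test trivially in both directions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from pqtlmr._version import __version__ as _version
from pqtlmr.coloc import coloc_abf, region_from_records
from pqtlmr.direction import bidirectional_mr, steiger_test
from pqtlmr.instruments import (
    GeneAnnotation,
    InstrumentConfig,
    build_instruments,
    read_ld_matrix,
    write_ld_matrix,
)
from pqtlmr.mr import MrResult, bonferroni, ivw, replicate, wald_ratio
from pqtlmr.simulate import StudyBundle, simulate_proteome
from pqtlmr.sumstats import (
    CASE_CONTROL,
    GwasRecord,
    harmonize,
    kept_pairs,
    read_sumstats,
    records_to_frame,
)
from pqtlmr.tiering import TargetFlags, build_network, build_report, drug_link, phenotype_scan

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the workflow, with the study-wide defaults."""

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    clump_window_bp: int = 10_000_000
    cis_window_bp: int = 1_000_000
    f_min: float = 10.0
    mhc_chrom: str = "6"
    mhc_start: int = 26_000_000
    mhc_end: int = 34_000_000
    alpha_family: float = 0.05
    n_tests: int | None = None  # default: number of proteins attempted
    replication_alpha: float = 0.05
    bidirectional_alpha: float = 0.05
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pph4_min: float = 0.8
    ppi_min: float = 0.4
    risk_factors: list[str] = field(default_factory=list)
    outcome_id: str = "cancer"
    seed: int = 0

    def instrument_config(self) -> InstrumentConfig:
        return InstrumentConfig(
            p_threshold=self.p_threshold,
            mhc_chrom=self.mhc_chrom,
            mhc_start=self.mhc_start,
            mhc_end=self.mhc_end,
            r2_threshold=self.r2_threshold,
            clump_window_bp=self.clump_window_bp,
            cis_window_bp=self.cis_window_bp,
            f_min=self.f_min,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ProteinInputs:
    """Everything the pipeline needs for one protein."""

    protein_id: str
    gene: GeneAnnotation
    exposure: list[GwasRecord]
    outcome: list[GwasRecord]
    ld: np.ndarray | None
    ld_snp_ids: list[str] | None
    replication_exposure: list[GwasRecord] = field(default_factory=list)
    replication_outcome: list[GwasRecord] = field(default_factory=list)


@dataclass
class ResultsBundle:
    """All tabular outputs of one discovery run plus the run manifest."""

    mr_results: pd.DataFrame
    coloc_results: pd.DataFrame
    tier_report: pd.DataFrame
    manifest: dict


def inputs_from_bundle(bundle: StudyBundle) -> list[ProteinInputs]:
    """Adapt a synthetic study bundle to pipeline inputs."""
    inputs = []
    for p in bundle.proteins:
        inputs.append(
            ProteinInputs(
                protein_id=p.protein_id,
                gene=p.gene,
                exposure=p.discovery.exposure + p.discovery.protein_at_disease_instruments,
                outcome=p.discovery.outcome + p.discovery.disease_instruments,
                ld=p.discovery.ld,
                ld_snp_ids=list(p.discovery.snp_ids),
                replication_exposure=p.replication.exposure
                + p.replication.protein_at_disease_instruments,
                replication_outcome=p.replication.outcome + p.replication.disease_instruments,
            )
        )
    return inputs


def _in_cis(rec: GwasRecord, gene: GeneAnnotation, window: int) -> bool:
    return rec.chrom == gene.chrom and abs(rec.pos - gene.tss_pos) <= window


def run_discovery(
    inputs: Sequence[ProteinInputs],
    config: PipelineConfig | None = None,
    ppi_edges: pd.DataFrame | None = None,
    drug_map: pd.DataFrame | None = None,
    annotation: pd.DataFrame | None = None,
) -> ResultsBundle:
    """Execute the full workflow over a set of proteins against one outcome."""
    config = config or PipelineConfig()
    icfg = config.instrument_config()
    network = build_network(
        ppi_edges if ppi_edges is not None else pd.DataFrame(columns=["a", "b", "s"]),
        config.ppi_min,
    )
    drug_map = drug_map if drug_map is not None else pd.DataFrame(columns=["drug", "target", "indication"])
    annotation = annotation if annotation is not None else pd.DataFrame(columns=["snp", "trait", "p"])

    fits: list[MrResult] = []
    per_protein: dict[str, dict] = {}
    mr_rows: list[dict] = []
    attempted = 0
    for item in inputs:
        attempted += 1
        row = {"protein": item.protein_id, "outcome": config.outcome_id, "status": "ok"}
        try:
            iv = build_instruments(item.exposure, item.gene, item.ld, item.ld_snp_ids, icfg)
            if len(iv) == 0:
                row["status"] = "no_instruments"
                mr_rows.append(row)
                continue
            pairs = kept_pairs(harmonize(iv.snps, item.outcome))
            pairs = [p for p in pairs if p.snp_id in set(iv.snp_ids)]
            if not pairs:
                row["status"] = "no_outcome_overlap"
                mr_rows.append(row)
                continue
            if len(pairs) == 1:
                fit = wald_ratio(pairs[0], item.protein_id, config.outcome_id)
            else:
                fit = ivw(pairs, item.protein_id, config.outcome_id)
            fits.append(fit)
            per_protein[item.protein_id] = {"item": item, "iv": iv, "pairs": pairs, "fit": fit}
            row.update(
                snps=";".join(fit.snp_ids),
                method=fit.method,
                n_snps=fit.n_snps,
                beta=fit.beta_mr,
                se=fit.se_mr,
                odds_ratio=fit.or_point,
                ci_low=fit.ci_low,
                ci_high=fit.ci_high,
                pval=fit.pval,
                q_stat=fit.q_stat,
                q_pval=fit.q_pval,
                pve=float(sum(iv.pve)),
                f_stat=float(min(iv.f_stat)),
            )
        except Exception:  # per-protein isolation: log and continue
            logger.exception("pipeline: protein %s failed; skipping", item.protein_id)
            row["status"] = "error"
        mr_rows.append(row)

    decision = bonferroni(fits, config.alpha_family, config.n_tests or max(attempted, 1))
    significant = set(decision.significant_ids)

    coloc_rows: list[dict] = []
    tier_rows: list[dict] = []
    excluded_reverse: list[str] = []
    extra: dict[str, dict] = {}
    for pid in sorted(significant):
        state = per_protein[pid]
        item, iv, pairs, fit = state["item"], state["iv"], state["pairs"], state["fit"]
        try:
            steiger = steiger_test(iv, pairs, outcome_id=config.outcome_id)
            outcome_nocis = [
                r for r in item.outcome if not _in_cis(r, item.gene, config.cis_window_bp)
            ]
            bid = bidirectional_mr(
                outcome_nocis,
                item.exposure,
                icfg,
                alpha=config.bidirectional_alpha,
                protein_id=pid,
                outcome_id=config.outcome_id,
            )
            exp_cis = [r for r in item.exposure if _in_cis(r, item.gene, config.cis_window_bp)]
            region = region_from_records(exp_cis, item.outcome, pid, config.outcome_id)
            coloc = coloc_abf(region, config.coloc_p1, config.coloc_p2, config.coloc_p12)
            coloc_pass = coloc.pph4 >= config.pph4_min

            rep_same = rep_sig = None
            if item.replication_exposure and item.replication_outcome:
                rep_pairs = kept_pairs(
                    harmonize(item.replication_exposure, item.replication_outcome)
                )
                rep_same = replicate(
                    fit, rep_pairs, "same_variant", config.replication_alpha
                )
                rep_iv = build_instruments(
                    item.replication_exposure, item.gene, item.ld, item.ld_snp_ids, icfg
                )
                rep_pairs_clumped = [p for p in rep_pairs if p.snp_id in set(rep_iv.snp_ids)]
                rep_sig = replicate(
                    fit,
                    rep_pairs_clumped,
                    "significant_variant",
                    config.replication_alpha,
                    config.p_threshold,
                )
            replicated = bool(
                (rep_same and rep_same.replicated) or (rep_sig and rep_sig.replicated)
            )

            hits = phenotype_scan(iv.snp_ids, annotation, config.risk_factors)
            linked, links = drug_link(pid, network, drug_map, config.outcome_id)

            extra[pid] = {
                "steiger_p": steiger.steiger_p,
                "steiger_correct": steiger.correct_direction,
                "bidirectional_p_ivw": bid.reverse_p_ivw,
                "bidirectional_p_egger": bid.reverse_p_egger,
                "reverse_causal": bid.reverse_causal,
            }
            coloc_rows.append(
                {
                    "protein": pid,
                    "outcome": config.outcome_id,
                    "n_snps": coloc.n_snps,
                    **coloc.as_dict(),
                    "colocalized": coloc_pass,
                }
            )
            if bid.reverse_causal:
                excluded_reverse.append(pid)
                continue
            report = build_report(
                pid,
                config.outcome_id,
                TargetFlags(replicated, coloc_pass, linked),
                hits,
                links,
            )
            tier_rows.append(
                {
                    "protein": pid,
                    "outcome": config.outcome_id,
                    "replicated": replicated,
                    "replicated_same_variant": bool(rep_same and rep_same.replicated),
                    "replicated_significant_variant": bool(rep_sig and rep_sig.replicated),
                    "coloc_pass": coloc_pass,
                    "ppi_drug_link": linked,
                    "n_phenotype_hits": len(hits),
                    "pleiotropy_flagged": any(h.flagged_pleiotropic for h in hits),
                    "tier": report.tier,
                }
            )
        except Exception:
            logger.exception("pipeline: validation stage failed for %s; skipping", pid)

    mr_results = pd.DataFrame(mr_rows)
    if not mr_results.empty:
        mr_results["significant"] = mr_results["protein"].isin(significant)
        for col in (
            "steiger_p",
            "steiger_correct",
            "bidirectional_p_ivw",
            "bidirectional_p_egger",
            "reverse_causal",
        ):
            mr_results[col] = mr_results["protein"].map(
                {pid: vals[col] for pid, vals in extra.items()}
            )

    manifest = {
        "package": "pqtlmr",
        "version": _version,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "bonferroni_threshold": decision.threshold,
        "n_proteins_attempted": attempted,
        "n_tests": decision.n_tests,
        "n_significant": len(significant),
        "excluded_reverse_causal": sorted(excluded_reverse),
    }
    return ResultsBundle(
        mr_results=mr_results,
        coloc_results=pd.DataFrame(coloc_rows),
        tier_report=pd.DataFrame(tier_rows),
        manifest=manifest,
    )


def make_report(results: ResultsBundle) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Volcano-plot data (ln OR vs −log10 p) and per-tier summary counts."""
    mr = results.mr_results
    if mr.empty or "beta" not in mr.columns:
        volcano = pd.DataFrame(columns=["protein", "ln_or", "neg_log10_p", "significant"])
    else:
        fitted = mr.dropna(subset=["beta"])
        volcano = pd.DataFrame(
            {
                "protein": fitted["protein"],
                "ln_or": fitted["beta"],
                "neg_log10_p": -np.log10(fitted["pval"]),
                "significant": fitted["significant"],
            }
        ).reset_index(drop=True)
    tiers = results.tier_report
    if tiers.empty:
        counts = pd.DataFrame({"tier": [1, 2, 3, 4], "count": [0, 0, 0, 0]})
    else:
        counts = (
            tiers["tier"].value_counts().reindex([1, 2, 3, 4], fill_value=0).rename("count")
        )
        counts = counts.rename_axis("tier").reset_index()
    return volcano, counts


def plot_volcano(volcano: pd.DataFrame, path: str | Path) -> None:
    """Optional matplotlib rendering of the volcano data."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if not volcano.empty:
        colors = np.where(volcano["significant"], "crimson", "grey")
        ax.scatter(volcano["ln_or"], volcano["neg_log10_p"], s=12, c=colors)
    ax.set_xlabel("ln(OR) per SD protein")
    ax.set_ylabel("-log10(P)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# file-based bundle round trip (the formats sumstats_io reads)
# ---------------------------------------------------------------------------


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> None:
    """Write a synthetic bundle in the delimited formats the pipeline reads."""
    outdir = Path(outdir)
    for sub in ("exposure", "replication_exposure", "ld"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    outcome_frames = []
    rep_outcome_frames = []
    gene_rows = []
    for p in bundle.proteins:
        exp = records_to_frame(p.discovery.exposure + p.discovery.protein_at_disease_instruments)
        exp.to_csv(outdir / "exposure" / f"{p.protein_id}.tsv", sep="\t", index=False)
        rep = records_to_frame(
            p.replication.exposure + p.replication.protein_at_disease_instruments
        )
        rep.to_csv(outdir / "replication_exposure" / f"{p.protein_id}.tsv", sep="\t", index=False)
        outcome_frames.append(
            records_to_frame(p.discovery.outcome + p.discovery.disease_instruments)
        )
        rep_outcome_frames.append(
            records_to_frame(p.replication.outcome + p.replication.disease_instruments)
        )
        write_ld_matrix(
            outdir / "ld" / f"{p.protein_id}.ld", p.discovery.ld, p.discovery.snp_ids
        )
        gene_rows.append(
            {
                "gene_id": p.gene.gene_id,
                "protein_id": p.gene.protein_id,
                "chr": p.gene.chrom,
                "tss": p.gene.tss_pos,
            }
        )
    pd.concat(outcome_frames).to_csv(outdir / "outcome.tsv", sep="\t", index=False)
    pd.concat(rep_outcome_frames).to_csv(outdir / "replication_outcome.tsv", sep="\t", index=False)
    pd.DataFrame(gene_rows).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    bundle.truth().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    bundle.ppi_edges.to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    bundle.drug_map.to_csv(outdir / "drugs.tsv", sep="\t", index=False)
    bundle.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)


def read_bundle(datadir: str | Path) -> tuple[list[ProteinInputs], dict[str, pd.DataFrame]]:
    """Read a written bundle back into pipeline inputs plus annotation tables."""
    datadir = Path(datadir)
    genes = pd.read_csv(datadir / "genes.tsv", sep="\t", dtype={"chr": str})
    outcome = read_sumstats(datadir / "outcome.tsv", trait_type=CASE_CONTROL)
    rep_outcome_path = datadir / "replication_outcome.tsv"
    rep_outcome = (
        read_sumstats(rep_outcome_path, trait_type=CASE_CONTROL)
        if rep_outcome_path.exists()
        else []
    )
    inputs: list[ProteinInputs] = []
    for row in genes.itertuples(index=False):
        pid = str(row.protein_id)
        gene = GeneAnnotation(str(row.gene_id), pid, str(row.chr), int(row.tss))
        exposure = read_sumstats(datadir / "exposure" / f"{pid}.tsv")
        ld_path = datadir / "ld" / f"{pid}.ld"
        ld, ld_ids = read_ld_matrix(ld_path) if ld_path.exists() else (None, None)
        rep_path = datadir / "replication_exposure" / f"{pid}.tsv"
        rep_exposure = read_sumstats(rep_path) if rep_path.exists() else []
        inputs.append(
            ProteinInputs(pid, gene, exposure, outcome, ld, ld_ids, rep_exposure, rep_outcome)
        )
    tables = {}
    for name in ("ppi", "drugs", "annotation"):
        path = datadir / f"{name}.tsv"
        tables[name] = pd.read_csv(path, sep="\t") if path.exists() else pd.DataFrame()
    return inputs, tables


def write_results(results: ResultsBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.mr_results.to_csv(outdir / "mr_results.tsv", sep="\t", index=False)
    results.coloc_results.to_csv(outdir / "coloc_results.tsv", sep="\t", index=False)
    results.tier_report.to_csv(outdir / "tier_report.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(results.manifest, fh, indent=2, sort_keys=True)
    volcano, counts = make_report(results)
    volcano.to_csv(outdir / "volcano.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "tier_counts.tsv", sep="\t", index=False)


def run_all(
    outdir: str | Path,
    seed: int = 17,
    n_proteins: int = 50,
    fraction_causal: float = 0.02,
    n_reverse: int = 0,
    config: PipelineConfig | None = None,
) -> ResultsBundle:
    """simulate → write → read back → discover → report, fully seeded."""
    outdir = Path(outdir)
    config = config or PipelineConfig()
    config.seed = seed
    bundle = simulate_proteome(n_proteins, fraction_causal, seed=seed, n_reverse=n_reverse)
    datadir = outdir / "data"
    write_bundle(bundle, datadir)
    inputs, tables = read_bundle(datadir)
    results = run_discovery(
        inputs,
        config,
        ppi_edges=tables["ppi"] if not tables["ppi"].empty else None,
        drug_map=tables["drugs"] if not tables["drugs"].empty else None,
        annotation=tables["annotation"] if not tables["annotation"].empty else None,
    )
    write_results(results, outdir)
    return results
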