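"""Phenotype scanning, PPI drug-target linkage and four-tier classification.

A discovery protein graduates through three evidence gates: external
replication, colocalization (PPH4 at threshold) and a protein–protein
interaction link to an existing drug's target for the same indication.
The tier rules:

* tier 1 — colocalizes AND replicates;
* tier 2 — PPI drug link AND replicates (and not tier 1);
* tier 3 — exactly one of the three evidence flags;
* tier 4 — everything else.

Phenotype scanning is a pure local-table lookup (SNP, trait, p): hits at
genome-wide significance are reported, and flagged as pleiotropic when
the trait is a known risk factor for the cancer under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

GENOME_WIDE_P = 5e-8
DEFAULT_PPI_SCORE = 0.4


@dataclass(frozen=True)
class PhenotypeHit:
    """A genome-wide-significant prior association of an instrument SNP."""

    snp_id: str
    trait_name: str
    pval: float
    flagged_pleiotropic: bool


@dataclass
class PpiNetwork:
    """Undirected protein interaction network with confidence-thresholded edges."""

    graph: nx.Graph
    score_threshold: float = DEFAULT_PPI_SCORE

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def neighbors(self, protein: str) -> dict[str, float]:
        if protein not in self.graph:
            return {}
        return {nbr: self.graph[protein][nbr]["score"] for nbr in self.graph[protein]}


@dataclass
class TargetFlags:
    """The three evidence flags feeding tier classification."""

    replicated: bool
    coloc_pass: bool
    ppi_drug_link: bool


@dataclass
class TargetReport:
    """Per-protein evidence summary and tier."""

    protein_id: str
    outcome_id: str
    flags: TargetFlags
    phenotype_flags: list[PhenotypeHit] = field(default_factory=list)
    drug_links: list[tuple[str, str, float]] = field(default_factory=list)
    tier: int = 4


def phenotype_scan(
    snp_ids: Iterable[str],
    annotation_table: pd.DataFrame,
    risk_factor_list: Iterable[str] = (),
) -> list[PhenotypeHit]:
    """Look up prior associations of instrument SNPs in a local annotation table.

    ``annotation_table`` needs columns ``snp``, ``trait``, ``p``. A hit is
    any (snp, trait) row with p < 5e-8; it is flagged pleiotropic when the
    trait is in ``risk_factor_list`` (known risk factors for the cancer).
    """
    wanted = set(snp_ids)
    risk = set(risk_factor_list)
    hits: list[PhenotypeHit] = []
    if annotation_table is None or annotation_table.empty:
        return hits
    for row in annotation_table.itertuples(index=False):
        if row.snp in wanted and float(row.p) < GENOME_WIDE_P:
            hits.append(
                PhenotypeHit(
                    snp_id=str(row.snp),
                    trait_name=str(row.trait),
                    pval=float(row.p),
                    flagged_pleiotropic=str(row.trait) in risk,
                )
            )
    return hits


def build_network(
    edge_list: pd.DataFrame | Sequence[tuple[str, str, float]],
    threshold: float = DEFAULT_PPI_SCORE,
) -> PpiNetwork:
    """Build the PPI network from a (protein_a, protein_b, combined_score) edge list.

    STRING-dialect integer scores (0–1000) are rescaled to [0, 1] whenever
    any score exceeds 1. Self-loops are dropped; duplicate edges keep the
    maximum score; edges below ``threshold`` (inclusive ≥ keeps) are removed.
    """
    if isinstance(edge_list, pd.DataFrame):
        rows = [
            (str(r[0]), str(r[1]), float(r[2]))
            for r in edge_list.itertuples(index=False)
        ]
    else:
        rows = [(str(a), str(b), float(s)) for a, b, s in edge_list]
    if rows and max(s for _, _, s in rows) > 1.0:
        rows = [(a, b, s / 1000.0) for a, b, s in rows]
    graph = nx.Graph()
    for a, b, score in rows:
        if a == b:
            continue
        if score < threshold:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b]["score"], score)
        else:
            graph.add_edge(a, b, score=score)
    return PpiNetwork(graph, threshold)


def _drug_targets_for_indication(
    drug_map: pd.DataFrame | Mapping[str, Sequence[str]], indication: str | None
) -> list[tuple[str, str]]:
    """(drug, target) pairs filtered to the indication (None keeps all)."""
    pairs: list[tuple[str, str]] = []
    if isinstance(drug_map, pd.DataFrame):
        if drug_map.empty:
            return pairs
        for row in drug_map.itertuples(index=False):
            row_ind = getattr(row, "indication", None)
            if indication is None or row_ind is None or str(row_ind) == indication:
                pairs.append((str(row.drug), str(row.target)))
    else:
        for drug, targets in drug_map.items():
            pairs.extend((drug, str(t)) for t in targets)
    return pairs


def drug_link(
    protein: str,
    network: PpiNetwork,
    drug_map: pd.DataFrame | Mapping[str, Sequence[str]],
    indication: str | None = None,
) -> tuple[bool, list[tuple[str, str, float]]]:
    """Does the protein connect to an existing drug's target for this cancer?

    True when the protein has a retained network edge to any target of any
    drug approved/used for the indication, or is itself such a target
    (identity link, score 1.0). Returns the qualifying
    (drug, target, score) evidence list.
    """
    links: list[tuple[str, str, float]] = []
    neighbors = network.neighbors(protein)
    for drug, target in _drug_targets_for_indication(drug_map, indication):
        if target == protein:
            links.append((drug, target, 1.0))
        elif target in neighbors:
            links.append((drug, target, neighbors[target]))
    return bool(links), links


def classify_tier(flags: TargetFlags) -> int:
    """Map the three evidence flags to a tier (total over all 8 combinations)."""
    if flags.coloc_pass and flags.replicated:
        return 1
    if flags.ppi_drug_link and flags.replicated:
        return 2
    if sum([flags.replicated, flags.coloc_pass, flags.ppi_drug_link]) == 1:
        return 3
    return 4


def build_report(
    protein_id: str,
    outcome_id: str,
    flags: TargetFlags,
    phenotype_flags: list[PhenotypeHit] | None = None,
    drug_links: list[tuple[str, str, float]] | None = None,
) -> TargetReport:
    return TargetReport(
        protein_id=protein_id,
        outcome_id=outcome_id,
        flags=flags,
        phenotype_flags=phenotype_flags or [],
        drug_links=drug_links or [],
        tier=classify_tier(flags),
    )
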