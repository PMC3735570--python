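"""End-to-end orchestration over the module stages.

Thin convenience layer: qualify genes from evidence, classify them, detect
clusters / duplications / families, and place + categorize markers. Each
step simply calls the corresponding module function with its defaults, so
scripted users can reproduce any stage in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import ClassifierParams, NbsClassification, classify_gene
from .domain_scan import (
    DomainEvidence,
    HomologyParams,
    qualify_nbs_genes,
    scan_nbs_motifs,
    score_coiled_coil,
)
from .genome_architecture import (
    ClusterParams,
    DuplicationParams,
    GeneCluster,
    DuplicationEvent,
    GeneFamily,
    build_families,
    detect_clusters,
    detect_duplications,
)
from .qtl_colocalization import (
    EpcrParams,
    MarkerCall,
    PrimerPair,
    QtlParams,
    categorize_marker,
    epcr,
)
from .records import GeneLocus, ProteinRecord


def classify_genes(
    proteins: dict[str, ProteinRecord],
    evidence: list[DomainEvidence],
    homology_hits=None,
    classifier_params: ClassifierParams | None = None,
    homology_params: HomologyParams | None = None,
) -> dict[str, NbsClassification]:
    """Qualify and classify every NBS gene; returns per-gene records."""
    qualified = qualify_nbs_genes(proteins, evidence, homology_hits,
                                  homology_params)
    by_gene: dict[str, list[DomainEvidence]] = {}
    for ev in evidence:
        by_gene.setdefault(ev.gene_id, []).append(ev)
    out: dict[str, NbsClassification] = {}
    for gid in sorted(qualified):
        protein = proteins[gid]
        hits = scan_nbs_motifs(protein)
        profile = score_coiled_coil(protein)
        out[gid] = classify_gene(
            protein, hits, by_gene.get(gid, []), profile, classifier_params
        )
    return out


@dataclass
class ArchitectureResult:
    clusters: list[GeneCluster]
    events: list[DuplicationEvent]
    families: list[GeneFamily]


def analyze_architecture(
    proteins: dict[str, ProteinRecord],
    loci: list[GeneLocus],
    cluster_params: ClusterParams | None = None,
    duplication_params: DuplicationParams | None = None,
) -> ArchitectureResult:
    clusters = detect_clusters(loci, cluster_params)
    events = detect_duplications(proteins, loci, clusters, duplication_params)
    return ArchitectureResult(clusters, events, build_families(events))


def place_markers(
    genome: dict[str, str],
    primers: list[PrimerPair],
    loci: list[GeneLocus],
    epcr_params: EpcrParams | None = None,
    qtl_params: QtlParams | None = None,
    chromosome_ids: set[str] | None = None,
) -> list[MarkerCall]:
    seq_lengths = {name: len(seq) for name, seq in genome.items()}
    calls = []
    for pair in primers:
        placements = epcr(genome, pair, epcr_params)
        calls.append(
            categorize_marker(
                placements, loci, seq_lengths, qtl_params, chromosome_ids,
                marker_id=pair.marker_id,
            )
        )
    return calls
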