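"""Genomic architecture of the NBS gene set.

* **Clusters** — the Holub criterion: a chromosome/scaffold region holding
  two or more NBS genes within 200 kb of each other. The rule is applied to
  adjacent-gene gaps with transitive chaining, so a chain whose extreme
  members are further than 200 kb apart is still one cluster.
* **Duplications** — the 70/70 rule: a gene pair is a duplication event when
  a global protein alignment covers more than 70% of the longer gene and
  more than 70% of the alignable columns are identical.
* **Families** — single-linkage connected components of the duplication
  graph: every member shows identity to at least one other member.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from Bio import Align

from .records import GeneLocus, ProteinRecord
from .util import pct


# ---------------------------------------------------------------------------
# Clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterParams:
    max_gap: int = 200_000  # bp between adjacent genes

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


@dataclass(frozen=True)
class GeneCluster:
    seq_id: str
    members: tuple[str, ...]  # ordered by genomic position
    span: tuple[int, int]

    def __len__(self) -> int:
        return len(self.members)


def detect_clusters(
    loci: list[GeneLocus], params: ClusterParams | None = None
) -> list[GeneCluster]:
    """Chain genes whose edge-to-edge gap is at most ``max_gap``.

    The inter-gene distance is ``max(0, next.start - prev.end)`` (overlapping
    genes count as distance zero). Chains of length >= 2 become clusters.
    """
    params = params or ClusterParams()
    seen: set[str] = set()
    for locus in loci:
        if locus.gene_id in seen:
            raise ValueError(f"duplicate gene_id {locus.gene_id!r}")
        seen.add(locus.gene_id)

    clusters: list[GeneCluster] = []
    by_seq: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        by_seq.setdefault(locus.seq_id, []).append(locus)
    for seq_id in sorted(by_seq):
        genes = sorted(by_seq[seq_id], key=lambda g: (g.start, g.end, g.gene_id))
        chain: list[GeneLocus] = []
        for gene in genes:
            if chain and max(0, gene.start - chain[-1].end) > params.max_gap:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(seq_id, chain))
                chain = []
            chain.append(gene)
        if len(chain) >= 2:
            clusters.append(_make_cluster(seq_id, chain))
    return clusters


def _make_cluster(seq_id: str, chain: list[GeneLocus]) -> GeneCluster:
    return GeneCluster(
        seq_id,
        tuple(g.gene_id for g in chain),
        (min(g.start for g in chain), max(g.end for g in chain)),
    )


# ---------------------------------------------------------------------------
# Duplications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicationParams:
    """Thresholds of the 70/70 duplication rule (both strict)."""

    min_coverage: float = 0.70  # alignable fraction of the longer gene
    min_identity: float = 0.70  # identical fraction of alignable columns
    collapse_linked: bool = False
    # global-aligner scoring (linear gaps keep the oracle simple)
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_score: float = -2.0

    def __post_init__(self) -> None:
        for frac in (self.min_coverage, self.min_identity):
            if not (0 < frac <= 1):
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass(frozen=True)
class DuplicationEvent:
    """An unordered qualifying gene pair (stored with gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    coverage: float
    identity: float
    linked: bool = False
    chromosome_level: bool = False

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("events must be stored with gene_a < gene_b")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))


def _aligner(params: DuplicationParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_score
    aligner.extend_gap_score = params.gap_score
    return aligner


def align_pair(
    a: ProteinRecord, b: ProteinRecord, params: DuplicationParams | None = None
) -> tuple[float, float]:
    """Global-alignment coverage and identity for one protein pair.

    Coverage is the number of alignable columns (both sequences contribute a
    residue) divided by the longer gene's length; identity is the identical
    fraction of those alignable columns.
    """
    params = params or DuplicationParams()
    aln = _aligner(params).align(a.sequence, b.sequence)[0]
    alignable = 0
    identical = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        alignable += a1 - a0
        for x, y in zip(a.sequence[a0:a1], b.sequence[b0:b1]):
            if x == y:
                identical += 1
    longer = max(a.length, b.length)
    coverage = alignable / longer
    identity = identical / alignable if alignable else 0.0
    return coverage, identity


def detect_duplications(
    proteins: dict[str, ProteinRecord],
    loci: list[GeneLocus],
    clusters: list[GeneCluster] | None = None,
    params: DuplicationParams | None = None,
) -> list[DuplicationEvent]:
    """All-vs-all 70/70 screen over the qualified gene set.

    Every unordered pair whose coverage and identity strictly exceed both
    thresholds becomes an event. Events between genomically adjacent members
    of the same cluster are flagged ``linked``; events whose genes lie on
    different sequences are flagged ``chromosome_level``. With
    ``collapse_linked`` set, same-cluster events between non-adjacent members
    are dropped, so a tandem array contributes one event per adjacent pair.
    """
    params = params or DuplicationParams()
    locus_by_id = {l.gene_id: l for l in loci}
    missing = set(locus_by_id) - set(proteins)
    if missing:
        raise ValueError(f"missing protein for loci: {sorted(missing)[:5]}")

    adjacency: set[frozenset[str]] = set()
    cluster_of: dict[str, int] = {}
    for ci, cluster in enumerate(clusters or []):
        for gid in cluster.members:
            cluster_of[gid] = ci
        for u, v in itertools.pairwise(cluster.members):
            adjacency.add(frozenset((u, v)))

    events: list[DuplicationEvent] = []
    for ga, gb in itertools.combinations(sorted(locus_by_id), 2):
        coverage, identity = align_pair(proteins[ga], proteins[gb], params)
        if coverage > params.min_coverage and identity > params.min_identity:
            same_cluster = (
                ga in cluster_of and gb in cluster_of
                and cluster_of[ga] == cluster_of[gb]
            )
            linked = frozenset((ga, gb)) in adjacency
            if params.collapse_linked and same_cluster and not linked:
                continue
            events.append(
                DuplicationEvent(
                    ga, gb, coverage, identity, linked,
                    chromosome_level=(
                        locus_by_id[ga].seq_id != locus_by_id[gb].seq_id
                    ),
                )
            )
    return events


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFamily:
    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a family needs at least two members")

    def __len__(self) -> int:
        return len(self.members)


def build_families(events: list[DuplicationEvent]) -> list[GeneFamily]:
    """Single-linkage families: connected components of the event graph."""
    graph = nx.Graph()
    for ev in events:
        graph.add_edge(ev.gene_a, ev.gene_b)
    families = [GeneFamily(frozenset(c)) for c in nx.connected_components(graph)]
    return sorted(families, key=lambda f: sorted(f.members))


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass
class ArchitectureSummary:
    """Per-location counts behind the clustered/duplicated percentages."""

    table: pd.DataFrame  # per seq_id: n_genes, n_clustered, n_dup, n_dup_in_cluster
    total_genes: int
    total_clustered: int
    total_duplicated: int
    total_dup_in_cluster: int
    n_excluded: int
    clustered_pct: float  # of (total - excluded), 2 decimals
    dup_in_cluster_pct: float  # of duplicated genes, 1 decimal


def singleton_location_genes(loci: list[GeneLocus]) -> set[str]:
    """Genes that are the sole NBS gene on their chromosome/scaffold.

    These are excluded from the clustered-percentage denominator: a gene
    alone on its sequence has no opportunity to cluster.
    """
    counts: dict[str, int] = {}
    for locus in loci:
        counts[locus.seq_id] = counts.get(locus.seq_id, 0) + 1
    return {l.gene_id for l in loci if counts[l.seq_id] == 1}


def summarize_architecture(
    loci: list[GeneLocus],
    clusters: list[GeneCluster],
    events: list[DuplicationEvent],
    exclusions: set[str] | None = None,
) -> ArchitectureSummary:
    """Location table plus the clustered / duplicated-in-cluster shares."""
    if exclusions is None:
        exclusions = singleton_location_genes(loci)
    clustered = {gid for c in clusters for gid in c.members}
    duplicated = {gid for ev in events for gid in ev.pair}
    rows = []
    seq_ids = sorted({l.seq_id for l in loci})
    for seq_id in seq_ids:
        ids = {l.gene_id for l in loci if l.seq_id == seq_id}
        rows.append(
            {
                "seq_id": seq_id,
                "n_genes": len(ids),
                "n_clustered": len(ids & clustered),
                "n_duplicated": len(ids & duplicated),
                "n_dup_in_cluster": len(ids & duplicated & clustered),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["seq_id", "n_genes", "n_clustered", "n_duplicated",
                 "n_dup_in_cluster"],
    )
    total = len(loci)
    denom = total - len(exclusions)
    clustered_pct = pct(len(clustered), denom) if denom else 0.0
    dup_in = len(duplicated & clustered)
    dupe_pct = pct(dup_in, len(duplicated), 1) if duplicated else 0.0
    return ArchitectureSummary(
        table,
        total_genes=total,
        total_clustered=len(clustered),
        total_duplicated=len(duplicated),
        total_dup_in_cluster=dup_in,
        n_excluded=len(exclusions),
        clustered_pct=clustered_pct,
        dup_in_cluster_pct=dupe_pct,
    )
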