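"""Synthetic genomes with known truth for every pipeline stage.

The generator emulates the statistical structure the pipeline is built to
detect: proteins with planted (optionally end-truncated) five-motif NBS
cassettes, N-termini carrying ideal or weakened heptad repeats or TIR
marker segments, chromosome layouts with 200-kb gene clusters and tandem
duplicate families mutated to controlled identity, and primer sites planted
at controlled distances from genes.

Every planted gene is verified by running the pipeline's own scanners and
classifier and resampling the random filler until the realized data imply
exactly the planted truth; marker sites are likewise verified by running
e-PCR on the assembled genome. Counts therefore realize the configured
targets by construction, not by sampling. With a fixed seed the outputs are
byte-identical across runs.

The fixed TIR/LRR cassettes are synthetic marker sequences (not biological
consensi); they exist so the evidence table and the built-in scanners
exercise the same classifier paths.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import ClassifierParams, classify_gene
from .domain_scan import (
    DomainEvidence,
    MotifModel,
    default_motif_models,
    scan_nbs_motifs,
    score_coiled_coil,
)
from .genome_architecture import DuplicationParams, align_pair
from .qtl_colocalization import EpcrParams, PrimerPair, epcr, revcomp
from .records import GeneLocus, ProteinRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Ideal heptad (a=L, d=L, e=E, g=K) and a weakened partner whose a/d core
#: is lost; alternating them yields a coiled-coil detected only below 0.90.
STRONG_HEPTAD = "LEALEKK"
WEAK_HEPTAD = "AEAAEKK"

#: Fixed synthetic N-/C-terminal marker cassettes, registered in the default
#: accession table as SYNTH_TIR / SYNTH_LRR. Their alphabets avoid the NBS
#: motif patterns and the coiled-coil scoring classes.
TIR_MARKER = "WTYDNSHQ" * 5
LRR_MARKER = "LPNSLTGE" * 4

#: Exemplar cassettes matching the default degenerate motif models.
MOTIF_CASSETTES = {
    "P-loop": "GPGGVGKT",
    "Kinase2": "LIVMLDD",
    "Kinase3a": "GSRILVTTR",
    "GLPL": "GLPLA",
    "MHDL": "MHDL",
}

MOTIF_ORDER = ("P-loop", "Kinase2", "Kinase3a", "GLPL", "MHDL")

VALID_NTERM = ("C", "c", "T", "X", "")
VALID_CTERM = ("L", "X", "")


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), n))


def _random_nt(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.frombuffer(b"ACGT", np.uint8)[rng.integers(0, 4, n)]


def parse_letter_code(code: str) -> tuple[str, str]:
    """Split a letter code into its N- and C-terminal parts."""
    rest = code
    nterm = ""
    if rest and rest[0] in "CcTX" and len(rest) >= 2 and rest[1] == "N":
        nterm, rest = rest[0], rest[1:]
    if not rest or rest[0] != "N":
        raise ValueError(f"malformed letter code {code!r}")
    cterm = rest[1:]
    if cterm not in VALID_CTERM:
        raise ValueError(f"malformed letter code {code!r}")
    return nterm, cterm


# ---------------------------------------------------------------------------
# Single-gene generation
# ---------------------------------------------------------------------------


@dataclass
class GeneArtifacts:
    """A planted gene: its protein, evidence rows and protected layout."""

    gene_id: str
    protein: ProteinRecord
    letter_code: str
    regularity: str
    motif_subset: tuple[str, ...]
    motif_positions: dict[str, tuple[int, int]]  # 1-based inclusive
    evidence: list[DomainEvidence]
    protected: list[tuple[int, int]]  # 0-based half-open, mutation-immune


class GenerationError(RuntimeError):
    pass


def _choose_subset(
    rng: np.random.Generator, motif_subset: tuple[str, ...] | None
) -> tuple[str, ...]:
    if motif_subset is not None:
        ranks = [MOTIF_ORDER.index(m) for m in motif_subset]
        if ranks != sorted(ranks) or len(set(ranks)) != len(ranks):
            raise ValueError("motif_subset must follow canonical order")
        return tuple(motif_subset)
    size = int(rng.integers(2, 5))  # 2-4 motifs, truncated from the ends
    start = int(rng.integers(0, 5 - size + 1))
    return MOTIF_ORDER[start : start + size]


def _compose_gene(
    gene_id: str,
    nterm: str,
    cterm: str,
    subset: tuple[str, ...],
    rng: np.random.Generator,
) -> GeneArtifacts:
    parts: list[str] = ["M"]
    protected: list[tuple[int, int]] = [(0, 1)]
    evidence_spans: dict[str, tuple[int, int]] = {}

    def cursor() -> int:
        return sum(len(p) for p in parts)

    def add(block: str, protect: bool = False, label: str | None = None) -> None:
        start = cursor()
        parts.append(block)
        if protect:
            protected.append((start, start + len(block)))
        if label is not None:
            evidence_spans[label] = (start + 1, start + len(block))

    # --- N-terminal region ------------------------------------------------
    add(_random_aa(rng, int(rng.integers(5, 16))))
    if nterm == "C":
        add(STRONG_HEPTAD * 6, protect=True)
        add(_random_aa(rng, int(rng.integers(5, 16))))
    elif nterm == "c":
        add((STRONG_HEPTAD + WEAK_HEPTAD) * 4, protect=True)
        add(_random_aa(rng, int(rng.integers(5, 16))))
    elif nterm == "T":
        add(TIR_MARKER, protect=True, label="TIR")
        add(_random_aa(rng, int(rng.integers(5, 16))))
    elif nterm == "X":
        add(_random_aa(rng, int(rng.integers(100, 131))))
    else:  # no code: pre-NBS flank must not exceed 100 residues
        add(_random_aa(rng, int(rng.integers(20, 60))))

    # --- NBS cassette block ----------------------------------------------
    motif_positions: dict[str, tuple[int, int]] = {}
    for i, motif in enumerate(subset):
        if i > 0:
            add(_random_aa(rng, int(rng.integers(12, 31))))
        cassette = MOTIF_CASSETTES[motif]
        start = cursor()
        add(cassette, protect=True)
        motif_positions[motif] = (start + 1, start + len(cassette))
    nbs_start = min(s for s, _ in motif_positions.values())
    nbs_end = max(e for _, e in motif_positions.values())
    evidence_spans["NBS"] = (nbs_start, nbs_end)

    # --- C-terminal region -------------------------------------------------
    if cterm == "L":
        add(_random_aa(rng, int(rng.integers(10, 26))))
        add(LRR_MARKER, protect=True, label="LRR")
        add(_random_aa(rng, int(rng.integers(20, 61))))
    elif cterm == "X":
        add(_random_aa(rng, int(rng.integers(105, 141))))
    else:
        add(_random_aa(rng, int(rng.integers(20, 81))))

    sequence = "".join(parts)
    evidence = [
        DomainEvidence(gene_id, "NBS", *evidence_spans["NBS"], 1e-30, "ingested",
                       "SYNTH_NBS")
    ]
    if "TIR" in evidence_spans:
        evidence.append(
            DomainEvidence(gene_id, "TIR", *evidence_spans["TIR"], 1e-20,
                           "ingested", "SYNTH_TIR")
        )
    if "LRR" in evidence_spans:
        evidence.append(
            DomainEvidence(gene_id, "LRR", *evidence_spans["LRR"], 1e-20,
                           "ingested", "SYNTH_LRR")
        )
    regularity = "regular" if len(subset) == 5 else "non-regular"
    return GeneArtifacts(
        gene_id,
        ProteinRecord(gene_id, sequence),
        f"{nterm}N{cterm}",
        regularity,
        subset,
        motif_positions,
        evidence,
        protected,
    )


def verify_gene(
    art: GeneArtifacts,
    models: dict[str, MotifModel] | None = None,
    params: ClassifierParams | None = None,
) -> bool:
    """Round-trip check: the pipeline classifies the gene as planted."""
    hits = scan_nbs_motifs(art.protein, models)
    if tuple(h.motif_name for h in hits) != art.motif_subset:
        return False
    if any(
        (h.start, h.end) != art.motif_positions[h.motif_name] for h in hits
    ):
        return False
    profile = score_coiled_coil(art.protein)
    rec = classify_gene(art.protein, hits, art.evidence, profile, params)
    return (
        rec.letter_code == art.letter_code and rec.regularity == art.regularity
    )


def generate_gene(
    letter_code: str,
    regularity: str,
    rng: np.random.Generator,
    gene_id: str = "gene",
    motif_subset: tuple[str, ...] | None = None,
    max_tries: int = 80,
) -> GeneArtifacts:
    """Generate one protein whose classification equals the given spec.

    Random filler segments are resampled until the pipeline's own scanners
    and classifier reproduce the planted truth exactly, so emitted data and
    truth labels are consistent by construction.
    """
    nterm, cterm = parse_letter_code(letter_code)
    if regularity not in ("regular", "non-regular"):
        raise ValueError(f"unknown regularity {regularity!r}")
    if regularity == "regular":
        if motif_subset is not None and tuple(motif_subset) != MOTIF_ORDER:
            raise ValueError("a regular gene requires all five motifs")
        subset = MOTIF_ORDER
    else:
        subset = _choose_subset(rng, motif_subset)
        if len(subset) == 5:
            raise ValueError("a non-regular gene cannot carry all five motifs")
    for _ in range(max_tries):
        art = _compose_gene(gene_id, nterm, cterm, subset, rng)
        if verify_gene(art):
            return art
    raise GenerationError(
        f"could not realize class {letter_code}/{regularity} for {gene_id}"
    )


# ---------------------------------------------------------------------------
# Controlled-identity mutation
# ---------------------------------------------------------------------------


def mutate_to_identity(
    sequence: str,
    target: float,
    rng: np.random.Generator,
    protected: list[tuple[int, int]] | None = None,
) -> str:
    """Substitute residues so post-alignment identity is within +-0.03 of
    the target.

    Substitution-only mutation keeps the alignment trivial, so the realized
    identity is exactly ``1 - n_mutated / length``. Intervals in
    ``protected`` (0-based half-open) are left untouched.
    """
    if not (0 < target <= 1):
        raise ValueError("target identity must lie in (0, 1]")
    n = len(sequence)
    n_mut = round((1 - target) * n)
    if n_mut == 0:
        return sequence
    blocked = np.zeros(n, bool)
    for s, e in protected or []:
        blocked[s:e] = True
    allowed = np.nonzero(~blocked)[0]
    if n_mut > allowed.size:
        raise ValueError(
            f"cannot place {n_mut} substitutions in {allowed.size} free positions"
        )
    picks = rng.choice(allowed, size=n_mut, replace=False)
    seq = list(sequence)
    for pos in picks:
        old = seq[pos]
        choices = [a for a in AA20 if a != old]
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq)


def _mutate_gene(
    parent: GeneArtifacts,
    gene_id: str,
    identity: float,
    rng: np.random.Generator,
    max_tries: int = 40,
) -> GeneArtifacts:
    """A duplicate-family member: parent mutated outside planted features."""
    for _ in range(max_tries):
        seq = mutate_to_identity(
            parent.protein.sequence, identity, rng, parent.protected
        )
        art = GeneArtifacts(
            gene_id,
            ProteinRecord(gene_id, seq),
            parent.letter_code,
            parent.regularity,
            parent.motif_subset,
            dict(parent.motif_positions),
            [dataclasses.replace(ev, gene_id=gene_id) for ev in parent.evidence],
            list(parent.protected),
        )
        if verify_gene(art):
            return art
    raise GenerationError(f"could not realize duplicate {gene_id}")


# ---------------------------------------------------------------------------
# Whole-genome simulation
# ---------------------------------------------------------------------------


def _default_class_counts() -> dict[tuple[str, str], int]:
    regular = {
        "CN": 1, "CNL": 5, "CNX": 3, "cNL": 8, "cNX": 3,
        "TN": 1, "TNL": 4, "TNX": 1, "N": 1, "NL": 1, "NX": 1,
    }
    non_regular = {
        "CN": 2, "CNL": 2, "CNX": 2, "cN": 3, "cNL": 2, "cNX": 3,
        "TN": 1, "TNL": 4, "TNX": 2, "XN": 1, "XNL": 1, "XNX": 1,
        "N": 2, "NL": 3, "NX": 2,
    }
    counts = {(code, "regular"): n for code, n in regular.items()}
    counts.update({(code, "non-regular"): n for code, n in non_regular.items()})
    return counts


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome.

    The defaults describe a compact genome in the image of the analysis the
    pipeline targets: 60 NBS genes of mixed letter codes and regularity
    (about half non-regular), five tandem clusters, four duplicate families
    at 0.80-0.90 protein identity, and 30 QTL markers planted across the
    co-localization categories.
    """

    seed: int = 0
    class_counts: dict[tuple[str, str], int] = field(
        default_factory=_default_class_counts
    )
    cluster_sizes: tuple[int, ...] = (12, 9, 7, 6, 5)
    intra_cluster_gap: int = 60_000  # bp between adjacent cluster members
    inter_cluster_gap: int = 400_000  # bp separating clusters/singletons
    n_gene_chromosomes: int = 5
    family_specs: tuple[tuple[int, float], ...] = (
        (3, 0.90), (3, 0.85), (2, 0.90), (2, 0.80)
    )
    n_singleton_scaffolds: int = 8
    marker_counts: dict[str, int] = field(
        default_factory=lambda: {
            "within_flank": 12,
            "outside_flank": 6,
            "small_scaffold_no_nbs": 5,
            "scaffold_with_nbs": 3,
            "unplaced": 4,
        }
    )
    primer_length: int = 20
    product_size_range: tuple[int, int] = (120, 600)
    qtl_flank: int = 3_000_000
    motif_degradation_rate: float = 0.0
    cc_degradation_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        if sum(self.cluster_sizes) + self.n_singleton_scaffolds > sum(
            self.class_counts.values()
        ):
            raise ValueError("layout needs more genes than configured")
        if any(s < 2 for s in self.cluster_sizes):
            raise ValueError("clusters need at least 2 genes")
        if (
            self.marker_counts.get("scaffold_with_nbs", 0) > 0
            and self.n_singleton_scaffolds == 0
        ):
            raise ValueError(
                "scaffold_with_nbs markers need singleton scaffolds"
            )


@dataclass
class TruthTable:
    """Planted truth, consistent with the emitted FASTA/GFF3 coordinates."""

    genes: dict[str, dict]
    clusters: list[list[str]]
    families: list[list[str]]
    markers: dict[str, dict]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    proteins: dict[str, ProteinRecord]
    loci: list[GeneLocus]
    evidence: list[DomainEvidence]
    primers: list[PrimerPair]
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        from . import io as _io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_fasta(outdir / "genome.fasta", self.genome, width=80)
        _io.write_fasta(
            outdir / "proteins.faa",
            {gid: p.sequence for gid, p in sorted(self.proteins.items())},
        )
        _io.write_gff3(outdir / "genes.gff3", self.loci)
        _io.write_evidence_tsv(outdir / "evidence.tsv", self.evidence)
        _io.write_primer_tsv(outdir / "primers.tsv", self.primers)
        (outdir / "truth.json").write_text(self.truth.to_json())


def generate_genome(config: SimConfig | None = None) -> SimResult:
    """Generate a genome + proteome + evidence + markers realizing the
    configured truth exactly. See the module docstring for the verification
    strategy."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    # ------------------------------------------------------------------ genes
    roster: list[tuple[str, str]] = []  # (letter_code, regularity)
    for (code, reg) in sorted(config.class_counts):
        roster += [(code, reg)] * config.class_counts[(code, reg)]
    gene_ids = [f"GrN{i + 1:03d}" for i in range(len(roster))]

    # carve duplicate families out of the largest class groups
    by_class: dict[tuple[str, str], list[int]] = {}
    for idx, spec in enumerate(roster):
        by_class.setdefault(spec, []).append(idx)
    family_members: list[list[int]] = []
    assigned: set[int] = set()
    for size, _identity in config.family_specs:
        pool = max(
            (g for g in sorted(by_class) if len(by_class[g]) >= size),
            key=lambda g: len(by_class[g]),
        )
        members = by_class[pool][:size]
        by_class[pool] = by_class[pool][size:]
        family_members.append(members)
        assigned.update(members)

    artifacts: dict[int, GeneArtifacts] = {}
    for fam, (size, identity) in zip(family_members, config.family_specs):
        code, reg = roster[fam[0]]
        parent = generate_gene(code, reg, rng, gene_ids[fam[0]])
        artifacts[fam[0]] = parent
        for idx in fam[1:]:
            child = _mutate_gene(parent, gene_ids[idx], identity, rng)
            cov, ident = align_pair(parent.protein, child.protein,
                                    DuplicationParams())
            if not (cov > 0.70 and ident > 0.70):
                raise GenerationError(
                    f"family member {child.gene_id} misses the 70/70 rule "
                    f"(coverage {cov:.2f}, identity {ident:.2f})"
                )
            artifacts[idx] = child
            parent = child  # chain: adjacent members meet the 70/70 rule
    for idx, (code, reg) in enumerate(roster):
        if idx not in artifacts:
            artifacts[idx] = generate_gene(code, reg, rng, gene_ids[idx])

    # Independently generated genes of one class share their planted cassette
    # blocks, so a pair can drift over the 70/70 line by chance; regenerate
    # non-family genes until the duplication graph holds exactly the planted
    # families.
    fam_index = {idx: f for f, fam in enumerate(family_members) for idx in fam}
    dup_params = DuplicationParams()
    for _ in range(20):
        offenders = []
        ids = sorted(artifacts)
        for i, j in ((a, b) for k, a in enumerate(ids) for b in ids[k + 1:]):
            if fam_index.get(i, -1) == fam_index.get(j, -2):
                continue  # same planted family: linkage is intended
            cov, ident = align_pair(
                artifacts[i].protein, artifacts[j].protein, dup_params
            )
            if cov > dup_params.min_coverage and ident > dup_params.min_identity:
                offenders.append(i if i not in fam_index else j)
        if not offenders:
            break
        for idx in set(offenders):
            if idx in fam_index:
                raise GenerationError(
                    "spurious duplication between two planted families"
                )
            code, reg = roster[idx]
            artifacts[idx] = generate_gene(code, reg, rng, gene_ids[idx])
    else:
        raise GenerationError("could not realize an event-free background")

    # ----------------------------------------------------------------- layout
    # clusters first (families kept contiguous inside one cluster each),
    # then sole-gene scaffolds, then isolated chromosome singletons.
    cluster_fill: list[list[int]] = [[] for _ in config.cluster_sizes]
    order = sorted(
        range(len(config.cluster_sizes)),
        key=lambda c: -config.cluster_sizes[c],
    )
    fams = sorted(range(len(family_members)),
                  key=lambda f: -len(family_members[f]))
    used: set[int] = set()
    for f in fams:
        target = next(
            c for c in order
            if config.cluster_sizes[c] - len(cluster_fill[c])
            >= len(family_members[f])
        )
        cluster_fill[target] += family_members[f]
        used.update(family_members[f])
    rest = [i for i in range(len(roster)) if i not in used]
    for c in range(len(config.cluster_sizes)):
        while len(cluster_fill[c]) < config.cluster_sizes[c]:
            cluster_fill[c].append(rest.pop(0))
    scaffold_singletons = [rest.pop(0) for _ in range(config.n_singleton_scaffolds)]
    chrom_singletons = rest

    chrom_names = [f"chr{i + 1}" for i in range(config.n_gene_chromosomes)]
    chrom_items: dict[str, list[list[int]]] = {c: [] for c in chrom_names}
    for i, members in enumerate(cluster_fill):
        chrom_items[chrom_names[i % len(chrom_names)]].append(members)
    for i, idx in enumerate(chrom_singletons):
        chrom_items[chrom_names[i % len(chrom_names)]].append([idx])

    loci: list[GeneLocus] = []
    truth_clusters: list[list[str]] = []
    gene_end_by_chrom: dict[str, int] = {}
    for chrom in chrom_names:
        pos = 150_000
        for group in chrom_items[chrom]:
            ids = []
            for k, idx in enumerate(group):
                if k > 0:
                    pos += config.intra_cluster_gap
                glen = 3 * artifacts[idx].protein.length
                strand = "+" if rng.integers(0, 2) == 0 else "-"
                loci.append(
                    GeneLocus(gene_ids[idx], chrom, pos, pos + glen - 1, strand)
                )
                ids.append(gene_ids[idx])
                pos = pos + glen - 1
            if len(group) >= 2:
                truth_clusters.append(ids)
            pos += config.inter_cluster_gap
        gene_end_by_chrom[chrom] = max(pos - config.inter_cluster_gap, 150_000)

    seq_lengths: dict[str, int] = {}
    for i, idx in enumerate(scaffold_singletons):
        name = f"scaffold{i + 1:02d}"
        glen = 3 * artifacts[idx].protein.length
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        loci.append(GeneLocus(gene_ids[idx], name, 100_000, 100_000 + glen - 1,
                              strand))
        seq_lengths[name] = 100_000 + glen + 100_000

    # ---------------------------------------------------------------- markers
    size_lo, size_hi = config.product_size_range
    plant_plan: list[dict] = []  # marker -> seq, pos(0-based), size, category
    marker_no = 0
    traits = ("VW", "FW", "RKN")

    def next_marker() -> tuple[str, str]:
        nonlocal marker_no
        marker_no += 1
        return f"MK{marker_no:03d}", traits[(marker_no - 1) % len(traits)]

    marker_end_by_chrom = dict(gene_end_by_chrom)
    gene_chroms = [c for c in chrom_names if chrom_items[c]]
    if not gene_chroms and (
        config.marker_counts.get("within_flank", 0)
        or config.marker_counts.get("outside_flank", 0)
    ):
        raise ValueError("chromosome markers need at least one gene-bearing "
                         "chromosome")
    for j in range(config.marker_counts.get("within_flank", 0)):
        chrom = gene_chroms[j % len(gene_chroms)]
        size = int(rng.integers(size_lo, size_hi + 1))
        # successive markers on one chromosome occupy disjoint 700-kb bands
        # inside the flanking window so planted sites never collide
        band = j // len(gene_chroms)
        dist = 100_000 + band * 700_000 + int(rng.integers(0, 600_000))
        if dist + size >= config.qtl_flank:
            raise ValueError("too many within-flank markers per chromosome")
        pos = gene_end_by_chrom[chrom] + dist
        mid, trait = next_marker()
        plant_plan.append(
            dict(marker_id=mid, trait=trait, seq_id=chrom, pos=pos, size=size,
                 category="within_flank")
        )
        marker_end_by_chrom[chrom] = max(marker_end_by_chrom[chrom], pos + size)
    far_chrom = gene_chroms[0] if gene_chroms else chrom_names[0]
    for j in range(config.marker_counts.get("outside_flank", 0)):
        size = int(rng.integers(size_lo, size_hi + 1))
        pos = (
            gene_end_by_chrom[far_chrom]
            + config.qtl_flank
            + 60_000
            + j * 25_000
        )
        mid, trait = next_marker()
        plant_plan.append(
            dict(marker_id=mid, trait=trait, seq_id=far_chrom, pos=pos,
                 size=size, category="outside_flank")
        )
        marker_end_by_chrom[far_chrom] = max(
            marker_end_by_chrom[far_chrom], pos + size
        )
    for j in range(config.marker_counts.get("small_scaffold_no_nbs", 0)):
        name = f"scaffold_mk{j + 1:02d}"
        length = int(rng.integers(500_000, 1_500_000))
        seq_lengths[name] = length
        size = int(rng.integers(size_lo, size_hi + 1))
        mid, trait = next_marker()
        plant_plan.append(
            dict(marker_id=mid, trait=trait, seq_id=name, pos=length // 2,
                 size=size, category="small_scaffold_no_nbs")
        )
    for j in range(config.marker_counts.get("scaffold_with_nbs", 0)):
        name = f"scaffold{(j % config.n_singleton_scaffolds) + 1:02d}"
        size = int(rng.integers(size_lo, size_hi + 1))
        pos = 30_000 + j * 5_000
        mid, trait = next_marker()
        plant_plan.append(
            dict(marker_id=mid, trait=trait, seq_id=name, pos=pos, size=size,
                 category="scaffold_with_nbs")
        )
    for _ in range(config.marker_counts.get("unplaced", 0)):
        mid, trait = next_marker()
        plant_plan.append(
            dict(marker_id=mid, trait=trait, seq_id=None, pos=None, size=None,
                 category="unplaced")
        )

    for chrom in chrom_names:
        seq_lengths[chrom] = marker_end_by_chrom[chrom] + 100_000

    # ------------------------------------------------------------- sequences
    genome_arr = {
        name: _random_nt(rng, seq_lengths[name]) for name in sorted(seq_lengths)
    }

    def random_primer() -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, config.primer_length))

    primers: list[PrimerPair] = []
    for plan in plant_plan:
        fwd, rev = random_primer(), random_primer()
        if plan["seq_id"] is not None:
            _plant_marker(genome_arr[plan["seq_id"]], plan, fwd, rev)
        plan["fwd"], plan["rev"] = fwd, rev

    # verify every marker against the assembled genome; resample on clashes
    epcr_params = EpcrParams(size_min=min(80, size_lo), size_max=max(700, size_hi))
    genome = {n: a.tobytes().decode() for n, a in genome_arr.items()}
    for plan in plant_plan:
        for _ in range(25):
            pair = PrimerPair(plan["marker_id"], plan["fwd"], plan["rev"],
                              plan["trait"])
            hits = epcr(genome, pair, epcr_params)
            if plan["seq_id"] is None:
                if not hits:
                    break
            elif (
                len(hits) == 1
                and hits[0].seq_id == plan["seq_id"]
                and hits[0].start == plan["pos"] + 1
                and hits[0].size == plan["size"]
            ):
                break
            plan["fwd"], plan["rev"] = random_primer(), random_primer()
            if plan["seq_id"] is not None:
                _plant_marker(genome_arr[plan["seq_id"]], plan, plan["fwd"],
                              plan["rev"])
                genome[plan["seq_id"]] = genome_arr[plan["seq_id"]].tobytes().decode()
        else:
            raise GenerationError(
                f"could not realize marker {plan['marker_id']}"
            )
        primers.append(
            PrimerPair(plan["marker_id"], plan["fwd"], plan["rev"], plan["trait"])
        )

    # ------------------------------------------------------------- noise
    proteins: dict[str, ProteinRecord] = {}
    for idx, art in sorted(artifacts.items()):
        seq = art.protein.sequence
        if config.motif_degradation_rate > 0 or config.cc_degradation_rate > 0:
            seq = _degrade(seq, art, config, rng)
        proteins[art.gene_id] = ProteinRecord(art.gene_id, seq)

    # --------------------------------------------------------------- truth
    truth_genes = {
        art.gene_id: {
            "letter_code": art.letter_code,
            "regularity": art.regularity,
            "motif_subset": list(art.motif_subset),
        }
        for art in artifacts.values()
    }
    locus_by_id = {l.gene_id: l for l in loci}
    for gid, info in truth_genes.items():
        locus = locus_by_id[gid]
        info.update(seq_id=locus.seq_id, start=locus.start, end=locus.end)
    truth_markers = {}
    for plan in plant_plan:
        entry = {"category": plan["category"], "trait": plan["trait"]}
        if plan["seq_id"] is not None:
            entry.update(
                seq_id=plan["seq_id"], start=plan["pos"] + 1,
                end=plan["pos"] + plan["size"], size=plan["size"],
            )
        truth_markers[plan["marker_id"]] = entry
    truth = TruthTable(
        genes=truth_genes,
        clusters=truth_clusters,
        families=[sorted(gene_ids[i] for i in fam) for fam in family_members],
        markers=truth_markers,
    )
    evidence = [ev for _, art in sorted(artifacts.items()) for ev in art.evidence]
    return SimResult(config, genome, proteins, loci, evidence, primers, truth)


def _plant_marker(arr: np.ndarray, plan: dict, fwd: str, rev: str) -> None:
    pos, size = plan["pos"], plan["size"]
    site_f = np.frombuffer(fwd.encode(), np.uint8)
    site_r = np.frombuffer(revcomp(rev).encode(), np.uint8)
    arr[pos : pos + len(site_f)] = site_f
    arr[pos + size - len(site_r) : pos + size] = site_r


def _degrade(
    seq: str, art: GeneArtifacts, config: SimConfig, rng: np.random.Generator
) -> str:
    """Point-substitution noise inside planted motif / coiled-coil blocks."""
    chars = list(seq)
    targets: list[tuple[float, int, int]] = []
    for s, e in ((s - 1, e) for s, e in art.motif_positions.values()):
        targets.append((config.motif_degradation_rate, s, e))
    nterm, _ = parse_letter_code(art.letter_code)
    if nterm in ("C", "c"):
        # the heptad block is the first protected interval after the Met
        s, e = art.protected[1]
        targets.append((config.cc_degradation_rate, s, e))
    for rate, s, e in targets:
        if rate <= 0:
            continue
        for i in range(s, e):
            if rng.random() < rate:
                choices = [a for a in AA20 if a != chars[i]]
                chars[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def simulate_clade_alignment(
    n_tir: int = 6,
    n_other: int = 8,
    ncol: int = 300,
    rng: np.random.Generator | None = None,
    within_rate: float = 0.03,
    between_rate: float = 0.35,
) -> tuple["object", frozenset[str]]:
    """A protein alignment evolved down a two-clade tree.

    Two ancestral sequences diverge at ``between_rate``; each tip mutates
    its clade ancestor at ``within_rate`` per residue. Returns the alignment
    and the TIR-labeled tip set (the first clade), which is monophyletic on
    the generating tree.
    """
    from .phylo import Alignment

    rng = rng if rng is not None else np.random.default_rng(0)
    root = _random_aa(rng, ncol)
    anc_tir = mutate_to_identity(root, 1 - between_rate / 2, rng)
    anc_other = mutate_to_identity(root, 1 - between_rate / 2, rng)
    rows: dict[str, str] = {}
    tir_labels = []
    for i in range(n_tir):
        label = f"TIR{i + 1:02d}"
        rows[label] = mutate_to_identity(anc_tir, 1 - within_rate, rng)
        tir_labels.append(label)
    for i in range(n_other):
        rows[f"CC{i + 1:02d}"] = mutate_to_identity(anc_other, 1 - within_rate, rng)
    return Alignment(rows), frozenset(tir_labels)
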