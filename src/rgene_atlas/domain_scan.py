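"""Per-gene domain and motif evidence.

This module produces the evidence layer every later stage consumes:

* a degenerate-pattern scanner for the five canonical NBS motifs
  (P-loop, Kinase2, Kinase3a, GLPL, MHDL — strictly ordered in the domain);
* a windowed heptad-register coiled-coil scorer that emits a per-residue
  probability profile graded against the standard 0.02/0.10/0.50/0.90
  detection thresholds;
* ingestion of InterProScan-style domain TSVs and BLAST outfmt-6 homology
  tables;
* the NBS-gene qualification filter (NBS domain evidence, optionally joined
  with a homology hit against a reference resistance-protein set).

Running the original external tools (BLAST, InterProScan, MARCOIL, SMART) is
out of scope; their outputs are either ingested or emulated by the built-in
scanners.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ProteinRecord

# ---------------------------------------------------------------------------
# Motif models
# ---------------------------------------------------------------------------

#: Canonical order of the five NBS motifs within the domain.
MOTIF_ORDER = ("P-loop", "Kinase2", "Kinase3a", "GLPL", "MHDL")

_HYDROPHOBIC = set("LIVMF")


def _parse_pattern(pattern: str) -> list[frozenset[str] | None]:
    """Parse a degenerate pattern into per-position allowed sets.

    Tokens: ``x`` matches anything (non-specific position), ``h`` matches a
    hydrophobic residue (L/I/V/M/F), ``[ABC]`` a set, any other letter itself.
    """
    tokens: list[frozenset[str] | None] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            tokens.append(frozenset(pattern[i + 1 : j]))
            i = j + 1
        elif ch == "x":
            tokens.append(None)
            i += 1
        elif ch == "h":
            tokens.append(frozenset(_HYDROPHOBIC))
            i += 1
        else:
            tokens.append(frozenset(ch))
            i += 1
    return tokens


@dataclass(frozen=True)
class MotifModel:
    """A degenerate amino-acid pattern for one NBS motif.

    ``min_score`` is the minimum fraction of specific (non-``x``) positions
    that must match for a hit to be reported; the default of 1.0 demands an
    exact match of every constrained position.
    """

    name: str
    pattern: str
    min_score: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "_tokens", _parse_pattern(self.pattern))

    @property
    def tokens(self) -> list[frozenset[str] | None]:
        return self._tokens  # type: ignore[attr-defined]

    @property
    def length(self) -> int:
        return len(self.tokens)

    @property
    def n_specific(self) -> int:
        return sum(1 for t in self.tokens if t is not None)

    def score_at(self, sequence: str, offset: int) -> float:
        """Fraction of specific positions matching at ``offset`` (0-based)."""
        if offset < 0 or offset + self.length > len(sequence):
            return 0.0
        matched = 0
        for k, tok in enumerate(self.tokens):
            if tok is not None and sequence[offset + k] in tok:
                matched += 1
        return matched / self.n_specific

    def consensus(self) -> str:
        """A fixed exemplar sequence matching the pattern exactly."""
        out = []
        for tok in self.tokens:
            out.append("G" if tok is None else sorted(tok)[0])
        return "".join(out)


def default_motif_models() -> dict[str, MotifModel]:
    """The shipped degenerate models for the five canonical NBS motifs.

    These follow the consensus forms widely used for NB-ARC motif annotation;
    users may override them with their own patterns or PWM-derived sets.
    """
    return {
        "P-loop": MotifModel("P-loop", "[GA]xxxxGK[ST]"),
        "Kinase2": MotifModel("Kinase2", "hhhhLDD"),
        "Kinase3a": MotifModel("Kinase3a", "GSR[IL][IL][LIV]TTR"),
        "GLPL": MotifModel("GLPL", "GLPL[AT]"),
        "MHDL": MotifModel("MHDL", "[MI]HD[LV]"),
    }


@dataclass(frozen=True)
class MotifHit:
    """A located motif call (1-based inclusive residue interval)."""

    gene_id: str
    motif_name: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad motif interval {self.start}-{self.end}")


def scan_nbs_motifs(
    protein: ProteinRecord,
    models: dict[str, MotifModel] | None = None,
) -> list[MotifHit]:
    """Scan a protein for the five NBS motifs.

    Every offset is scored against every model; per motif only the single
    best-scoring hit at or above ``min_score`` is kept (ties resolved to the
    left-most offset). Hits for distinct motifs are made non-overlapping by
    keeping the higher-scoring hit (ties resolved by canonical motif order).
    The returned list is sorted by start position.
    """
    if models is None:
        models = default_motif_models()
    missing = set(MOTIF_ORDER) - set(models)
    if missing:
        raise ValueError(f"motif models missing canonical names: {sorted(missing)}")
    seq = protein.sequence.upper()
    if not seq:
        raise ValueError("empty sequence")

    best: list[MotifHit] = []
    for name in MOTIF_ORDER:
        model = models[name]
        top_score, top_off = 0.0, None
        for off in range(len(seq) - model.length + 1):
            s = model.score_at(seq, off)
            if s >= model.min_score and s > top_score:
                top_score, top_off = s, off
        if top_off is not None:
            best.append(
                MotifHit(protein.gene_id, name, top_off + 1,
                         top_off + model.length, top_score)
            )

    # resolve cross-motif overlaps: higher score wins, then canonical rank
    rank = {n: i for i, n in enumerate(MOTIF_ORDER)}
    kept: list[MotifHit] = []
    for hit in sorted(best, key=lambda h: (-h.score, rank[h.motif_name])):
        if all(hit.end < k.start or hit.start > k.end for k in kept):
            kept.append(hit)
    return sorted(kept, key=lambda h: h.start)


# ---------------------------------------------------------------------------
# Coiled-coil profile
# ---------------------------------------------------------------------------

#: Residues scored as hydrophobic at heptad core (a/d) positions.
CC_CORE = frozenset("LIVMF")
#: Residues scored as charged at heptad flank (e/g) positions.
CC_CHARGED = frozenset("DEKR")

#: Logistic calibration of the raw heptad-register score onto [0, 1].
#: With these constants an ideal LEALEKK repeat (raw score 1.0) maps to
#: ~0.995 and a proline homopolymer (raw score 0.0) to ~3e-7, so the
#: standard 0.02 and 0.90 detection thresholds behave as graded cut-offs.
CC_LOGISTIC_K = 20.3
CC_LOGISTIC_MID = 0.7418

DEFAULT_CC_THRESHOLDS = (0.02, 0.10, 0.50, 0.90)


@dataclass
class CoiledCoilProfile:
    """Per-residue coiled-coil probability with graded thresholds."""

    gene_id: str
    prob: np.ndarray
    window: int
    thresholds: tuple[float, ...] = DEFAULT_CC_THRESHOLDS

    def max_prob(self, start: int = 1, end: int | None = None) -> float:
        """Maximum probability over a 1-based inclusive residue range."""
        if end is None:
            end = len(self.prob)
        if start > end or len(self.prob) == 0 or start > len(self.prob):
            return 0.0
        return float(self.prob[start - 1 : end].max()) if end >= start else 0.0

    def segments(self, threshold: float) -> list[tuple[int, int]]:
        """Maximal 1-based runs of residues with probability >= threshold."""
        mask = self.prob >= threshold
        segs: list[tuple[int, int]] = []
        start = None
        for i, flag in enumerate(mask):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                segs.append((start + 1, i))
                start = None
        if start is not None:
            segs.append((start + 1, len(mask)))
        return segs


def score_coiled_coil(protein: ProteinRecord, window: int = 28) -> CoiledCoilProfile:
    """Score heptad-repeat propensity with a sliding windowed register model.

    For every length-``window`` segment and every heptad register the raw
    score is the mean of (i) the fraction of core a/d positions occupied by
    hydrophobic residues and (ii) the fraction of flank e/g positions
    occupied by charged residues; each residue receives the maximum logistic-
    calibrated score over all windows covering it. Proteins shorter than the
    window yield an all-zero profile with a warning.
    """
    if window < 14:
        raise ValueError("window must be >= 14 residues (two heptads)")
    seq = protein.sequence.upper()
    n = len(seq)
    if n < window:
        warnings.warn(
            f"protein {protein.gene_id!r} shorter than window ({n} < {window}); "
            "all-zero coiled-coil profile",
            stacklevel=2,
        )
        return CoiledCoilProfile(protein.gene_id, np.zeros(n), window)

    core = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_core = np.isin(core, np.frombuffer("".join(CC_CORE).encode(), np.uint8))
    is_chg = np.isin(core, np.frombuffer("".join(CC_CHARGED).encode(), np.uint8))

    prob = np.zeros(n)
    # per-register boolean masks of heptad position classes along the sequence
    idx = np.arange(n)
    for reg in range(7):
        hept = (idx + reg) % 7
        ad = np.isin(hept, (0, 3))
        eg = np.isin(hept, (4, 6))
        core_hits = (is_core & ad).astype(float)
        chg_hits = (is_chg & eg).astype(float)
        ad_f = ad.astype(float)
        eg_f = eg.astype(float)
        # windowed sums via cumulative sums
        def wsum(a: np.ndarray) -> np.ndarray:
            c = np.concatenate(([0.0], np.cumsum(a)))
            return c[window:] - c[:-window]

        raw = 0.5 * (wsum(core_hits) / np.maximum(wsum(ad_f), 1.0)) + 0.5 * (
            wsum(chg_hits) / np.maximum(wsum(eg_f), 1.0)
        )
        p_win = 1.0 / (1.0 + np.exp(-CC_LOGISTIC_K * (raw - CC_LOGISTIC_MID)))
        # spread each window's probability onto the residues it covers
        for j, p in enumerate(p_win):
            lo, hi = j, j + window
            np.maximum(prob[lo:hi], p, out=prob[lo:hi])
    return CoiledCoilProfile(protein.gene_id, prob, window)


# ---------------------------------------------------------------------------
# Domain evidence
# ---------------------------------------------------------------------------

DOMAIN_TYPES = ("NBS", "TIR", "LRR", "CC", "OTHER")

#: Default accession -> domain-type table (Pfam NB-ARC, TIR, LRR clans plus
#: the synthetic marker accessions emitted by the simulator).
DEFAULT_ACCESSION_TABLE = {
    "PF00931": "NBS",
    "PF01582": "TIR",
    "PF13676": "TIR",
    "PF00560": "LRR",
    "PF07725": "LRR",
    "PF12799": "LRR",
    "PF13855": "LRR",
    "SYNTH_NBS": "NBS",
    "SYNTH_TIR": "TIR",
    "SYNTH_LRR": "LRR",
}


@dataclass(frozen=True)
class DomainEvidence:
    """A located domain call on a protein (1-based inclusive interval)."""

    gene_id: str
    domain_type: str
    start: int
    end: int
    score: float = 0.0
    source: str = "ingested"
    name: str = ""

    def __post_init__(self) -> None:
        base = self.domain_type.split("(")[0]
        if base not in DOMAIN_TYPES:
            raise ValueError(f"unknown domain type {self.domain_type!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"bad domain interval {self.start}-{self.end} for {self.gene_id!r}"
            )


def ingest_domain_tsv(
    path,
    accession_table: dict[str, str] | None = None,
    proteins: dict[str, ProteinRecord] | None = None,
) -> list[DomainEvidence]:
    """Read an InterProScan-style TSV into :class:`DomainEvidence` rows.

    Expected tab-separated columns: gene_id, accession, name, start, end,
    score. Unknown accessions are retained as ``OTHER(name)``; they never
    block classification. When ``proteins`` is given, intervals are checked
    against protein lengths.
    """
    table = dict(DEFAULT_ACCESSION_TABLE)
    if accession_table:
        table.update(accession_table)
    out: list[DomainEvidence] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            gene_id, acc, name, s_start, s_end, s_score = parts[:6]
            try:
                start, end, score = int(s_start), int(s_end), float(s_score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row ({exc})") from None
            if end < start or start < 1:
                raise ValueError(f"{path}:{lineno}: bad coordinates {start}-{end}")
            if proteins is not None:
                prot = proteins.get(gene_id)
                if prot is not None and end > prot.length:
                    raise ValueError(
                        f"{path}:{lineno}: interval {start}-{end} outside "
                        f"protein {gene_id!r} (length {prot.length})"
                    )
            dtype = table.get(acc)
            if dtype is None:
                dtype = f"OTHER({name or acc})"
            out.append(
                DomainEvidence(gene_id, dtype, start, end, score, "ingested", name)
            )
    return out


BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def ingest_blast_tab(path) -> pd.DataFrame:
    """Read BLAST tabular output (12-column outfmt-6 dialect)."""
    df = pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns")
    return df


# ---------------------------------------------------------------------------
# Qualification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomologyParams:
    """Thresholds for the resistance-protein homology check.

    ``evalue_cutoff`` applies to ingested BLAST hits; ``min_bitscore`` to the
    built-in local-alignment mode (no database size is available at desk
    scale, so raw bit-score thresholds replace e-values there).
    """

    evalue_cutoff: float = 1e-15
    min_bitscore: float = 80.0

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")


def qualify_nbs_genes(
    proteins: dict[str, ProteinRecord],
    evidence: list[DomainEvidence],
    homology_hits: pd.DataFrame | None = None,
    params: HomologyParams | None = None,
) -> set[str]:
    """Apply the NBS-gene qualification filter.

    A gene qualifies when it carries NBS domain evidence; when a homology-hit
    table is supplied it must additionally hit at least one reference
    resistance protein at ``evalue <= evalue_cutoff``. Without a hits table
    (synthetic mode) NBS evidence alone qualifies.
    """
    params = params or HomologyParams()
    nbs_genes = {ev.gene_id for ev in evidence if ev.domain_type == "NBS"}
    nbs_genes &= set(proteins)
    if homology_hits is None:
        return nbs_genes
    passing = set(
        homology_hits.loc[homology_hits["evalue"] <= params.evalue_cutoff, "qseqid"]
    )
    return nbs_genes & passing


def homology_bitscores(
    proteins: dict[str, ProteinRecord],
    references: dict[str, ProteinRecord],
) -> pd.DataFrame:
    """Built-in homology mode: best local-alignment score per gene.

    Uses a BLOSUM62 local alignment (Smith-Waterman via Biopython) against
    each reference and reports the best score, in the same frame layout as
    :func:`ingest_blast_tab` (``qseqid``/``sseqid``/``bitscore``; e-values
    are reported as NaN).
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    rows = []
    for gid, prot in proteins.items():
        for rid, ref in references.items():
            score = aligner.score(prot.sequence.replace("*", "X"),
                                  ref.sequence.replace("*", "X"))
            rows.append({"qseqid": gid, "sseqid": rid, "bitscore": float(score),
                         "evalue": float("nan")})
    return pd.DataFrame(rows)


def evidence_to_frame(evidence: list[DomainEvidence]) -> pd.DataFrame:
    """Consolidated evidence table for TSV export."""
    return pd.DataFrame(
        [
            {
                "gene_id": ev.gene_id,
                "domain_type": ev.domain_type,
                "start": ev.start,
                "end": ev.end,
                "score": ev.score,
                "source": ev.source,
                "name": ev.name,
            }
            for ev in evidence
        ]
    )
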