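"""Letter-code classification of qualified NBS genes.

Each qualified gene is classified on three axes:

* **regularity** — ``regular`` iff all five NBS motifs are present in
  canonical order and the ORF is complete (initial Met, no internal stop);
  otherwise ``non-regular`` with the ordered motif subset and a contiguity
  flag (whether the subset occupies consecutive canonical ranks, i.e. looks
  like an end-truncation of the full cassette).
* **N-terminal code** — ``T`` for TIR evidence before the NBS, else ``C``
  for a strong coiled-coil (probability >= 0.90), else ``c`` for a weak
  coiled-coil (detected at 0.50, 0.10 or 0.02), else ``X`` when the pre-NBS
  flank exceeds 100 residues with no known domain, else no code.
* **C-terminal code** — ``L`` for LRR evidence after the NBS, else ``X``
  when the post-NBS tail exceeds 100 residues, else no code.

The composed letter code is ``<nterm>N<cterm>`` with absent codes rendered
as empty (e.g. ``CNL``, ``cNX``, ``TN``, ``N``).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .domain_scan import CoiledCoilProfile, DomainEvidence, MotifHit, MOTIF_ORDER
from .records import ProteinRecord
from .util import pct

NTERM_CODES = ("T", "C", "c", "X", "")
CTERM_CODES = ("L", "X", "")


@dataclass(frozen=True)
class ClassifierParams:
    cc_major_threshold: float = 0.90
    cc_minor_thresholds: tuple[float, ...] = (0.50, 0.10, 0.02)
    min_flank_len: int = 100  # strict: flank must exceed this to earn an X
    tir_priority: bool = True

    def __post_init__(self) -> None:
        if self.min_flank_len <= 0:
            raise ValueError("min_flank_len must be positive")
        lo = min(self.cc_minor_thresholds)
        if not (0 < lo < self.cc_major_threshold <= 1):
            raise ValueError("thresholds must be strictly ordered in (0, 1]")


@dataclass(frozen=True)
class NbsClassification:
    gene_id: str
    regularity: str  # "regular" | "non-regular"
    motif_subset: tuple[str, ...]
    subset_contiguous: bool
    nterm_code: str
    cterm_code: str

    @property
    def letter_code(self) -> str:
        return f"{self.nterm_code}N{self.cterm_code}"


class ClassificationError(ValueError):
    pass


def _orf_complete(protein: ProteinRecord) -> bool:
    seq = protein.sequence.upper().rstrip("*")
    return seq.startswith("M") and "*" not in seq


def assess_regularity(
    hits: list[MotifHit], protein: ProteinRecord
) -> tuple[str, tuple[str, ...], bool]:
    """Regularity call from motif hits plus an ORF-completeness check."""
    ordered = sorted(hits, key=lambda h: h.start)
    names = tuple(h.motif_name for h in ordered)
    canonical_rank = {n: i for i, n in enumerate(MOTIF_ORDER)}
    ranks = [canonical_rank[n] for n in names]
    in_order = ranks == sorted(ranks) and len(set(ranks)) == len(ranks)
    contiguous = bool(ranks) and in_order and (
        sorted(ranks) == list(range(min(ranks), max(ranks) + 1))
    )
    if len(names) == 5 and in_order and _orf_complete(protein):
        return "regular", names, True
    return "non-regular", names, contiguous


def nbs_span(
    evidence: list[DomainEvidence] | None, hits: list[MotifHit] | None
) -> tuple[int, int]:
    """The NBS domain interval: ingested NBS evidence if present, else the
    span of the motif hits."""
    if evidence:
        nbs = [ev for ev in evidence if ev.domain_type == "NBS"]
        if nbs:
            return min(e.start for e in nbs), max(e.end for e in nbs)
    if hits:
        return min(h.start for h in hits), max(h.end for h in hits)
    raise ClassificationError("gene has neither NBS evidence nor motif hits")


def assign_nterm_code(
    protein: ProteinRecord,
    evidence: list[DomainEvidence],
    cc_profile: CoiledCoilProfile | None,
    params: ClassifierParams,
    nbs_start: int,
) -> str:
    """N-terminal code from evidence strictly before the NBS start."""
    flank_end = nbs_start - 1
    if flank_end < 0:
        raise ClassificationError(f"NBS starts before residue 1 for {protein.gene_id}")
    tir_in_flank = any(
        ev.domain_type == "TIR" and ev.start <= flank_end for ev in evidence
    )
    if params.tir_priority and tir_in_flank:
        return "T"
    cc_max = cc_profile.max_prob(1, flank_end) if cc_profile is not None else 0.0
    if cc_max >= params.cc_major_threshold:
        return "C"
    if not params.tir_priority and tir_in_flank:
        return "T"
    if cc_max >= min(params.cc_minor_thresholds):
        return "c"
    # OTHER (non-TIR, non-CC) domain evidence never blocks the X code: long
    # N-termini carrying novel domains are still "other kind of N-terminal".
    if flank_end > params.min_flank_len:
        return "X"
    return ""


def assign_cterm_code(
    protein: ProteinRecord,
    evidence: list[DomainEvidence],
    params: ClassifierParams,
    nbs_end: int,
) -> str:
    """C-terminal code from evidence strictly after the NBS end."""
    tail_len = protein.length - nbs_end
    if any(ev.domain_type == "LRR" and ev.end > nbs_end for ev in evidence):
        return "L"
    if tail_len > params.min_flank_len:
        return "X"
    return ""


def classify_gene(
    protein: ProteinRecord,
    hits: list[MotifHit],
    evidence: list[DomainEvidence],
    cc_profile: CoiledCoilProfile | None = None,
    params: ClassifierParams | None = None,
) -> NbsClassification:
    """Compose regularity, N- and C-terminal codes for one qualified gene."""
    params = params or ClassifierParams()
    regularity, subset, contiguous = assess_regularity(hits, protein)
    start, end = nbs_span(evidence, hits)
    nterm = assign_nterm_code(protein, evidence, cc_profile, params, start)
    cterm = assign_cterm_code(protein, evidence, params, end)
    return NbsClassification(
        protein.gene_id, regularity, subset, contiguous, nterm, cterm
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class ClassSummary:
    """Per-(regularity, letter-code) counts with percentage-of-total."""

    table: pd.DataFrame  # columns: regularity, letter_code, count, pct
    group_totals: pd.DataFrame  # per regularity: count, pct
    total: int


def summarize_classes(
    records: list[NbsClassification], total: int | None = None
) -> ClassSummary:
    """Tabulate subgroup counts and half-up two-decimal percentages.

    ``total`` defaults to the number of records; it may be larger when the
    percentage base is a wider census than the records at hand.
    """
    if total is None:
        total = len(records)
    if total == 0:
        raise ValueError("cannot summarize against a zero total")
    if total < len(records):
        raise ValueError("total smaller than the number of records")
    rows: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.regularity, rec.letter_code)
        rows[key] = rows.get(key, 0) + 1
    table = pd.DataFrame(
        [
            {
                "regularity": reg,
                "letter_code": code,
                "count": n,
                "pct": pct(n, total),
            }
            for (reg, code), n in sorted(rows.items())
        ],
        columns=["regularity", "letter_code", "count", "pct"],
    )
    groups = (
        table.groupby("regularity")["count"].sum()
        if len(table)
        else pd.Series(dtype=int)
    )
    group_totals = pd.DataFrame(
        [
            {"regularity": reg, "count": int(n), "pct": pct(int(n), total)}
            for reg, n in groups.items()
        ],
        columns=["regularity", "count", "pct"],
    )
    return ClassSummary(table, group_totals, total)
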