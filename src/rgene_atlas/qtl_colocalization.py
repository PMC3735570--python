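"""Electronic PCR marker placement and QTL co-localization.

Disease-resistance QTL are represented by their markers' primer pairs.
Each marker is placed on the genome by electronic PCR: a placement is any
convergent pair of primer-binding sites (forward primer on one strand,
reverse primer on the opposite strand, 3' ends facing each other) whose
amplicon size falls within a configured window (default 80-700 bp). Sites
may carry up to ``max_mismatch`` mismatches but must match exactly over the
3'-terminal ``anchor3`` bases; indels are not modelled.

A placed marker is then classified against the NBS gene set: within a
+-3-Mb flanking window of a gene on a chromosome, outside it, or on a
scaffold (with NBS genes, or a small gene-free scaffold that might still
land near a gene once anchored to a chromosome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import GeneLocus
from .util import pct

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    marker_id: str
    fwd: str
    rev: str
    trait: str = ""

    def __post_init__(self) -> None:
        for name, primer in (("fwd", self.fwd), ("rev", self.rev)):
            if len(primer) < 15:
                raise ValueError(
                    f"{self.marker_id}: {name} primer shorter than 15 nt"
                )


@dataclass(frozen=True)
class EpcrParams:
    size_min: int = 80
    size_max: int = 700
    max_mismatch: int = 2
    anchor3: int = 3  # 3'-terminal bases requiring an exact match

    def __post_init__(self) -> None:
        if not (0 < self.size_min < self.size_max):
            raise ValueError("need 0 < size_min < size_max")
        if self.anchor3 < 1:
            raise ValueError("anchor3 must be >= 1")


@dataclass(frozen=True)
class MarkerPlacement:
    """One amplicon (1-based inclusive product interval on the plus strand)."""

    marker_id: str
    seq_id: str
    start: int
    end: int
    fwd_start: int
    rev_start: int
    fwd_mismatches: int
    rev_mismatches: int
    orientation: str  # "+" fwd on plus strand, "-" fwd on minus strand

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def _match_sites(
    arr: np.ndarray,
    primer: str,
    max_mismatch: int,
    anchor3: int,
    anchor_at_end: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """0-based start positions (and mismatch counts) of primer occurrences.

    ``anchor_at_end`` selects which end of the written sequence carries the
    exact-match 3' anchor (the end for a plus-strand primer, the start for
    a written-out reverse complement whose first base is the 3' terminus).
    """
    m = len(primer)
    n_pos = len(arr) - m + 1
    if n_pos <= 0:
        return np.empty(0, int), np.empty(0, int)
    p = np.frombuffer(primer.upper().encode(), np.uint8)
    anchor = range(m - anchor3, m) if anchor_at_end else range(anchor3)
    mask = np.ones(n_pos, bool)
    for k in anchor:
        mask &= arr[k : k + n_pos] == p[k]
    cand = np.nonzero(mask)[0]
    if cand.size == 0:
        return cand, np.empty(0, int)
    windows = arr[cand[:, None] + np.arange(m)]
    mm = (windows != p).sum(axis=1)
    keep = mm <= max_mismatch
    return cand[keep], mm[keep].astype(int)


def epcr(
    genome: dict[str, str],
    pair: PrimerPair,
    params: EpcrParams | None = None,
) -> list[MarkerPlacement]:
    """All placements of a primer pair on a genome.

    Both orientations are scanned: forward primer on the plus strand with
    the reverse primer on the minus strand downstream, and vice versa.
    """
    params = params or EpcrParams()
    if min(len(pair.fwd), len(pair.rev)) < params.anchor3:
        raise ValueError(f"{pair.marker_id}: primer shorter than the 3' anchor")
    placements: list[MarkerPlacement] = []
    for seq_id in sorted(genome):
        arr = np.frombuffer(genome[seq_id].upper().encode(), np.uint8)
        for orientation, left, right in (
            ("+", pair.fwd, pair.rev),
            ("-", pair.rev, pair.fwd),
        ):
            lpos, lmm = _match_sites(
                arr, left, params.max_mismatch, params.anchor3, True
            )
            rpos, rmm = _match_sites(
                arr, revcomp(right), params.max_mismatch, params.anchor3, False
            )
            if lpos.size == 0 or rpos.size == 0:
                continue
            rlen = len(right)
            for i, i_mm in zip(lpos, lmm):
                # product: left site start .. right site end, size-windowed
                lo = i + params.size_min - rlen  # smallest admissible rpos
                hi = i + params.size_max - rlen
                a = np.searchsorted(rpos, max(lo, i))
                b = np.searchsorted(rpos, hi, side="right")
                for k, k_mm in zip(rpos[a:b], rmm[a:b]):
                    start, end = int(i) + 1, int(k) + rlen
                    fwd_start = start if orientation == "+" else int(k) + 1
                    rev_start = int(k) + 1 if orientation == "+" else start
                    fwd_mm = i_mm if orientation == "+" else k_mm
                    rev_mm = k_mm if orientation == "+" else i_mm
                    placements.append(
                        MarkerPlacement(
                            pair.marker_id, seq_id, start, end,
                            fwd_start, rev_start, int(fwd_mm), int(rev_mm),
                            orientation,
                        )
                    )
    return sorted(placements, key=lambda p: (p.seq_id, p.start, p.end))


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------

CATEGORIES = (
    "within_flank",
    "outside_flank",
    "small_scaffold_no_nbs",
    "scaffold_with_nbs",
    "unplaced",
)


@dataclass(frozen=True)
class QtlParams:
    flank: int = 3_000_000  # symmetric flanking window around each gene
    small_scaffold_max: int = 2_000_000

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.small_scaffold_max <= 0:
            raise ValueError("flank and small_scaffold_max must be positive")


@dataclass(frozen=True)
class MarkerCall:
    marker_id: str
    category: str
    placement: MarkerPlacement | None
    distance: float  # bp from product midpoint to nearest gene (inf if none)


def is_chromosome(seq_id: str, chromosome_ids: set[str] | None = None) -> bool:
    if chromosome_ids is not None:
        return seq_id in chromosome_ids
    return not seq_id.lower().startswith(("scaffold", "contig"))


def _distance_to_nearest(
    mid: float, genes: list[GeneLocus]
) -> float:
    best = float("inf")
    for g in genes:
        if g.start <= mid <= g.end:
            return 0.0
        best = min(best, abs(g.start - mid), abs(mid - g.end))
    return best


def categorize_marker(
    placements: list[MarkerPlacement],
    loci: list[GeneLocus],
    seq_lengths: dict[str, int],
    params: QtlParams | None = None,
    chromosome_ids: set[str] | None = None,
    marker_id: str | None = None,
) -> MarkerCall:
    """Classify one marker from its placements.

    The representative placement is the one nearest to any NBS gene (the
    reading most favorable to co-localization); all placements should
    nonetheless be reported alongside. Placements on unknown sequences are
    an error.
    """
    params = params or QtlParams()
    if not placements:
        return MarkerCall(marker_id or "?", "unplaced", None, float("inf"))
    mid = marker_id or placements[0].marker_id
    genes_by_seq: dict[str, list[GeneLocus]] = {}
    for locus in loci:
        genes_by_seq.setdefault(locus.seq_id, []).append(locus)

    best: tuple[float, int, MarkerPlacement] | None = None
    for idx, pl in enumerate(placements):
        if pl.seq_id not in seq_lengths:
            raise ValueError(f"placement on unknown sequence {pl.seq_id!r}")
        dist = _distance_to_nearest(pl.midpoint, genes_by_seq.get(pl.seq_id, []))
        if best is None or dist < best[0]:
            best = (dist, idx, pl)
    dist, _, rep = best

    if is_chromosome(rep.seq_id, chromosome_ids):
        category = "within_flank" if dist <= params.flank else "outside_flank"
    elif genes_by_seq.get(rep.seq_id):
        category = "scaffold_with_nbs"
    elif seq_lengths[rep.seq_id] <= params.small_scaffold_max:
        category = "small_scaffold_no_nbs"
    else:
        category = "outside_flank"
    return MarkerCall(mid, category, rep, dist)


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


@dataclass
class QtlSummary:
    """Per-location marker/gene counts plus the co-localization shares.

    ``n_within_chromosome`` counts markers inside the flanking window on
    chromosomes; ``n_scaffold_with_nbs`` markers on NBS-bearing scaffolds.
    The headline co-localized count (``n_within_total``) is their sum, and
    ``within_pct`` is its share of placed markers; ``placed_pct`` is the
    share of all markers that could be placed at all.
    """

    table: pd.DataFrame
    n_markers: int
    n_placed: int
    n_within_chromosome: int
    n_outside: int
    n_scaffold_with_nbs: int
    n_scaffold_no_nbs: int
    n_unplaced: int
    n_within_total: int
    within_pct: float
    placed_pct: float


def summarize_qtl(calls: list[MarkerCall], loci: list[GeneLocus]) -> QtlSummary:
    genes_per_seq: dict[str, int] = {}
    for locus in loci:
        genes_per_seq[locus.seq_id] = genes_per_seq.get(locus.seq_id, 0) + 1
    by_cat: dict[str, int] = {c: 0 for c in CATEGORIES}
    rows_by_seq: dict[str, dict[str, int]] = {}
    for call in calls:
        by_cat[call.category] += 1
        if call.placement is None:
            continue
        row = rows_by_seq.setdefault(
            call.placement.seq_id,
            {"n_markers": 0, "n_within": 0, "n_outside": 0},
        )
        row["n_markers"] += 1
        if call.category in ("within_flank", "scaffold_with_nbs"):
            row["n_within"] += 1
        elif call.category == "outside_flank":
            row["n_outside"] += 1
    seq_ids = sorted(set(genes_per_seq) | set(rows_by_seq))
    table = pd.DataFrame(
        [
            {
                "seq_id": s,
                "n_genes": genes_per_seq.get(s, 0),
                **rows_by_seq.get(
                    s, {"n_markers": 0, "n_within": 0, "n_outside": 0}
                ),
            }
            for s in seq_ids
        ],
        columns=["seq_id", "n_genes", "n_markers", "n_within", "n_outside"],
    )
    n_markers = len(calls)
    n_unplaced = by_cat["unplaced"]
    n_placed = n_markers - n_unplaced
    n_within_total = by_cat["within_flank"] + by_cat["scaffold_with_nbs"]
    return QtlSummary(
        table=table,
        n_markers=n_markers,
        n_placed=n_placed,
        n_within_chromosome=by_cat["within_flank"],
        n_outside=by_cat["outside_flank"],
        n_scaffold_with_nbs=by_cat["scaffold_with_nbs"],
        n_scaffold_no_nbs=by_cat["small_scaffold_no_nbs"],
        n_unplaced=n_unplaced,
        n_within_total=n_within_total,
        within_pct=pct(n_within_total, n_placed, 1) if n_placed else 0.0,
        placed_pct=pct(n_placed, n_markers, 1) if n_markers else 0.0,
    )
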