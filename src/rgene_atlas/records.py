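"""Core record types shared across the pipeline.

Coordinates are 1-based inclusive throughout, both for residue intervals on
proteins and for base-pair intervals on chromosomes/scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass(frozen=True)
class ProteinRecord:
    """A gene's translated amino-acid sequence.

    The sequence may contain the 20 standard residues plus ``X`` (unknown)
    and ``*`` (stop, only meaningful as a terminal or internal stop marker).
    Gap characters are not allowed.
    """

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.gene_id!r}")
        bad = set(self.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"invalid residues {sorted(bad)} in protein {self.gene_id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """A gene's genomic interval (1-based inclusive)."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"bad interval {self.start}-{self.end} for {self.gene_id!r}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0
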