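"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython, GFF3 through gffutils; the tabular formats
(evidence, primers, classifications, summaries) are plain TSVs handled with
pandas. Genomic intervals are 1-based inclusive in GFF3 and in memory;
cluster BED output is 0-based half-open per the BED convention.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .domain_scan import DomainEvidence, evidence_to_frame
from .genome_architecture import GeneCluster
from .qtl_colocalization import PrimerPair
from .records import GeneLocus, ProteinRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_proteins(path: str | Path) -> dict[str, ProteinRecord]:
    return {
        gid: ProteinRecord(gid, seq) for gid, seq in read_fasta(path).items()
    }


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_gff_loci(path: str | Path, feature_type: str = "gene") -> list[GeneLocus]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    loci = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        loci.append(
            GeneLocus(feat.id, feat.seqid, feat.start, feat.end,
                      feat.strand if feat.strand in "+-" else "+")
        )
    return loci


def write_gff3(path: str | Path, loci: list[GeneLocus]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in sorted(loci, key=lambda l: (l.seq_id, l.start)):
            fh.write(
                f"{locus.seq_id}\trgene_atlas\tgene\t{locus.start}\t{locus.end}"
                f"\t.\t{locus.strand}\t.\tID={locus.gene_id}\n"
            )


def write_evidence_tsv(path: str | Path, evidence: list[DomainEvidence]) -> None:
    """Six-column evidence TSV re-readable by ``ingest_domain_tsv``."""
    acc_by_type = {"NBS": "PF00931", "TIR": "SYNTH_TIR", "LRR": "SYNTH_LRR"}
    with open(path, "w") as fh:
        for ev in evidence:
            acc = acc_by_type.get(ev.domain_type, ev.name or ev.domain_type)
            fh.write(
                f"{ev.gene_id}\t{acc}\t{ev.name}\t{ev.start}\t{ev.end}"
                f"\t{ev.score}\n"
            )


def write_consolidated_evidence(path: str | Path, evidence: list[DomainEvidence]) -> None:
    evidence_to_frame(evidence).to_csv(path, sep="\t", index=False)


def read_primer_tsv(path: str | Path) -> list[PrimerPair]:
    df = pd.read_csv(path, sep="\t")
    required = {"marker_id", "fwd", "rev"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return [
        PrimerPair(
            str(r.marker_id), str(r.fwd), str(r.rev),
            str(getattr(r, "trait", "")),
        )
        for r in df.itertuples(index=False)
    ]


def write_primer_tsv(path: str | Path, primers: list[PrimerPair]) -> None:
    pd.DataFrame(
        [
            {"marker_id": p.marker_id, "fwd": p.fwd, "rev": p.rev,
             "trait": p.trait}
            for p in primers
        ]
    ).to_csv(path, sep="\t", index=False)


def write_clusters_bed(path: str | Path, clusters: list[GeneCluster]) -> None:
    """BED (0-based half-open) with the member list in column 4."""
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters, start=1):
            members = ",".join(cl.members)
            fh.write(
                f"{cl.seq_id}\t{cl.span[0] - 1}\t{cl.span[1]}\t"
                f"cluster{i};{members}\n"
            )
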