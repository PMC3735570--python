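"""Scan proteins for NBS motifs and coiled-coils, then assign letter codes.

Builds a handful of synthetic resistance proteins with known domain layouts,
runs the built-in scanners and the classifier, and prints each gene's motif
content and composed letter code (e.g. CNL = strong coiled-coil N-terminus,
NBS domain, LRR C-terminus).
"""

import numpy as np

from rgene_atlas import classify_gene, scan_nbs_motifs, score_coiled_coil
from rgene_atlas.classify import summarize_classes
from rgene_atlas.synthetic_data import generate_gene

rng = np.random.default_rng(42)
specs = [
    ("CNL", "regular"),
    ("cNX", "regular"),
    ("TNL", "non-regular"),
    ("NX", "non-regular"),
    ("XN", "non-regular"),
]

records = []
for code, regularity in specs:
    art = generate_gene(code, regularity, rng, gene_id=f"demo_{code}")
    hits = scan_nbs_motifs(art.protein)
    profile = score_coiled_coil(art.protein)
    rec = classify_gene(art.protein, hits, art.evidence, profile)
    records.append(rec)
    motifs = ",".join(h.motif_name for h in hits)
    print(
        f"{rec.gene_id:>10}  {rec.letter_code:>4}  {rec.regularity:>11}  "
        f"motifs: {motifs}"
    )

summary = summarize_classes(records)
print("\nSubgroup counts (percent of the 5 demo genes):")
print(summary.table.to_string(index=False))
# Each gene's printed letter code matches its planted layout; a "regular"
# gene carries all five NBS motifs in order plus a complete ORF, while the
# non-regular genes carry an end-truncated contiguous subset.
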