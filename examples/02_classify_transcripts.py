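"""Classify long-read transcripts against a reference annotation.

A query transcript is a known isoform when its intron chain matches an
annotated transcript, a novel isoform when it overlaps a known gene's
exons with a new chain, and otherwise founds (or joins) a novel locus.
"""

from isotrx import classify, simulate
from isotrx.model import TranscriptModel

cfg = simulate.SimulationConfig(seed=42, n_genes=30)
genes, _, _ = simulate.simulate_reference(cfg)

known = genes[0].transcripts[0]
shifted = list(known.exons)
shifted[1] = (shifted[1][0] + 15, shifted[1][1])  # move one acceptor 15 bp
queries = [
    known,
    TranscriptModel("novel_iso", known.chrom, known.strand, tuple(shifted)),
    TranscriptModel("novel_loc", "chr9", "+", ((1000, 2000), (3000, 4000))),
]
for call in classify.classify_transcripts(queries, genes):
    print(f"{call.transcript_id:>10} -> {call.category} ({call.matched_gene_id})")
# The annotated transcript is recognized by its intron chain; the shifted
# acceptor makes a novel isoform of the same gene; the off-annotation
# query founds a novel locus.
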