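#!/usr/bin/env python
"""Scan 500 bp proximal promoters for the MBS and MBSIIG MYB cis-elements.

Extracts the 500 bp upstream of each annotated translation start (both
gene orientations handled) and scans both strands for the two degenerate
consensus motifs, writing a BED-like hit list and a gene-by-motif presence
table.
"""

import argparse
from pathlib import Path

import pandas as pd

from lignoreg import io_formats, promoter_motif


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    genome = io_formats.read_fasta(args.data / "genome.fa")
    genes = io_formats.read_gff3(args.data / "genes.gff3")
    presence, hits, errors = promoter_motif.motif_presence_table(genes, genome)
    for gene, msg in errors.items():
        print(f"warning: {gene} skipped ({msg})")

    io_formats.write_bed_hits(
        [(h.gene_id, h.pos - 1, h.pos + 7, h.motif, 0, h.strand) for h in hits],
        args.outdir / "motif_hits.bed",
    )
    table = pd.DataFrame(presence).T.rename_axis("gene_id")
    table.to_csv(args.outdir / "motif_presence.tsv", sep="\t")

    print(f"scanned {len(presence)} promoters; {len(hits)} motif hit(s)")
    for motif in table.columns:
        with_m = table.index[table[motif]].tolist()
        print(f"  {motif} present in {len(with_m)}/{len(table)}: {with_m}")


if __name__ == "__main__":
    main()
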