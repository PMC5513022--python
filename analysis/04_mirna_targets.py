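#!/usr/bin/env python
"""Predict miRNA target sites on the transcript screen.

Slides the mature miRNA over every transcript window, scores mismatches
(1.0) and G:U wobbles (0.5), applies the positional duplex rules and the
penalty <= 2.5 threshold, and writes accepted hits with their predicted
cleavage coordinates.
"""

import argparse
from pathlib import Path

import pandas as pd

from lignoreg import io_formats, mirna_target


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--threshold", type=float, default=2.5)
    ap.add_argument("--out", type=Path, default=Path("results/hits.tsv"))
    args = ap.parse_args()

    mir_rec = io_formats.read_fasta(args.data / "mirna.fa")[0]
    mir = mirna_target.Mirna(mir_rec.id, mir_rec.seq)
    txs = io_formats.read_fasta(args.data / "transcripts.fa")
    hits = mirna_target.scan_transcriptome(mir, txs, threshold=args.threshold)

    pd.DataFrame(
        [
            {
                "transcript_id": h.transcript_id, "start": h.start, "end": h.end,
                "penalty": h.penalty, "pair_classes": h.pair_classes,
                "cleavage_pos": h.cleavage_pos,
            }
            for h in hits
        ]
    ).to_csv(args.out, sep="\t", index=False)

    targets = sorted({h.transcript_id for h in hits})
    penalties = sorted(h.penalty for h in hits)
    print(f"screened {len(txs)} transcripts with {mir.id} ({len(mir)} nt)")
    print(f"predicted targets: {len(targets)} "
          f"(penalties {penalties[0]:.1f}-{penalties[-1]:.1f}): {targets}")


if __name__ == "__main__":
    main()
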