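#!/usr/bin/env python
"""Combine expression, clustering and promoter evidence into candidate calls.

A gene is called a bona fide lignin-pathway candidate when it is at least
2-fold up (P < 0.01) in stem vs leaf, root vs leaf AND inner vs outer stem
tissue; co-clustering with the other candidates and MBSIIG promoter
presence are reported as corroborating evidence.
"""

import argparse
from pathlib import Path

import pandas as pd

from lignoreg import prioritize, qpcr_quant


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--calls", type=Path, default=Path("results/calls.tsv"))
    ap.add_argument("--clusters", type=Path, default=Path("results/clusters.tsv"))
    ap.add_argument("--motifs", type=Path, default=Path("results/motif_presence.tsv"))
    ap.add_argument("--min-lfc", type=float, default=1.0)
    ap.add_argument("--alpha", type=float, default=0.01)
    ap.add_argument("--out", type=Path, default=Path("results/candidates.tsv"))
    args = ap.parse_args()

    df = pd.read_csv(args.calls, sep="\t")
    calls = [
        qpcr_quant.DiffCall(
            assay=r.assay, condition=r.condition, control=r.control,
            log2_ratio=float(r.log2_ratio), p_value=float(r.p_value),
            significant=bool(r.significant), testable=bool(r.testable),
        )
        for r in df.itertuples()
    ]
    cdf = pd.read_csv(args.clusters, sep="\t")
    clusters = dict(zip(cdf["gene_id"], cdf["cluster"].astype(int)))
    mdf = pd.read_csv(args.motifs, sep="\t", index_col=0)
    motifs = {g: row.astype(bool).to_dict() for g, row in mdf.iterrows()}

    candidates = prioritize.call_candidates(
        calls, clusters, motifs, min_lfc=args.min_lfc, alpha=args.alpha
    )
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id, "bona_fide": c.bona_fide,
                **{f"log2fc_{k}": round(v, 3) for k, v in sorted(c.log2fc.items())},
                "cluster": c.cluster, "in_modal_cluster": c.in_modal_cluster,
                "mbsiig_present": c.mbsiig_present, "evidence": c.evidence,
            }
            for c in candidates
        ]
    ).to_csv(args.out, sep="\t", index=False)

    bona = [c for c in candidates if c.bona_fide]
    print(f"{len(bona)} bona fide candidate(s) of {len(candidates)} assayed genes:")
    for c in bona:
        lfc = ", ".join(f"{k}={v:.2f}" for k, v in sorted(c.log2fc.items()))
        print(f"  {c.gene_id}: {lfc}; cluster {c.cluster}"
              f"{' (modal)' if c.in_modal_cluster else ''};"
              f" MBSIIG {'present' if c.mbsiig_present else 'absent'}")


if __name__ == "__main__":
    main()
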