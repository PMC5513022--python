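#!/usr/bin/env python
"""Normalize the Cq table and call differential expression.

Estimates per-assay amplification efficiencies from the dilution series,
computes normalized relative quantities against the three reference genes,
and tests stem-vs-leaf, root-vs-leaf and inner-vs-outer stem tissue with
the exact Mann-Whitney test (P < 0.01).  Writes nrq.tsv, calls.tsv and the
log2 heat-map table under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from lignoreg import io_formats, qpcr_quant
from lignoreg.pipeline import REFERENCE_ASSAYS


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.01)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cq_df = io_formats.read_cq_table(args.data / "cq.tsv")
    dil = pd.read_csv(args.data / "dilutions.tsv", sep="\t")
    eff = qpcr_quant.estimate_efficiency(dil)
    print(f"efficiencies: {min(eff.values()):.3f}-{max(eff.values()):.3f} "
          f"over {len(eff)} assays")

    cq = qpcr_quant.CqMatrix(cq_df, eff, frozenset(REFERENCE_ASSAYS))
    nrq = qpcr_quant.normalize(cq)
    comparisons = [("stem", "leaf"), ("root", "leaf"), ("IT", "OT")]
    calls, heatmap = qpcr_quant.condition_ratios(nrq, comparisons, alpha=args.alpha)

    nrq.values.to_csv(args.outdir / "nrq.tsv", sep="\t", index=False)
    pd.DataFrame([vars(c) for c in calls]).to_csv(
        args.outdir / "calls.tsv", sep="\t", index=False
    )
    heatmap.to_csv(args.outdir / "heatmap.tsv", sep="\t")

    n_sig = sum(c.significant for c in calls)
    print(f"{len(calls)} comparisons tested, {n_sig} significant at "
          f"P < {args.alpha}")
    up_all = heatmap[(heatmap >= 1).all(axis=1)].index.tolist()
    print(f"genes >=2-fold up in all three comparisons: {up_all}")


if __name__ == "__main__":
    main()
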