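"""Combine expression, clustering and promoter evidence into candidate calls.

A gene is a *bona fide* lignin-pathway candidate when it is significantly
and substantially up-regulated in every lignifying-vs-hypolignified
comparison: stem vs leaf, root vs leaf, and inner (xylem-rich) vs outer
(bast-fiber-rich) stem tissue.  The gate is explicit — log2 fold change at
least ``min_lfc`` (default 1.0, i.e. 2-fold) with Mann-Whitney P below
``alpha`` (default 0.01) in all three.  Co-membership in the modal cluster
of the candidates and MBSIIG promoter presence are reported as
corroborating evidence but never gate the call; a gene strongly induced in
only some comparisons (the LusHCT4 pattern — high in the outer, poorly
lignified tissues) is thereby excluded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .qpcr_quant import DiffCall

__all__ = ["CandidateCall", "call_candidates", "REQUIRED_COMPARISONS"]

# (condition, control) pairs the call gates on
REQUIRED_COMPARISONS = (
    ("stem", "leaf"),
    ("root", "leaf"),
    ("IT", "OT"),
)


@dataclass
class CandidateCall:
    gene_id: str
    log2fc: dict[str, float]  # comparison name -> log2 ratio
    p_values: dict[str, float]
    cluster: int | None
    in_modal_cluster: bool
    mbsiig_present: bool | None
    bona_fide: bool
    evidence: str = ""


def call_candidates(
    diffcalls: list[DiffCall],
    clusters: dict[str, int] | None = None,
    motif_presence: dict[str, dict[str, bool]] | None = None,
    min_lfc: float = 1.0,
    alpha: float = 0.01,
    comparisons=REQUIRED_COMPARISONS,
) -> list[CandidateCall]:
    """Gate every assayed gene on the three expression comparisons.

    ``diffcalls`` must cover each (condition, control) in ``comparisons``
    for the genes to be callable; a missing comparison is an error.  Genes
    absent from ``clusters`` are flagged, not fatal.  Raising ``min_lfc`` or
    lowering ``alpha`` can only remove candidates (monotone gate).
    """
    clusters = clusters or {}
    motif_presence = motif_presence or {}
    wanted = {f"{c}_vs_{ctrl}": (c, ctrl) for c, ctrl in comparisons}
    by_gene: dict[str, dict[str, DiffCall]] = {}
    for dc in diffcalls:
        name = f"{dc.condition}_vs_{dc.control}"
        if name in wanted:
            by_gene.setdefault(dc.assay, {})[name] = dc

    calls: list[CandidateCall] = []
    for gene, comps in sorted(by_gene.items()):
        missing = set(wanted) - set(comps)
        if missing:
            raise ValueError(f"gene {gene}: missing comparison(s) {sorted(missing)}")
        lfc = {n: c.log2_ratio for n, c in comps.items()}
        pvals = {n: c.p_value for n, c in comps.items()}
        ok = all(
            c.testable and c.log2_ratio >= min_lfc and c.p_value < alpha
            for c in comps.values()
        )
        calls.append(
            CandidateCall(
                gene_id=gene,
                log2fc=lfc,
                p_values=pvals,
                cluster=clusters.get(gene),
                in_modal_cluster=False,
                mbsiig_present=motif_presence.get(gene, {}).get("MBSIIG"),
                bona_fide=ok,
            )
        )

    # corroborating (non-gating): do candidates share one co-expression cluster?
    candidate_clusters = [
        c.cluster for c in calls if c.bona_fide and c.cluster is not None
    ]
    modal = Counter(candidate_clusters).most_common(1)[0][0] if candidate_clusters else None
    for c in calls:
        c.in_modal_cluster = modal is not None and c.cluster == modal
        parts = [
            f"min_lfc={min_lfc}",
            f"alpha={alpha}",
            "bona_fide" if c.bona_fide else "rejected",
        ]
        if c.cluster is None:
            parts.append("unclustered")
        elif c.in_modal_cluster:
            parts.append(f"co-clustered(cluster {modal})")
        if c.mbsiig_present:
            parts.append("MBSIIG+")
        c.evidence = ";".join(parts)
    return calls
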