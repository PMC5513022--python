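"""Proximal-promoter extraction and degenerate MYB cis-element scanning.

Promoters are the 500 bp immediately upstream of the annotated translation
start (the only anchor reproducibly annotated), reported 5'→3' on the gene's
coding strand.  Both strands of each promoter are scanned for the two MYB
binding consensus motifs:

* MBS     = YAACWAMC  —  (C/T)AAC(A/T)A(A/C)C
* MBSIIG  = YACCWAMC  —  (C/T)ACC(A/T)A(A/C)C  (a.k.a. SMRE)

Each consensus expands to exactly 8 concrete 8-mers (2·1·1·1·2·1·2·1).
Hit positions are reported both promoter-local (1-based, 5'-most matched
base) and relative to the anchor (anchor = 0, so a full-length promoter
yields positions in [−500, −8]).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass

from .io_formats import GeneModel, SeqRecord, reverse_complement

__all__ = [
    "MotifDef",
    "MotifHit",
    "DEFAULT_MOTIFS",
    "iupac_expand",
    "extract_promoter",
    "scan_motifs",
    "motif_presence_table",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifDef:
    name: str
    consensus: str  # IUPAC degenerate, DNA

    def __post_init__(self) -> None:
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC codes {sorted(bad)}")

    def regex(self) -> str:
        return "".join(
            b if len(IUPAC[b]) == 1 else f"[{IUPAC[b]}]"
            for b in self.consensus.upper()
        )

    def words(self) -> list[str]:
        """All concrete words the consensus matches."""
        return [
            "".join(w)
            for w in itertools.product(*(IUPAC[b] for b in self.consensus.upper()))
        ]


DEFAULT_MOTIFS = (
    MotifDef("MBS", "YAACWAMC"),
    MotifDef("MBSIIG", "YACCWAMC"),
)


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif: str
    strand: str  # + : consensus on given sequence; - : its reverse complement
    pos: int  # 1-based, 5'-most base of the match on the promoter sequence
    pos_rel_anchor: int  # anchor (translation start) = 0


def extract_promoter(
    genome: dict[str, SeqRecord] | list[SeqRecord],
    gene: GeneModel,
    length: int = 500,
) -> SeqRecord:
    """The `length` bases upstream of the translation start, 5'→3'.

    + strand: genomic [cds_start − length, cds_start − 1].
    − strand: reverse complement of [cds_end + 1, cds_end + length].
    Truncated at the scaffold edge with a warning; a zero-length promoter is
    an error.
    """
    if isinstance(genome, list):
        genome = {r.id: r for r in genome}
    scaffold = genome[gene.seq_id]
    if gene.strand == "+":
        start1 = max(1, gene.cds_start - length)
        end1 = gene.cds_start - 1
        seq = scaffold.seq[start1 - 1 : end1]
    else:
        start1 = gene.cds_end + 1
        end1 = min(len(scaffold), gene.cds_end + length)
        seq = reverse_complement(scaffold.seq[start1 - 1 : end1])
    if len(seq) == 0:
        raise ValueError(f"gene {gene.gene_id}: empty promoter after truncation")
    if len(seq) < length:
        warnings.warn(
            f"gene {gene.gene_id}: promoter truncated to {len(seq)} bp at scaffold edge"
        )
    return SeqRecord(f"{gene.gene_id}_promoter", seq, "DNA")


def scan_motifs(
    promoter: SeqRecord, motifs: tuple[MotifDef, ...] = DEFAULT_MOTIFS, gene_id: str | None = None
) -> list[MotifHit]:
    """All overlapping occurrences of each motif on both strands.

    − strand hits are found by matching the reverse complement of the
    consensus against the promoter sequence; the reported position is the
    5'-most matched base in promoter coordinates either way.  The
    anchor-relative position is ``pos − L − 1`` for a promoter of length L
    (so pos 1 on a 500 bp promoter is −500).
    """
    gene_id = gene_id or promoter.id.removesuffix("_promoter")
    seq = promoter.seq
    L = len(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        for strand, pattern in (
            ("+", motif.regex()),
            ("-", MotifDef(motif.name, reverse_complement(motif.consensus)).regex()),
        ):
            for m in re.finditer(f"(?=({pattern}))", seq):
                pos = m.start() + 1
                hits.append(MotifHit(gene_id, motif.name, strand, pos, pos - L - 1))
    hits.sort(key=lambda h: (h.motif, h.pos, h.strand))
    return hits


def motif_presence_table(
    genes: list[GeneModel],
    genome: dict[str, SeqRecord] | list[SeqRecord],
    motifs: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
    length: int = 500,
) -> tuple[dict[str, dict[str, bool]], list[MotifHit], dict[str, str]]:
    """Per-gene presence of each motif plus the full hit list.

    Returns (presence, hits, errors): ``presence[gene][motif]`` is a boolean,
    ``errors`` maps gene_id → message for genes whose promoter could not be
    extracted (others continue).
    """
    presence: dict[str, dict[str, bool]] = {}
    all_hits: list[MotifHit] = []
    errors: dict[str, str] = {}
    for gene in genes:
        try:
            promoter = extract_promoter(genome, gene, length=length)
        except (ValueError, KeyError) as exc:
            errors[gene.gene_id] = str(exc)
            continue
        hits = scan_motifs(promoter, motifs, gene_id=gene.gene_id)
        all_hits.extend(hits)
        presence[gene.gene_id] = {
            m.name: any(h.motif == m.name for h in hits) for m in motifs
        }
    return presence, all_hits, errors
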