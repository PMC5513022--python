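"""Map RLM-RACE fragment 5' ends onto transcripts and summarise cleavage.

RNA-ligase-mediated 5'-RACE captures the uncapped 5' ends of miRNA-cleaved
transcripts; the 5'-most base of a sequenced fragment marks the cleavage
site.  Each adaptor-trimmed fragment is located by exact full-length
substring search across all transcripts: a fragment counts only if it
occurs exactly once in the whole set (multi-locus fragments are ambiguous,
absent ones unmapped).  Per transcript the report gives the clone count at
every observed 5' position and, once a predicted site from the duplex
scanner is attached, the "x/y" statistic — fragments at the predicted
position over total mapped clones for the transcript.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import FormatError, SeqRecord
from .mirna_target import DuplexHit

__all__ = ["CleavageReport", "map_fragments", "confirm"]

DEFAULT_MIN_CLONES = 2


@dataclass
class CleavageReport:
    transcript_id: str
    position_counts: dict[int, int] = field(default_factory=dict)  # 1-based 5' pos
    total: int = 0  # mapped clones on this transcript
    ambiguous: int = 0
    unmapped: int = 0
    predicted_pos: int | None = None
    validated: bool | None = None

    @property
    def at_site(self) -> int:
        if self.predicted_pos is None:
            return 0
        return self.position_counts.get(self.predicted_pos, 0)

    @property
    def fraction_string(self) -> str:
        return f"{self.at_site}/{self.total}"


def _occurrences(fragment: str, seq: str) -> list[int]:
    """All 0-based start positions of fragment in seq (overlaps included)."""
    out, start = [], 0
    while True:
        i = seq.find(fragment, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def map_fragments(
    fragments: list[SeqRecord], transcripts: list[SeqRecord]
) -> dict[str, CleavageReport]:
    """Exact-match mapping of fragment 5' ends; one report per transcript.

    A fragment maps iff it occurs exactly once across all transcripts; its
    1-based start position is counted.  Ambiguous and unmapped totals are
    spread onto every report so the conservation
    mapped + ambiguous + unmapped = n_fragments holds per report.
    """
    reports = {
        tx.id: CleavageReport(tx.id) for tx in transcripts
    }
    counters: dict[str, Counter] = {tx.id: Counter() for tx in transcripts}
    n_ambiguous = 0
    n_unmapped = 0
    for frag in fragments:
        if len(frag.seq) == 0:
            raise FormatError(f"empty RACE fragment {frag.id}")
        locs = [
            (tx.id, pos0)
            for tx in transcripts
            for pos0 in _occurrences(frag.seq, tx.seq)
        ]
        if len(locs) == 1:
            tx_id, pos0 = locs[0]
            counters[tx_id][pos0 + 1] += 1
        elif len(locs) > 1:
            n_ambiguous += 1
        else:
            n_unmapped += 1
    for tx_id, counter in counters.items():
        rep = reports[tx_id]
        rep.position_counts = dict(sorted(counter.items()))
        rep.total = sum(counter.values())
        rep.ambiguous = n_ambiguous
        rep.unmapped = n_unmapped
    return reports


def confirm(
    reports: dict[str, CleavageReport],
    hits: list[DuplexHit],
    min_clones: int = DEFAULT_MIN_CLONES,
) -> dict[str, CleavageReport]:
    """Attach predicted cleavage positions and call validation.

    For each transcript with an accepted duplex hit, predicted_pos is the
    hit's cleavage coordinate (best-penalty hit if several) and the
    transcript is VALIDATED iff at least ``min_clones`` fragments start
    exactly there.  The x/y fraction is the primary output; the boolean call
    is advisory.  Transcripts without a prediction keep predicted_pos None.
    """
    best: dict[str, DuplexHit] = {}
    for h in hits:
        if not h.accepted:
            continue
        cur = best.get(h.transcript_id)
        if cur is None or (h.penalty, h.start) < (cur.penalty, cur.start):
            best[h.transcript_id] = h
    for tx_id, rep in reports.items():
        hit = best.get(tx_id)
        if hit is None:
            rep.predicted_pos = None
            rep.validated = None
        else:
            rep.predicted_pos = hit.cleavage_pos
            rep.validated = rep.at_site >= min_clones
    return reports
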