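"""Ungapped miRNA target prediction with wobble-aware penalty scoring.

A mature miRNA (5'→3', RNA) is slid over every window of each transcript
(read as RNA: T ≡ U).  The duplex is antiparallel, so miRNA position *i*
(1 = miRNA 5' end) pairs with window position ``L − i + 1``.  Each position
is classed M (Watson–Crick), W (G:U wobble) or X (mismatch); the penalty is
``1.0·#X + 0.5·#W``.  A hit is accepted when it satisfies the positional
rules — at most one mismatch among miRNA positions 1–9, none at 10–11, no
run of more than two consecutive mismatches after position 11 — and its
penalty does not exceed the threshold (2.5 by default, boundary inclusive).
Wobbles count as pairs for all positional rules but still cost 0.5.

The predicted cleavage site is the transcript nucleotide paired with miRNA
position 10: the 5' nucleotide of the 3' cleavage fragment, which is what
RLM-RACE sequencing observes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .io_formats import SeqRecord

__all__ = [
    "Mirna",
    "DuplexHit",
    "classify_pair",
    "score_window",
    "apply_rules",
    "scan_transcriptome",
    "DEFAULT_PENALTY_THRESHOLD",
]

DEFAULT_PENALTY_THRESHOLD = 2.5

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}
_RNA = set("ACGU")


@dataclass
class Mirna:
    """A mature miRNA sequence, 5'→3', RNA alphabet, no ambiguity codes."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("T", "U")
        bad = set(self.seq) - _RNA
        if bad:
            raise ValueError(f"miRNA {self.id}: ambiguous bases {sorted(bad)}")
        if len(self.seq) < 12:
            raise ValueError(
                f"miRNA {self.id}: length {len(self.seq)} < 12 "
                "(positional rules reference position 11)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class DuplexHit:
    """One ungapped miRNA:window duplex.

    ``start``/``end`` are 1-based inclusive transcript coordinates of the
    window; ``pair_classes[i-1]`` is the class at miRNA position *i*;
    ``cleavage_pos`` is the 1-based transcript coordinate paired with miRNA
    position 10.
    """

    transcript_id: str
    start: int
    end: int
    pair_classes: str
    penalty: float
    cleavage_pos: int
    accepted: bool = False
    reasons: tuple[str, ...] = ()


def classify_pair(mirna_base: str, target_base: str) -> str:
    """Class of one duplex position: M (Watson–Crick), W (G:U wobble), X.

    The target base is read as RNA (T ≡ U).  Ambiguity codes are an error.
    """
    m = mirna_base.upper()
    t = target_base.upper().replace("T", "U")
    if m not in _RNA or t not in _RNA:
        raise ValueError(f"ambiguous base in pair ({mirna_base}, {target_base})")
    pair = (m, t)
    if pair in _WC:
        return "M"
    if pair in _WOBBLE:
        return "W"
    return "X"


def score_window(
    mirna: Mirna, window: str, transcript_id: str = "", window_start: int = 1
) -> DuplexHit:
    """Score one transcript window of length L against the miRNA (unfiltered).

    ``window_start`` is the 1-based transcript coordinate of the window's
    first base; cleavage_pos = window_start + (L − 10).
    """
    L = len(mirna)
    if len(window) != L:
        raise ValueError(f"window length {len(window)} != miRNA length {L}")
    classes = []
    for i in range(1, L + 1):  # miRNA position i pairs with window pos L-i+1
        classes.append(classify_pair(mirna.seq[i - 1], window[L - i]))
    pair_classes = "".join(classes)
    penalty = 1.0 * pair_classes.count("X") + 0.5 * pair_classes.count("W")
    return DuplexHit(
        transcript_id=transcript_id,
        start=window_start,
        end=window_start + L - 1,
        pair_classes=pair_classes,
        penalty=penalty,
        cleavage_pos=window_start + (L - 10),
    )


def apply_rules(
    hit: DuplexHit,
    threshold: float = DEFAULT_PENALTY_THRESHOLD,
    strict_wc_at_site: bool = False,
) -> DuplexHit:
    """Apply the positional duplex rules and penalty threshold.

    Reason codes: SEED (>1 mismatch at positions 1–9), SITE (mismatch at 10
    or 11; with ``strict_wc_at_site`` a wobble there also rejects), RUN
    (>2 consecutive mismatches after position 11), PENALTY (penalty above
    threshold).  ``accepted`` iff no reason applies.
    """
    pc = hit.pair_classes
    L = len(pc)
    reasons: list[str] = []
    if pc[0:9].count("X") > 1:
        reasons.append("SEED")
    site = pc[9:11]
    if "X" in site or (strict_wc_at_site and "W" in site):
        reasons.append("SITE")
    run = 0
    for c in pc[11:L]:
        run = run + 1 if c == "X" else 0
        if run > 2:
            reasons.append("RUN")
            break
    if hit.penalty > threshold:
        reasons.append("PENALTY")
    hit.reasons = tuple(reasons)
    hit.accepted = not reasons
    return hit


def scan_transcriptome(
    mirna: Mirna,
    transcripts: list[SeqRecord],
    threshold: float = DEFAULT_PENALTY_THRESHOLD,
    strict_wc_at_site: bool = False,
    report_rejected: bool = False,
) -> list[DuplexHit]:
    """Scan every window of every transcript; return accepted hits.

    Overlapping accepted hits are all reported, sorted by
    (transcript, penalty, position).  Transcripts shorter than the miRNA are
    skipped with a warning.  With ``report_rejected`` every scored window is
    returned (rejected ones carry their reason codes).
    """
    L = len(mirna)
    hits: list[DuplexHit] = []
    for tx in transcripts:
        if len(tx) < L:
            warnings.warn(
                f"transcript {tx.id} shorter than miRNA ({len(tx)} < {L}); skipped"
            )
            continue
        for start0 in range(len(tx) - L + 1):
            hit = score_window(
                mirna, tx.seq[start0 : start0 + L], tx.id, start0 + 1
            )
            apply_rules(hit, threshold=threshold, strict_wc_at_site=strict_wc_at_site)
            if hit.accepted or report_rejected:
                hits.append(hit)
    hits.sort(key=lambda h: (h.transcript_id, h.penalty, h.start))
    return hits
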