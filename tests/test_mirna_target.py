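import numpy as np
import pytest

from lignoreg import mirna_target as mt
from lignoreg.io_formats import SeqRecord, reverse_complement
from lignoreg.synthetic_data import make_targets

# independent per-position oracle tables (kept separate from the implementation)
_ORACLE_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_ORACLE_WOBBLE = {("G", "U"), ("U", "G")}


def _oracle_classify(m, t):
    t = t.replace("T", "U")
    if (m, t) in _ORACLE_WC:
        return "M"
    if (m, t) in _ORACLE_WOBBLE:
        return "W"
    return "X"


def _oracle_score(mirna_seq, window):
    L = len(mirna_seq)
    classes = "".join(
        _oracle_classify(mirna_seq[i], window[L - 1 - i]) for i in range(L)
    )
    return classes, classes.count("X") + 0.5 * classes.count("W")


def _oracle_rules_ok(classes, penalty, threshold=2.5):
    if classes[:9].count("X") > 1:
        return False
    if "X" in classes[9:11]:
        return False
    if "XXX" in classes[11:]:
        return False
    return penalty <= threshold


# --- pair classification -----------------------------------------------------

@pytest.mark.parametrize(
    "m,t,cls",
    [("G", "C", "M"), ("A", "T", "M"), ("A", "U", "M"),
     ("G", "U", "W"), ("G", "T", "W"), ("U", "G", "W"),
     ("A", "G", "X"), ("C", "U", "X"), ("A", "C", "X")],
)
def test_classify_pair(m, t, cls):
    assert mt.classify_pair(m, t) == cls


def test_classify_pair_rejects_ambiguity_codes():
    with pytest.raises(ValueError):
        mt.classify_pair("N", "A")


def test_mirna_validation():
    with pytest.raises(ValueError, match="12"):
        mt.Mirna("short", "ACGUACGUACG")
    with pytest.raises(ValueError, match="ambiguous"):
        mt.Mirna("amb", "ACGUACGUACGUN")


# --- window scoring ----------------------------------------------------------

def test_perfect_reverse_complement_scores_zero(mir397):
    window = reverse_complement(mir397.seq)
    hit = mt.score_window(mir397, window)
    assert hit.penalty == 0.0 and set(hit.pair_classes) == {"M"}


def test_single_wobble_scores_half(mir397):
    window = list(reverse_complement(mir397.seq))
    # miRNA position 10 is G; antiparallel partner is window position L-9
    L = len(mir397)
    window[L - 10] = "T"  # G:C -> G:U wobble
    hit = mt.score_window(mir397, "".join(window))
    assert hit.penalty == 0.5
    assert hit.pair_classes[9] == "W"


def test_window_length_mismatch_errors(mir397):
    with pytest.raises(ValueError, match="length"):
        mt.score_window(mir397, "ACGT")


def test_cleavage_coordinate_is_position_ten_partner(mir397):
    L = len(mir397)
    hit = mt.score_window(mir397, reverse_complement(mir397.seq), "tx", 101)
    assert hit.cleavage_pos == 101 + (L - 10)
    # the base at cleavage_pos occupies window offset L-10, the antiparallel
    # partner of miRNA position 10
    offset = hit.cleavage_pos - hit.start
    assert offset == L - 10


def test_scoring_matches_independent_oracle_on_random_windows(mir397):
    rng = np.random.default_rng(0)
    L = len(mir397)
    for _ in range(10_000):
        window = "".join(rng.choice(list("ACGT"), L))
        hit = mt.score_window(mir397, window)
        classes, penalty = _oracle_score(mir397.seq, window)
        assert hit.pair_classes == classes and hit.penalty == penalty


# --- rules -------------------------------------------------------------------

def _hit_from_classes(classes):
    hit = mt.DuplexHit("t", 1, len(classes), classes,
                       classes.count("X") + 0.5 * classes.count("W"), 1)
    return hit


@pytest.mark.parametrize(
    "edits,reasons",
    [
        ([(10, "X")], ("SITE",)),
        ([(11, "X")], ("SITE",)),
        ([(1, "X"), (5, "X")], ("SEED",)),
        ([(13, "X"), (14, "X"), (15, "X")], ("RUN", "PENALTY")),
        ([(4, "X"), (14, "X"), (17, "X")], ("PENALTY",)),
    ],
)
def test_rejection_reason_codes(edits, reasons):
    classes = ["M"] * 21
    for pos, c in edits:
        classes[pos - 1] = c
    hit = mt.apply_rules(_hit_from_classes("".join(classes)))
    assert not hit.accepted and hit.reasons == reasons


def test_three_consecutive_wobbles_accepted_as_pairs():
    # wobbles are pairs, not mismatches: W at 13,14,15 passes the run rule
    classes = ["M"] * 21
    for pos in (13, 14, 15):
        classes[pos - 1] = "W"
    hit = mt.apply_rules(_hit_from_classes("".join(classes)))
    assert hit.accepted and hit.penalty == 1.5


def test_strict_wc_at_site_flag_rejects_wobble_at_ten():
    classes = ["M"] * 21
    classes[9] = "W"
    hit = mt.apply_rules(_hit_from_classes("".join(classes)), strict_wc_at_site=True)
    assert not hit.accepted and "SITE" in hit.reasons


def test_acceptance_monotone_under_pair_degradation(mir397):
    """M -> W adds exactly 0.5, M -> X exactly 1.0; neither can rescue a hit."""
    rng = np.random.default_rng(1)
    L = len(mir397)
    for _ in range(200):
        window = "".join(rng.choice(list("ACGT"), L))
        base = mt.apply_rules(mt.score_window(mir397, window))
        i = int(rng.integers(L))
        for cls, dp in (("W", 0.5), ("X", 1.0)):
            if base.pair_classes[i] != "M":
                continue
            classes = base.pair_classes[: i] + cls + base.pair_classes[i + 1 :]
            worse = mt.apply_rules(_hit_from_classes(classes))
            assert worse.penalty == pytest.approx(base.penalty + dp)
            if base.accepted is False:
                assert set(base.reasons) - {"PENALTY"} <= set(worse.reasons) | {"PENALTY"}
            if not base.accepted and "PENALTY" not in base.reasons:
                assert not worse.accepted


# --- transcriptome scan ------------------------------------------------------

def test_empty_transcript_list_gives_empty_result(mir397):
    assert mt.scan_transcriptome(mir397, []) == []


def test_short_transcript_skipped_with_warning(mir397):
    with pytest.warns(UserWarning, match="skipped"):
        hits = mt.scan_transcriptome(mir397, [SeqRecord("t", "ACGT")])
    assert hits == []


def test_scan_equals_naive_oracle_on_random_transcripts(mir397):
    rng = np.random.default_rng(2)
    txs = [
        SeqRecord(f"t{i}", "".join(rng.choice(list("ACGT"), 120)))
        for i in range(50)
    ]
    hits = mt.scan_transcriptome(mir397, txs)
    found = {(h.transcript_id, h.start, h.penalty) for h in hits}
    expected = set()
    L = len(mir397)
    for tx in txs:
        for s in range(len(tx.seq) - L + 1):
            classes, penalty = _oracle_score(mir397.seq, tx.seq[s : s + L])
            if _oracle_rules_ok(classes, penalty):
                expected.add((tx.id, s + 1, penalty))
    assert found == expected


def test_planting_contract_exact_recovery(mir397):
    ok = ["M" * 21, "M" * 3 + "W" + "M" * 17]  # positions 4 = U can wobble
    bad = ["M" * 9 + "X" + "M" * 11]  # X at position 10
    txs, man = make_targets(mir397, ok + bad, n_decoys=5, seed=0)
    hits = mt.scan_transcriptome(mir397, txs)
    found = {(h.transcript_id, h.start) for h in hits}
    planted_ok = {
        (p["transcript_id"], p["window_start"])
        for p in man["planted_targets"]
        if p["rule_satisfying"]
    }
    assert found == planted_ok


def test_no_hit_on_reverse_complement_strand(mir397):
    """Targets live on the sense transcript; the antisense strand is silent."""
    txs, _ = make_targets(mir397, ["M" * 21], n_decoys=0, seed=3)
    rc = [SeqRecord(t.id + "_rc", reverse_complement(t.seq)) for t in txs]
    assert mt.scan_transcriptome(mir397, txs)
    assert mt.scan_transcriptome(mir397, rc) == []


def test_penalty_bounds_and_sorting(mir397):
    txs, _ = make_targets(mir397, ["M" * 21, "M" * 13 + "X" + "M" * 7], seed=4)
    hits = mt.scan_transcriptome(mir397, txs)
    assert all(0 <= h.penalty <= len(mir397) for h in hits)
    assert hits == sorted(hits, key=lambda h: (h.transcript_id, h.penalty, h.start))
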