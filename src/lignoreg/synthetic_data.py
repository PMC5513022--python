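"""Seeded generators for every input the pipeline consumes, with ground truth.

Each generator emulates one data stream of the study design — scaffolds with
ATG-anchored promoters carrying planted MYB motifs, transcripts embedding
miRNA target duplexes of controlled per-position pair structure, Fluidigm-
style Cq matrices with planted fold-changes over stable reference genes,
RACE clone sets concentrated at a planted cleavage position, and log2
expression profiles with planted cluster structure.  Background sequence is
i.i.d. uniform over ACGT, under which accidental motif or target matches are
rare and computable; every generator scan-verifies its plantings and records
them (plus any accidental hits) in a JSON-serializable truth manifest.
Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .io_formats import GeneModel, SeqRecord, reverse_complement
from .mirna_target import Mirna, apply_rules, scan_transcriptome, score_window
from .promoter_motif import DEFAULT_MOTIFS, MotifDef, scan_motifs

__all__ = [
    "make_genome",
    "make_targets",
    "make_cq_dataset",
    "make_race_reads",
    "make_profiles",
]

PROMOTER_LEN = 500
BASES = np.array(list("ACGT"))

# target base (DNA) forming a Watson-Crick pair with each miRNA base
_WC_TARGET = {"A": "T", "U": "A", "G": "C", "C": "G"}
# target base (DNA) forming a G:U wobble with each miRNA base (G and U only)
_WOBBLE_TARGET = {"G": "T", "U": "G"}


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


# --- genome with planted promoter motifs ------------------------------------

def make_genome(
    n_genes: int,
    promoter_motif_spec: dict[int, list[tuple]] | None = None,
    seed: int = 0,
    motifs: tuple[MotifDef, ...] = DEFAULT_MOTIFS,
    cds_len: int = 300,
    max_tries: int = 200,
) -> tuple[list[SeqRecord], list[GeneModel], dict]:
    """One scaffold per gene; promoters carry the requested motif plantings.

    ``promoter_motif_spec`` maps gene index (0-based) to a list of
    (motif_name, offset) or (motif_name, offset, strand) entries; the offset
    is the anchor-relative position of the planted match's 5' end and must
    lie in [−500, −len(motif)].  Genes alternate between strands.  Promoters
    are redrawn until every planted instance is recovered by scanning and no
    unintended match overlaps a planted one; accidental non-overlapping
    matches are kept and recorded in the manifest.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    promoter_motif_spec = promoter_motif_spec or {}
    motif_by_name = {m.name: m for m in motifs}
    rng = np.random.default_rng(seed)

    scaffolds: list[SeqRecord] = []
    genes: list[GeneModel] = []
    planted_manifest = []
    accidental_manifest = []

    for i in range(n_genes):
        gene_id = f"G{i + 1:03d}"
        strand = "+" if i % 2 == 0 else "-"
        plantings = []
        for entry in promoter_motif_spec.get(i, []):
            name, offset = entry[0], int(entry[1])
            mstrand = entry[2] if len(entry) > 2 else ("+", "-")[int(rng.integers(2))]
            motif = motif_by_name[name]
            mlen = len(motif.consensus)
            if not (-PROMOTER_LEN <= offset <= -mlen):
                raise ValueError(
                    f"gene {gene_id}: offset {offset} outside "
                    f"[-{PROMOTER_LEN}, -{mlen}] for motif {name}"
                )
            plantings.append((motif, offset, mstrand))

        for _ in range(max_tries):
            promoter = list(_random_dna(rng, PROMOTER_LEN))
            for motif, offset, mstrand in plantings:
                words = motif.words()
                word = words[int(rng.integers(len(words)))]
                if mstrand == "-":
                    word = reverse_complement(word)
                p0 = offset + PROMOTER_LEN  # 0-based local start
                promoter[p0 : p0 + len(word)] = word
            promoter_seq = "".join(promoter)
            hits = scan_motifs(SeqRecord(gene_id, promoter_seq), motifs, gene_id)
            planted_keys = {
                (m.name, s, off + PROMOTER_LEN + 1) for m, off, s in plantings
            }
            found_keys = {(h.motif, h.strand, h.pos) for h in hits}
            if not planted_keys <= found_keys:
                continue  # a planting was clobbered by another; redraw
            windows = [
                range(off + PROMOTER_LEN, off + PROMOTER_LEN + len(m.consensus))
                for m, off, s in plantings
            ]
            extra = [h for h in hits if (h.motif, h.strand, h.pos) not in planted_keys]
            overlap = any(
                set(range(h.pos - 1, h.pos + 7)) & set(w)
                for h in extra
                for w in windows
            )
            if not overlap:
                break
        else:
            raise RuntimeError(f"gene {gene_id}: could not realize motif plantings")

        cds = _random_dna(rng, cds_len)
        flank5, flank3 = _random_dna(rng, 50), _random_dna(rng, 50)
        if strand == "+":
            scaffold_seq = flank5 + promoter_seq + cds + flank3
            cds_start = len(flank5) + PROMOTER_LEN + 1
            cds_end = cds_start + cds_len - 1
        else:
            # promoter lies downstream of cds_end in genome coordinates
            scaffold_seq = flank5 + reverse_complement(cds) + reverse_complement(
                promoter_seq
            ) + flank3
            cds_start = len(flank5) + 1
            cds_end = cds_start + cds_len - 1
        scaffold_id = f"scaffold{i + 1}"
        scaffolds.append(SeqRecord(scaffold_id, scaffold_seq))
        genes.append(GeneModel(gene_id, scaffold_id, strand, cds_start, cds_end))
        for m, off, s in plantings:
            planted_manifest.append([gene_id, m.name, s, off])
        for h in extra:
            accidental_manifest.append([gene_id, h.motif, h.strand, h.pos_rel_anchor])

    manifest = {
        "seed": seed,
        "planted_motifs": planted_manifest,
        "accidental_motifs": accidental_manifest,
    }
    return scaffolds, genes, manifest


# --- transcripts with planted miRNA target sites -----------------------------

def _window_for_pattern(mirna: Mirna, pattern: str, rng: np.random.Generator) -> str:
    """Build the DNA target window realizing the per-position pair classes.

    pattern[i-1] is the class at miRNA position i; window position L−i+1
    (antiparallel) carries the chosen base.
    """
    L = len(mirna)
    if len(pattern) != L:
        raise ValueError(f"pattern length {len(pattern)} != miRNA length {L}")
    window = [""] * L
    for i in range(1, L + 1):
        b = mirna.seq[i - 1]
        cls = pattern[i - 1]
        if cls == "M":
            t = _WC_TARGET[b]
        elif cls == "W":
            if b not in _WOBBLE_TARGET:
                raise ValueError(
                    f"position {i}: miRNA base {b} admits no G:U wobble partner"
                )
            t = _WOBBLE_TARGET[b]
        elif cls == "X":
            forbidden = {_WC_TARGET[b], _WOBBLE_TARGET.get(b)}
            choices = [c for c in "ACGT" if c not in forbidden]
            t = choices[int(rng.integers(len(choices)))]
        else:
            raise ValueError(f"pattern class {cls!r} not in {{M,W,X}}")
        window[L - i] = t
    return "".join(window)


def _pattern_expectations(pattern: str) -> tuple[float, bool]:
    """(expected penalty, rule-satisfying?) for a pair-class pattern."""
    hit = score_window(
        Mirna("probe", "A" * len(pattern)), "T" * len(pattern)
    )  # geometry only; overwrite classes
    hit.pair_classes = pattern
    hit.penalty = 1.0 * pattern.count("X") + 0.5 * pattern.count("W")
    apply_rules(hit)
    return hit.penalty, hit.accepted


def make_targets(
    mirna: Mirna,
    site_specs: list[str],
    n_decoys: int = 0,
    seed: int = 0,
    flank_len: int = 150,
    decoy_len: int = 400,
    max_tries: int = 200,
) -> tuple[list[SeqRecord], dict]:
    """One transcript per pair-class spec plus clean decoys.

    Each spec is a string over {M, W, X} of the miRNA's length; the emitted
    transcript embeds exactly one window realizing that pattern (flanks are
    redrawn until the rule engine finds no other accepted window).  Decoys
    are verified to contain no window with penalty ≤ 2.5 at all.
    """
    rng = np.random.default_rng(seed)
    L = len(mirna)
    transcripts: list[SeqRecord] = []
    planted = []

    for s_idx, pattern in enumerate(site_specs):
        window = _window_for_pattern(mirna, pattern, rng)
        penalty, ok = _pattern_expectations(pattern)
        tx_id = f"T{s_idx + 1:03d}"
        for _ in range(max_tries):
            left = _random_dna(rng, flank_len)
            right = _random_dna(rng, flank_len)
            seq = left + window + right
            start1 = flank_len + 1
            rec = SeqRecord(tx_id, seq)
            accepted = scan_transcriptome(mirna, [rec])
            positions = {(h.start, h.pair_classes) for h in accepted}
            if ok and positions == {(start1, pattern)}:
                break
            if not ok and not accepted:
                break
        else:
            raise RuntimeError(f"transcript {tx_id}: could not realize spec {pattern}")
        transcripts.append(rec)
        planted.append(
            {
                "transcript_id": tx_id,
                "window_start": start1,
                "pair_classes": pattern,
                "expected_penalty": penalty,
                "expected_cleavage_pos": start1 + (L - 10),
                "rule_satisfying": ok,
            }
        )

    for d in range(n_decoys):
        tx_id = f"D{d + 1:03d}"
        for _ in range(max_tries):
            rec = SeqRecord(tx_id, _random_dna(rng, decoy_len))
            penalties = [
                score_window(mirna, rec.seq[i : i + L]).penalty
                for i in range(len(rec.seq) - L + 1)
            ]
            if min(penalties) > 2.5:
                break
        else:
            raise RuntimeError(f"decoy {tx_id}: could not draw a clean sequence")
        transcripts.append(rec)

    manifest = {"seed": seed, "mirna": mirna.seq, "planted_targets": planted}
    return transcripts, manifest


# --- Cq matrices with planted fold-changes -----------------------------------

def make_cq_dataset(
    design: dict,
    fold_changes: dict[tuple[str, str], float],
    efficiencies: dict[str, float],
    noise_sd: float = 0.1,
    seed: int = 0,
    dilutions: tuple[float, ...] = (1.0, 0.1, 0.01, 1e-3, 1e-4),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Cq table + dilution series with planted condition fold-changes.

    ``design`` needs keys: conditions (list, first one is the control unless
    'control' given), assays, reference_assays, and optionally n_bio / n_tech
    (default 3 × 3, i.e. n = 9 values per condition).  ``fold_changes`` maps
    (assay, condition) to the true expression ratio vs the control; reference
    assays (and any omitted pair) have fold 1.  Cq = baseline −
    log_E(quantity) + Normal(0, noise_sd); the dilution series is noise-free
    and encodes the same per-assay efficiency.
    """
    conditions = list(design["conditions"])
    control = design.get("control", conditions[0])
    assays = list(design["assays"])
    refs = set(design.get("reference_assays", []))
    n_bio = int(design.get("n_bio", 3))
    n_tech = int(design.get("n_tech", 3))
    for a, e in efficiencies.items():
        if not (1.0 < e <= 2.2):
            raise ValueError(f"assay {a}: efficiency {e} outside (1, 2.2]")

    rng = np.random.default_rng(seed)
    baselines = {a: float(rng.uniform(18, 24)) for a in assays}

    rows = []
    for assay in assays:
        e = efficiencies[assay]
        for cond in conditions:
            fold = 1.0 if assay in refs or cond == control else float(
                fold_changes.get((assay, cond), 1.0)
            )
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    cqv = (
                        baselines[assay]
                        - math.log(fold, e)
                        + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    )
                    rows.append(
                        {
                            "assay": assay,
                            "sample": f"{cond}_b{b}",
                            "condition": cond,
                            "replicate": t,
                            "cq": cqv,
                        }
                    )
    cq_df = pd.DataFrame(rows)

    dil_rows = [
        {
            "assay": assay,
            "dilution": dil,
            "cq": baselines[assay] - math.log(dil, efficiencies[assay]),
        }
        for assay in assays
        for dil in dilutions
    ]
    dil_df = pd.DataFrame(dil_rows)

    manifest = {
        "seed": seed,
        "control": control,
        "noise_sd": noise_sd,
        "reference_assays": sorted(refs),
        "efficiencies": dict(efficiencies),
        "planted_fold_changes": {
            f"{a}|{c}": (1.0 if a in refs or c == control
                         else float(fold_changes.get((a, c), 1.0)))
            for a in assays
            for c in conditions
        },
    }
    return cq_df, dil_df, manifest


# --- RACE clone sets ----------------------------------------------------------

def make_race_reads(
    transcript: SeqRecord,
    cleavage_pos: int,
    n_at_site: int,
    n_background: int,
    read_len: int = 40,
    seed: int = 0,
) -> tuple[list[SeqRecord], dict]:
    """RACE fragments: ``n_at_site`` exact clones starting at the cleavage
    position (1-based) plus background clones starting uniformly elsewhere."""
    if cleavage_pos + read_len - 1 > len(transcript):
        raise ValueError(
            f"read of {read_len} nt at position {cleavage_pos} overruns "
            f"transcript {transcript.id} ({len(transcript)} nt)"
        )
    rng = np.random.default_rng(seed)
    reads: list[SeqRecord] = []
    for i in range(n_at_site):
        frag = transcript.seq[cleavage_pos - 1 : cleavage_pos - 1 + read_len]
        reads.append(SeqRecord(f"{transcript.id}_race{i + 1:03d}", frag))
    valid_starts = [
        p for p in range(1, len(transcript) - read_len + 2) if p != cleavage_pos
    ]
    for i in range(n_background):
        p = valid_starts[int(rng.integers(len(valid_starts)))]
        frag = transcript.seq[p - 1 : p - 1 + read_len]
        reads.append(
            SeqRecord(f"{transcript.id}_race{n_at_site + i + 1:03d}", frag)
        )
    manifest = {
        "seed": seed,
        "planted_race": {
            "transcript_id": transcript.id,
            "cleavage_pos": cleavage_pos,
            "n_at_site": n_at_site,
            "n_background": n_background,
            "read_len": read_len,
        },
    }
    return reads, manifest


# --- expression profiles with planted clusters -------------------------------

def make_profiles(
    k: int,
    genes_per_cluster: int = 7,
    separation: float = 3.0,
    noise_sd: float = 0.3,
    n_conditions: int = 12,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """log2 expression profiles with k planted co-expression clusters.

    Cluster archetypes are mutually orthogonal after centering (pairwise
    Pearson correlation 0), scaled by ``separation``; member profiles add
    i.i.d. Gaussian noise.  At separation 0 the labels are unidentifiable
    but are still recorded in the manifest.  Requires
    ``n_conditions − 1 ≥ k`` so that k orthogonal centered archetypes exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    if n_conditions - 1 < k:
        raise ValueError("need n_conditions - 1 >= k for orthogonal archetypes")
    rng = np.random.default_rng(seed)

    raw = rng.normal(size=(k, n_conditions))
    arch = []
    for v in raw:
        v = v - v.mean()
        for u in arch:
            v = v - (v @ u) * u
        v = v - v.mean()
        v = v / np.linalg.norm(v)
        arch.append(v)
    arch = np.stack(arch) * math.sqrt(n_conditions)  # unit variance per profile

    rows, labels = [], {}
    for c in range(1, k + 1):
        for g in range(1, genes_per_cluster + 1):
            gid = f"P_c{c}_g{g}"
            rows.append(separation * arch[c - 1] + rng.normal(0, noise_sd, n_conditions))
            labels[gid] = c
    df = pd.DataFrame(
        np.stack(rows),
        index=list(labels),
        columns=[f"cond{j + 1}" for j in range(n_conditions)],
    )
    manifest = {"seed": seed, "planted_clusters": labels}
    return df, manifest
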