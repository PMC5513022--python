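"""Readers and writers for the plain-text formats every pipeline stage touches.

Coordinate conventions
----------------------
Everything read from or written to FASTA/GFF3/BED-like files uses the
convention native to that format: GFF3 is 1-based inclusive, BED-like output
is 0-based half-open.  Internal window arithmetic elsewhere in the package is
0-based half-open; :func:`to_zero_based` / :func:`to_one_based` convert
between the two and are exact inverses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SeqRecord",
    "GeneModel",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_cq_table",
    "write_cq_table",
    "write_bed_hits",
    "read_manifest",
    "write_manifest",
    "to_zero_based",
    "to_one_based",
    "reverse_complement",
]

DNA_ALPHABET = set("ACGTN")
RNA_ALPHABET = set("ACGUN")


class FormatError(ValueError):
    """A structural problem in an input file (bad row, duplicate id, ...)."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence, uppercase, DNA or RNA."""

    id: str
    seq: str
    alphabet: str = "DNA"  # "DNA" | "RNA"

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        self.seq = self.seq.upper()
        allowed = RNA_ALPHABET if self.alphabet == "RNA" else DNA_ALPHABET
        bad = set(self.seq) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r}: characters {sorted(bad)} outside "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A gene's CDS span on a scaffold; promoters are anchored at cds_start
    (+ strand) or cds_end (− strand), i.e. at the annotated translation start."""

    gene_id: str
    seq_id: str
    strand: str
    cds_start: int  # 1-based inclusive
    cds_end: int  # 1-based inclusive
    family: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if not (1 <= self.cds_start <= self.cds_end):
            raise FormatError(
                f"gene {self.gene_id}: bad CDS span {self.cds_start}..{self.cds_end}"
            )


# --- coordinate conversions -------------------------------------------------

def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive [start1, end1] -> 0-based half-open [start0, end0)."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open [start0, end0) -> 1-based inclusive [start1, end1]."""
    return start0 + 1, end0


_COMPL = str.maketrans("ACGTUN", "TGCAAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (U treated as T)."""
    return str(Seq(seq.upper().replace("U", "T")).reverse_complement())


# --- FASTA ------------------------------------------------------------------

def _infer_alphabet(seq: str) -> str:
    return "RNA" if "U" in seq and "T" not in seq else "DNA"


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SeqRecord]:
    """Read a multi-record FASTA file.

    Sequences are uppercased; U is kept for RNA records and T for DNA
    (alphabet inferred per record unless given).  Duplicate ids raise
    :class:`FormatError`; an empty file yields an empty list.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        records.append(
            SeqRecord(rec.id, seq, alphabet or _infer_alphabet(seq))
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# --- GFF3 -------------------------------------------------------------------

def _parse_attrs(attr_field: str) -> dict[str, str]:
    out = {}
    for item in attr_field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3: per gene, the CDS span is the min start /
    max end over its CDS children.  1-based inclusive coordinates preserved.

    A CDS whose Parent is not a declared gene, or a strandless gene, is a
    :class:`FormatError` (promoter extraction needs strand).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", force=True
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        if g.strand not in ("+", "-"):
            raise FormatError(f"gene {g.id}: strand {g.strand!r} not usable")
        fam = g.attributes.get("family", [None])[0]
        genes[g.id] = GeneModel(g.id, g.seqid, g.strand, g.start, g.end, fam)

    cds_seen: dict[str, list[tuple[int, int]]] = {}
    for c in db.features_of_type("CDS"):
        parents = c.attributes.get("Parent", [])
        parent = next((p for p in parents if p in genes), None)
        if parent is None:
            raise FormatError(f"CDS at {c.seqid}:{c.start} has no parent gene")
        cds_seen.setdefault(parent, []).append((c.start, c.end))

    out = []
    for gid, gm in genes.items():
        if gid in cds_seen:
            spans = cds_seen[gid]
            gm.cds_start = min(s for s, _ in spans)
            gm.cds_end = max(e for _, e in spans)
        out.append(gm)
    return out


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write one gene + one CDS feature per model (the dialect read_gff3 consumes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fam = f";family={g.family}" if g.family else ""
            fh.write(
                f"{g.seq_id}\tlignoreg\tgene\t{g.cds_start}\t{g.cds_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}{fam}\n"
            )
            fh.write(
                f"{g.seq_id}\tlignoreg\tCDS\t{g.cds_start}\t{g.cds_end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}.cds;Parent={g.gene_id}\n"
            )


# --- Cq tables --------------------------------------------------------------

CQ_COLUMNS = ["assay", "sample", "condition", "replicate", "cq"]


def read_cq_table(path: str | Path) -> pd.DataFrame:
    """Read a Cq TSV (assay, sample, condition, replicate, cq).

    "ND" (not detected) is parsed as missing — never zero.  Any other
    non-numeric cq raises :class:`FormatError` with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    cq = []
    for i, raw in enumerate(df["cq"]):
        s = str(raw).strip()
        if s.upper() == "ND":
            cq.append(float("nan"))
        else:
            try:
                cq.append(float(s))
            except ValueError:
                # +2: header line plus 1-based numbering
                raise FormatError(f"{path}: non-numeric cq {s!r} at line {i + 2}")
    out = df.copy()
    out["cq"] = cq
    out["replicate"] = out["replicate"].astype(int)
    return out


def write_cq_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["cq"] = [
        "ND" if pd.isna(v) else format(float(v), ".6f") for v in out["cq"]
    ]
    out.to_csv(path, sep="\t", index=False)


# --- BED-like hit output and JSON manifests ---------------------------------

def write_bed_hits(hits: Iterable[tuple], path: str | Path) -> None:
    """Write 6-column BED-like rows: (seq_id, start0, end0, name, score, strand)."""
    with open(path, "w") as fh:
        for seq_id, start0, end0, name, score, strand in hits:
            fh.write(f"{seq_id}\t{start0}\t{end0}\t{name}\t{score}\t{strand}\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
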