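"""Domain types, coordinate conventions and on-disk formats.

Internal coordinates are 0-based half-open everywhere.  GTF-lite input
(1-based closed, as in GTF) is converted at the boundary; BED is used
natively.  Sequences are held in the DNA alphabet; RNA input (U) is
normalised to T with the original alphabet recorded.

``end_pos`` on a read is the 0-based genomic coordinate of the last
templated nucleotide (the half-open end minus one): a single-nt anchor
that simplifies 3'-end clustering.
"""

from __future__ import annotations

import csv
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

QC_TAGS = ("PASS", "SUFFCLIP", "FAIL")
CONDITIONS = ("control", "stimulated")

TAIL_TABLE_COLUMNS = (
    "read_id",
    "transcript_id",
    "sample_id",
    "condition",
    "tail_length",
    "tail_seq",
    "end_pos",
    "qc_tag",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSeqs(Mapping):
    """Named nucleotide sequences (uppercase DNA, alphabet ACGTN).

    ``had_uracil`` records whether the source used the RNA alphabet.
    """

    def __init__(self, sequences: dict[str, str], had_uracil: bool = False):
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for record {name!r}")
        self._sequences = dict(sequences)
        self.had_uracil = had_uracil

    def __getitem__(self, name: str) -> str:
        return self._sequences[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sequences)

    def __len__(self) -> int:
        return len(self._sequences)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenomeSeqs({len(self)} sequences)"


@dataclass
class TranscriptModel:
    """A transcript: sorted non-overlapping exons plus an optional 3'UTR.

    All intervals are 0-based half-open genomic intervals.  The 3'UTR, when
    present, must be covered by the exons.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    utr3: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id}: no exons")
        exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in exons:
            if s >= e:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty exon [{s},{e})"
                )
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        self.exons = exons
        if self.utr3 is not None:
            u = (int(self.utr3[0]), int(self.utr3[1]))
            if u[0] >= u[1]:
                raise ValueError(
                    f"transcript {self.transcript_id}: empty 3'UTR interval"
                )
            if not self._covered(u):
                raise ValueError(
                    f"transcript {self.transcript_id}: 3'UTR {u} not inside exons"
                )
            self.utr3 = u

    def _covered(self, interval: tuple[int, int]) -> bool:
        pos = interval[0]
        for s, e in self.exons:
            if pos < s:
                return False
            if pos < e:
                pos = e
            if pos >= interval[1]:
                return True
        return pos >= interval[1]

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass
class ReadRecord:
    """One sequenced molecule: transcript assignment, condition, tail."""

    read_id: str
    transcript_id: str
    sample_id: str
    condition: str
    tail_length: int
    tail_seq: str
    end_pos: int
    qc_tag: str = "PASS"
    was_rna: bool = False

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"read {self.read_id}: condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.qc_tag not in QC_TAGS:
            raise ValueError(
                f"read {self.read_id}: qc_tag {self.qc_tag!r} not in {QC_TAGS}"
            )
        if self.tail_length < 0:
            raise ValueError(f"read {self.read_id}: negative tail_length")
        if "U" in self.tail_seq or "u" in self.tail_seq:
            self.was_rna = True
        self.tail_seq = self.tail_seq.upper().replace("U", "T")
        if self.tail_seq and set(self.tail_seq) - set("ACGTN"):
            raise ValueError(f"read {self.read_id}: tail_seq has non-ACGU letters")
        if self.tail_seq and len(self.tail_seq) != self.tail_length:
            raise ValueError(
                f"read {self.read_id}: tail_length {self.tail_length} != "
                f"len(tail_seq) {len(self.tail_seq)}"
            )


@dataclass
class BedRecord:
    """A BED6 interval (0-based half-open, native convention)."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"BED record {self.name!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"BED record {self.name!r}: strand required")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> GenomeSeqs:
    """Read a FASTA file; uppercase, map U->T, reject duplicates/empties."""
    sequences: dict[str, str] = {}
    had_uracil = False
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        if "U" in seq:
            had_uracil = True
            seq = seq.replace("U", "T")
        if set(seq) - set("ACGTN"):
            raise ValueError(f"FASTA record {rec.id!r}: non-ACGTUN letters")
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeSeqs(sequences, had_uracil=had_uracil)


def write_fasta(genome: GenomeSeqs, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF-lite annotation

_GTF_FEATURES = ("gene", "transcript", "exon", "three_prime_utr")


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            key, value = part.split(None, 1)
        except ValueError:
            continue
        attrs[key] = value.strip().strip('"')
    return attrs


def read_annotation(path) -> list[TranscriptModel]:
    """Read GTF-lite (gene/transcript/exon/three_prime_utr features).

    1-based closed intervals are converted to 0-based half-open.  Exons
    outside a declared transcript span raise an error naming the transcript.
    """
    spans: dict[str, tuple[int, int]] = {}
    meta: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    utr3s: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _, feature, start, end, _, strand, _, attr_text = fields[:9]
            if feature not in _GTF_FEATURES:
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            iv = (int(start) - 1, int(end))  # 1-based closed -> 0-based half-open
            attrs = _parse_attributes(attr_text)
            if feature == "gene":
                continue
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: missing transcript_id")
            if tid not in meta:
                meta[tid] = {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                }
                order.append(tid)
            if feature == "transcript":
                if tid in spans:
                    raise ValueError(f"duplicate transcript {tid!r}")
                spans[tid] = iv
            elif feature == "exon":
                exons.setdefault(tid, []).append(iv)
            elif feature == "three_prime_utr":
                utr3s.setdefault(tid, []).append(iv)
    models = []
    for tid in order:
        m = meta[tid]
        ex = sorted(exons.get(tid, []))
        if tid in spans:
            lo, hi = spans[tid]
            for s, e in ex:
                if s < lo or e > hi:
                    raise ValueError(
                        f"transcript {tid}: exon [{s},{e}) outside declared span"
                    )
        utr3: Optional[tuple[int, int]] = None
        if tid in utr3s:
            parts = sorted(utr3s[tid])
            utr3 = (parts[0][0], parts[-1][1])
        models.append(
            TranscriptModel(
                gene_id=m["gene_id"],
                transcript_id=tid,
                chrom=m["chrom"],
                strand=m["strand"],
                exons=ex,
                utr3=utr3,
            )
        )
    return models


def write_annotation(models: Sequence[TranscriptModel], path) -> None:
    """Write GTF-lite (0-based half-open converted back to 1-based closed)."""
    with open(path, "w") as fh:
        for m in models:
            lo, hi = m.span
            common = f"{m.chrom}\ttailscape"
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            fh.write(f"{common}\ttranscript\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t{attrs}\n")
            for s, e in m.exons:
                fh.write(f"{common}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n")
            if m.utr3 is not None:
                s, e = m.utr3
                fh.write(
                    f"{common}\tthree_prime_utr\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Per-read tail table (TSV)


def read_tail_table(path) -> list[ReadRecord]:
    """Read a per-read TSV.  FAIL-tagged reads are parsed and retained;
    downstream stages filter on qc_tag."""
    records: list[ReadRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(TAIL_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            records.append(
                ReadRecord(
                    read_id=row["read_id"],
                    transcript_id=row["transcript_id"],
                    sample_id=row["sample_id"],
                    condition=row["condition"],
                    tail_length=int(row["tail_length"]),
                    tail_seq=row["tail_seq"],
                    end_pos=int(row["end_pos"]),
                    qc_tag=row["qc_tag"],
                )
            )
    return records


def write_tail_table(records: Sequence[ReadRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TAIL_TABLE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.read_id,
                    r.transcript_id,
                    r.sample_id,
                    r.condition,
                    r.tail_length,
                    r.tail_seq,
                    r.end_pos,
                    r.qc_tag,
                ]
            )


# ---------------------------------------------------------------------------
# BED6


def read_bed(path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, name, score, strand = fields[:6]
            records.append(
                BedRecord(chrom, int(start), int(end), name, int(score), strand)
            )
    return records


def write_bed(records: Sequence[BedRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n"
            )


# ---------------------------------------------------------------------------
# Terminal-window extraction


def terminal_window(model: TranscriptModel, genome: GenomeSeqs, window: int) -> str:
    """mRNA-sense sequence of the last ``window`` nt of the 3'UTR.

    The nucleotides adjacent to the poly(A) tail sit at the right end of the
    returned string; minus-strand UTRs are reverse-complemented.  If the UTR
    is shorter than ``window`` the whole UTR is returned.
    """
    if model.utr3 is None:
        raise ValueError(
            f"transcript {model.transcript_id}: no annotated 3'UTR"
        )
    if window < 1:
        raise ValueError("window must be >= 1")
    s, e = model.utr3
    seq = genome[model.chrom]
    if model.strand == "+":
        lo = max(s, e - window)
        return seq[lo:e]
    hi = min(e, s + window)
    return revcomp(seq[s:hi])
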