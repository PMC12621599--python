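"""FIMO-like PWM scanning of 3'UTRs with exact p-values.

Letter-probability matrices (MEME minimal text) are converted to log-odds
scores against a 0-order background, the scores are rounded to integers on
a fixed scale, and the null score distribution is computed exactly by
positional convolution under the background model — so every reported
p-value is P(score >= observed) under that null, not an approximation.
Scanning is sense-strand only: cytoplasmic polyadenylation elements are
mRNA elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd


from .io import GenomeSeqs, TranscriptModel, revcomp

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_SCALE = 1000
DEFAULT_THRESHOLD = 1e-4


@dataclass
class LetterProbMatrix:
    """Position-dependent letter probabilities, rows = positions (ACGT)."""

    motif_id: str
    probs: np.ndarray  # shape (W, 4)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id}: matrix must be W x 4, W >= 1")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6) or (self.probs < 0).any():
            raise ValueError(
                f"motif {self.motif_id}: each position must sum to 1 within 1e-6"
            )

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))


@dataclass
class LogOddsMatrix:
    """log2((p + c*q_b) / (1 + c) / q_b) scores derived from an LPM."""

    motif_id: str
    scores: np.ndarray  # shape (W, 4)

    @property
    def width(self) -> int:
        return self.scores.shape[0]


@dataclass
class MotifHit:
    motif_id: str
    sequence_id: str
    start: int  # 0-based
    matched: str
    score: float
    p_value: float


def read_meme_motifs(path) -> list[LetterProbMatrix]:
    """Read MEME minimal motif text into validated matrices.

    Probabilities are kept at full printed precision (count-based parsers
    quantise them through nsites, which would break round-tripping).
    """
    out: list[LetterProbMatrix] = []
    with open(path) as fh:
        lines = [line.strip() for line in fh]
    if not any(line.startswith("MEME version") for line in lines):
        raise ValueError(f"{path}: missing 'MEME version' header")
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: MOTIF line without an identifier")
            motif_id = parts[1]
            j = i + 1
            while j < len(lines) and not lines[j].startswith(
                "letter-probability matrix"
            ):
                if lines[j].startswith("MOTIF"):
                    raise ValueError(
                        f"{path}: motif {motif_id} lacks a probability matrix"
                    )
                j += 1
            if j == len(lines):
                raise ValueError(
                    f"{path}: motif {motif_id} lacks a probability matrix"
                )
            header = lines[j]
            width = None
            tokens = header.replace("=", " = ").split()
            for k, tok in enumerate(tokens):
                if tok == "w" and k + 2 < len(tokens):
                    width = int(tokens[k + 2])
            if width is None:
                raise ValueError(f"{path}: motif {motif_id}: no width in header")
            rows = []
            for k in range(width):
                values = lines[j + 1 + k].split()
                if len(values) != 4:
                    raise ValueError(
                        f"{path}: motif {motif_id}: expected 4 columns per row"
                    )
                rows.append([float(v) for v in values])
            out.append(LetterProbMatrix(motif_id=motif_id, probs=np.array(rows)))
            i = j + width + 1
        else:
            i += 1
    if not out:
        raise ValueError(f"{path}: no motifs found")
    return out


def write_meme_motifs(
    matrices: Sequence[LetterProbMatrix],
    path,
    background: Optional[Sequence[float]] = None,
) -> None:
    bg = np.asarray(background if background is not None else [0.25] * 4)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(ALPHABET)) + "\n\n"
        )
        for m in matrices:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 100 E= 0\n"
            )
            for row in m.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def build_log_odds(
    lpm: LetterProbMatrix,
    background: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> LogOddsMatrix:
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    if (bg <= 0).any():
        raise ValueError("zero background frequency; smooth the background model")
    scores = np.log2((lpm.probs + pseudocount * bg) / (1.0 + pseudocount) / bg)
    return LogOddsMatrix(motif_id=lpm.motif_id, scores=scores)


class ScoreDistribution:
    """Exact null distribution of integer-scaled PWM scores.

    Scores are rounded to integers at ``scale`` units per log2; the null
    pmf over total scores is the positional convolution of the per-position
    atom distributions under the background model.
    """

    def __init__(
        self,
        lom: LogOddsMatrix,
        background: Sequence[float],
        scale: int = DEFAULT_SCALE,
    ):
        bg = np.asarray(background, dtype=float)
        self.scale = scale
        self.int_scores = np.rint(lom.scores * scale).astype(np.int64)
        cur = np.array([1.0])
        cur_lo = 0
        for i in range(self.int_scores.shape[0]):
            row = self.int_scores[i]
            rmin, rmax = int(row.min()), int(row.max())
            step = np.zeros(rmax - rmin + 1)
            for b in range(4):
                step[row[b] - rmin] += bg[b]
            cur = np.convolve(cur, step)
            cur_lo += rmin
        self.min_score = cur_lo
        self.pmf = cur
        total = cur.sum()
        if abs(total - 1.0) > 1e-9:
            raise AssertionError("null pmf does not sum to 1")
        # survival: P(score >= t)
        self._sf = np.cumsum(cur[::-1])[::-1]

    def pvalue(self, int_score: int) -> float:
        idx = int_score - self.min_score
        if idx < 0:
            return 1.0
        if idx >= len(self._sf):
            return 0.0
        return float(min(self._sf[idx], 1.0))


def estimate_background(sequences: Iterable[str]) -> np.ndarray:
    """0-order background from the scanned sequences, Laplace-smoothed."""
    counts = np.ones(4)
    for seq in sequences:
        for b, i in _CODE.items():
            counts[i] += seq.count(b)
    return counts / counts.sum()


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.upper().encode().translate(bytes.maketrans(b"ACGT", bytes([0, 1, 2, 3]))),
        dtype=np.uint8,
    )


def scan(
    sequences: Union[Mapping[str, str], Sequence[tuple[str, str]]],
    lom: LogOddsMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    background: Optional[Sequence[float]] = None,
    scale: int = DEFAULT_SCALE,
) -> list[MotifHit]:
    """All positions with exact p-value <= threshold, sense strand only."""
    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = list(sequences)
    if background is None:
        background = estimate_background(seq for _, seq in items)
    dist = ScoreDistribution(lom, background, scale=scale)
    W = lom.width
    hits: list[MotifHit] = []
    for seq_id, seq in items:
        if len(seq) < W:
            continue
        codes = _encode(seq)
        valid = codes < 4
        n_win = len(seq) - W + 1
        totals = np.zeros(n_win, dtype=np.int64)
        ok = np.ones(n_win, dtype=bool)
        for i in range(W):
            sl = codes[i : i + n_win]
            ok &= valid[i : i + n_win]
            totals += dist.int_scores[i][np.minimum(sl, 3)]
        for pos in np.nonzero(ok)[0]:
            p = dist.pvalue(int(totals[pos]))
            if p <= threshold:
                hits.append(
                    MotifHit(
                        motif_id=lom.motif_id,
                        sequence_id=seq_id,
                        start=int(pos),
                        matched=seq[pos : pos + W],
                        score=float(totals[pos] / scale),
                        p_value=p,
                    )
                )
    return hits


def utr3_sequences(
    models: Sequence[TranscriptModel], genome: GenomeSeqs
) -> dict[str, str]:
    """mRNA-sense 3'UTR sequence per transcript (skips UTR-less models)."""
    out = {}
    for m in models:
        if m.utr3 is None:
            continue
        s, e = m.utr3
        seq = genome[m.chrom][s:e]
        out[m.transcript_id] = seq if m.strand == "+" else revcomp(seq)
    return out


def annotate_cpe(
    models: Sequence[TranscriptModel],
    genome: GenomeSeqs,
    matrices: Sequence[LetterProbMatrix],
    threshold: float = DEFAULT_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-transcript CPE flags from scanning the full 3'UTR sense sequence.

    Transcripts without an annotated 3'UTR get all flags False and
    ``utr3_present`` False.
    """
    utrs = utr3_sequences(models, genome)
    if background is None and utrs:
        background = estimate_background(utrs.values())
    flags: dict[str, dict[str, bool]] = {
        m.transcript_id: {f"has_{lpm.motif_id}": False for lpm in matrices}
        for m in models
    }
    for lpm in matrices:
        if not utrs:
            break
        lom = build_log_odds(lpm, background, pseudocount)
        for hit in scan(utrs, lom, threshold=threshold, background=background):
            flags[hit.sequence_id][f"has_{lpm.motif_id}"] = True
    frame = pd.DataFrame.from_dict(flags, orient="index").sort_index()
    frame.insert(0, "utr3_present", [tid in utrs for tid in frame.index])
    frame.index.name = "transcript_id"
    return frame


def example_cpe_motifs() -> list[LetterProbMatrix]:
    """Synthetic CPE-like matrices (U-rich consensus) for demonstration and
    testing only — not the published CPEB-binding matrices."""

    def sharp(motif_id: str, consensus: str, p: float = 0.85) -> LetterProbMatrix:
        probs = np.full((len(consensus), 4), (1 - p) / 3)
        for i, b in enumerate(consensus):
            probs[i, _CODE[b]] = p
        return LetterProbMatrix(motif_id=motif_id, probs=probs)

    return [sharp("CPE1", "TTTTTAT"), sharp("CPE2_4", "TTTTAAGT")]
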