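"""Semi-templated tail discovery from A/T-rich 3'UTR termini.

Candidate transcripts are those whose terminal window (the last 60 nt of
the annotated 3'UTR, and/or the 60 nt upstream of each called PAS anchor,
mRNA sense) satisfies either rule:

* rule 1 — A/T content strictly above 0.60, or
* rule 2 — a run of >= 13 consecutive A/T nucleotides anywhere in the
  window AND the window's last three nucleotides (those adjacent to the
  poly(A) tail) all A/T.

Merged candidates are then filtered by read support: at least 10
QC-passing reads and at least 3 tails containing a non-adenosine.  All
intermediate set sizes (per rule, per source, union, post-filter) are
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .apa import PasCluster
from .io import GenomeSeqs, ReadRecord, TranscriptModel, revcomp, terminal_window


@dataclass
class SemiTemplatedConfig:
    window: int = 60
    at_fraction_threshold: float = 0.60  # strict >
    run_length: int = 13  # inclusive >=
    terminal_run: int = 3
    min_reads: int = 10
    min_decorated: int = 3
    qc_allowed: tuple[str, ...] = ("PASS", "SUFFCLIP")

    def __post_init__(self) -> None:
        if not self.terminal_run <= self.run_length <= self.window:
            raise ValueError("need terminal_run <= run_length <= window")


@dataclass
class CandidateWindow:
    transcript_id: str
    source: str  # reference_utr | pas_predicted
    seq: str
    truncated: bool = False


@dataclass
class SemiTemplatedCall:
    transcript_id: str
    source: str  # reference_utr | pas_predicted | both
    at_fraction: float
    max_at_run: int
    terminal_ok: bool
    rule1: bool
    rule2: bool
    n_reads: int
    n_decorated: int
    called: bool


def at_fraction(seq: str) -> float:
    """(#A + #T) / length of a non-empty DNA string."""
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("A") + seq.count("T")) / len(seq)


def max_at_run(seq: str, terminal_run: int = 3) -> tuple[int, bool]:
    """Longest A/T run and whether the final ``terminal_run`` nt are A/T."""
    if not seq:
        raise ValueError("empty sequence")
    best = run = 0
    for ch in seq:
        if ch in "AT":
            run += 1
            best = max(best, run)
        else:
            run = 0
    terminal_ok = len(seq) >= terminal_run and all(
        ch in "AT" for ch in seq[-terminal_run:]
    )
    return best, terminal_ok


def candidate_windows(
    models: Sequence[TranscriptModel],
    genome: GenomeSeqs,
    pas_clusters: Sequence[PasCluster] = (),
    config: Optional[SemiTemplatedConfig] = None,
) -> dict[str, list[CandidateWindow]]:
    """Terminal windows per transcript: one per annotated 3'UTR end plus
    one per called PAS anchor (window ends at the anchor, mRNA sense)."""
    config = config or SemiTemplatedConfig()
    w = config.window
    out: dict[str, list[CandidateWindow]] = {}
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
        if m.utr3 is not None:
            out.setdefault(m.transcript_id, []).append(
                CandidateWindow(
                    transcript_id=m.transcript_id,
                    source="reference_utr",
                    seq=terminal_window(m, genome, w),
                    truncated=(m.utr3[1] - m.utr3[0]) < w,
                )
            )
    skipped = 0
    for c in pas_clusters:
        transcripts = by_gene.get(c.gene_id)
        if not transcripts:
            skipped += 1
            continue
        seq = genome[c.chrom]
        if c.strand == "+":
            lo = max(0, c.anchor + 1 - w)
            window = seq[lo : c.anchor + 1]
            truncated = c.anchor + 1 - w < 0
        else:
            hi = min(len(seq), c.anchor + w)
            window = revcomp(seq[c.anchor : hi])
            truncated = c.anchor + w > len(seq)
        if not window:
            skipped += 1
            continue
        for m in transcripts:
            out.setdefault(m.transcript_id, []).append(
                CandidateWindow(
                    transcript_id=m.transcript_id,
                    source="pas_predicted",
                    seq=window,
                    truncated=truncated,
                )
            )
    if skipped:
        warnings.warn(f"{skipped} PAS clusters without usable windows skipped")
    return out


@dataclass
class SemiTemplatedResults:
    calls: list[SemiTemplatedCall]
    counts: dict[str, int]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.calls])

    @property
    def called(self) -> list[SemiTemplatedCall]:
        return [c for c in self.calls if c.called]

    def summary(self) -> str:
        c = self.counts
        return "\n".join(
            [
                "Semi-templated tail discovery",
                f"rule 1 (A/T fraction): {c['rule1']}",
                f"rule 2 (terminal A/T run): {c['rule2']}",
                f"reference-derived candidates: {c['reference_utr']}",
                f"PAS-derived candidates: {c['pas_predicted']}",
                f"merged candidates: {c['union']}",
                f"called after read/decoration support filter: {c['called']}",
            ]
        )


def call_semitemplated(
    windows: dict[str, list[CandidateWindow]],
    reads: Iterable[ReadRecord],
    config: Optional[SemiTemplatedConfig] = None,
) -> SemiTemplatedResults:
    """Apply the window rules per candidate, then the support filter.

    Rules are evaluated per window and OR-ed per transcript; a candidate
    with windows but no reads is retained with ``called`` False.
    """
    config = config or SemiTemplatedConfig()
    support: dict[str, list[int]] = {}
    for r in reads:
        if r.qc_tag not in config.qc_allowed:
            continue
        s = support.setdefault(r.transcript_id, [0, 0])
        s[0] += 1
        if r.tail_seq and any(b != "A" for b in r.tail_seq):
            s[1] += 1

    calls: list[SemiTemplatedCall] = []
    counts = {
        "rule1": 0,
        "rule2": 0,
        "reference_utr": 0,
        "pas_predicted": 0,
        "union": 0,
        "called": 0,
    }
    for tid in sorted(windows):
        wins = windows[tid]
        rule1 = rule2 = False
        passing_sources: set[str] = set()
        best_frac = 0.0
        best_run = 0
        terminal_ok = False
        for w in wins:
            frac = at_fraction(w.seq)
            run, term = max_at_run(w.seq, config.terminal_run)
            best_frac = max(best_frac, frac)
            best_run = max(best_run, run)
            terminal_ok = terminal_ok or term
            w_rule1 = frac > config.at_fraction_threshold
            w_rule2 = run >= config.run_length and term
            rule1 = rule1 or w_rule1
            rule2 = rule2 or w_rule2
            if w_rule1 or w_rule2:
                passing_sources.add(w.source)
        if not (rule1 or rule2):
            continue
        n_reads, n_dec = support.get(tid, [0, 0])
        source = (
            "both" if len(passing_sources) > 1 else next(iter(passing_sources))
        )
        called = (
            n_reads >= config.min_reads and n_dec >= config.min_decorated
        )
        counts["rule1"] += rule1
        counts["rule2"] += rule2
        counts["union"] += 1
        for s in passing_sources:
            counts[s] += 1
        counts["called"] += called
        calls.append(
            SemiTemplatedCall(
                transcript_id=tid,
                source=source,
                at_fraction=best_frac,
                max_at_run=best_run,
                terminal_ok=terminal_ok,
                rule1=rule1,
                rule2=rule2,
                n_reads=n_reads,
                n_decorated=n_dec,
                called=called,
            )
        )
    return SemiTemplatedResults(calls=calls, counts=counts)
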