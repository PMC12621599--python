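"""Polyadenylation-site calling and differential usage from read 3' ends.

PAS clusters are formed per gene by single-linkage clustering of read end
positions (maximum gap ``cluster_gap``), anchored at the modal end.
Differential usage contrasts each PAS against the gene's other PASs in a
2x2 Fisher exact test, BH-adjusted across all tested PASs.  Proximal and
distal are defined in mRNA orientation (proximal = 5'-most, the stop-codon
side).  A positional histogram of canonical A[A/T]TAAA hexamers upstream
of anchors provides the signal-enrichment check.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import BedRecord, GenomeSeqs, ReadRecord, TranscriptModel, revcomp
from .tailstats import bh_adjust

CANONICAL_HEXAMERS = ("AATAAA", "ATTAAA")
# common single-substitution variants, selectable via ApaConfig
VARIANT_HEXAMERS = (
    "AGTAAA",
    "TATAAA",
    "CATAAA",
    "GATAAA",
    "AATATA",
    "AATACA",
    "AATAGA",
    "ACTAAA",
    "AAGAAA",
    "AATGAA",
)

FEATURES = ("three_prime_utr", "exon", "intron", "within_transcript", "unassigned")


@dataclass
class ApaConfig:
    cluster_gap: int = 24
    min_support: int = 3
    fisher_alpha: float = 0.05
    adj_threshold: float = 0.1
    hexamer_window: int = 40
    include_variant_hexamers: bool = False
    qc_allowed: tuple[str, ...] = ("PASS", "SUFFCLIP")

    def __post_init__(self) -> None:
        if self.cluster_gap < 0:
            raise ValueError("cluster_gap must be >= 0")
        if not 0 < self.adj_threshold < 1 or not 0 < self.fisher_alpha < 1:
            raise ValueError("thresholds must lie in (0, 1)")

    @property
    def hexamer_set(self) -> tuple[str, ...]:
        if self.include_variant_hexamers:
            return CANONICAL_HEXAMERS + VARIANT_HEXAMERS
        return CANONICAL_HEXAMERS


@dataclass
class PasCluster:
    pas_id: str
    gene_id: str
    chrom: str
    strand: str
    anchor: int
    span: tuple[int, int]
    support: dict[tuple[str, str], int]  # (sample_id, condition) -> reads
    feature: str = "unassigned"

    def total_support(self) -> int:
        return sum(self.support.values())

    def condition_support(self, condition: str) -> int:
        return sum(v for (s, c), v in self.support.items() if c == condition)

    def to_bed(self) -> BedRecord:
        return BedRecord(
            chrom=self.chrom,
            start=self.span[0],
            end=self.span[1],
            name=self.pas_id,
            score=self.total_support(),
            strand=self.strand,
        )


@dataclass
class PasUsageResult:
    pas_id: str
    gene_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_raw: float
    p_adj: float
    differential: bool
    rank: str  # proximal / distal / middle
    log2_shift: float


def cluster_read_ends(
    reads: Iterable[ReadRecord],
    models: Sequence[TranscriptModel],
    config: Optional[ApaConfig] = None,
) -> list[PasCluster]:
    """Single-linkage cluster read 3' ends per gene; drop weak clusters.

    The anchor is the modal end position; ties break toward the 3'-most
    end in mRNA orientation.  Input order never affects the result.
    """
    config = config or ApaConfig()
    gene_of = {m.transcript_id: (m.gene_id, m.chrom, m.strand) for m in models}
    ends: dict[str, list[tuple[int, str, str]]] = {}
    for r in reads:
        if r.qc_tag not in config.qc_allowed:
            continue
        if r.transcript_id not in gene_of:
            continue
        gene_id = gene_of[r.transcript_id][0]
        ends.setdefault(gene_id, []).append((r.end_pos, r.sample_id, r.condition))

    clusters: list[PasCluster] = []
    for gene_id in sorted(ends):
        _, chrom, strand = next(
            v for k, v in gene_of.items() if v[0] == gene_id
        )
        items = sorted(ends[gene_id])
        runs: list[list[tuple[int, str, str]]] = [[items[0]]]
        for item in items[1:]:
            if item[0] - runs[-1][-1][0] <= config.cluster_gap:
                runs[-1].append(item)
            else:
                runs.append([item])
        for run in runs:
            if len(run) < config.min_support:
                continue
            positions = [p for p, _, _ in run]
            counts = Counter(positions)
            top = max(counts.values())
            modal = [p for p, c in counts.items() if c == top]
            anchor = max(modal) if strand == "+" else min(modal)
            support: dict[tuple[str, str], int] = {}
            for _, sample, condition in run:
                key = (sample, condition)
                support[key] = support.get(key, 0) + 1
            clusters.append(
                PasCluster(
                    pas_id=f"{gene_id}:{anchor}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    anchor=anchor,
                    span=(positions[0], positions[-1] + 1),
                    support=support,
                )
            )
    return clusters


def assign_feature(cluster: PasCluster, models: Sequence[TranscriptModel]) -> str:
    """Genomic feature of the anchor, precedence 3'UTR > exon > intron >
    within_transcript > unassigned, over the cluster's gene's transcripts."""
    a = cluster.anchor
    in_exon_with_utr = False
    in_intron = False
    in_span_no_utr_exon = False
    for m in models:
        if m.gene_id != cluster.gene_id or m.chrom != cluster.chrom:
            continue
        if m.utr3 is not None and m.utr3[0] <= a < m.utr3[1]:
            return "three_prime_utr"
        lo, hi = m.span
        if not (lo <= a < hi):
            continue
        in_any_exon = any(s <= a < e for s, e in m.exons)
        if in_any_exon:
            if m.utr3 is not None:
                in_exon_with_utr = True
            else:
                in_span_no_utr_exon = True
        else:
            in_intron = True
    if in_exon_with_utr:
        return "exon"
    if in_intron:
        return "intron"
    if in_span_no_utr_exon:
        return "within_transcript"
    return "unassigned"


def annotate_features(
    clusters: Sequence[PasCluster], models: Sequence[TranscriptModel]
) -> None:
    for c in clusters:
        c.feature = assign_feature(c, models)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table; 1.0 on a zero margin."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(min(stats.fisher_exact(t).pvalue, 1.0))


def differential_pas_usage(
    clusters: Sequence[PasCluster], config: Optional[ApaConfig] = None
) -> list[PasUsageResult]:
    """Fisher test of each PAS against its gene's other PASs, BH across all."""
    config = config or ApaConfig()
    by_gene: dict[str, list[PasCluster]] = {}
    for c in clusters:
        by_gene.setdefault(c.gene_id, []).append(c)

    results: list[PasUsageResult] = []
    raw_p: list[float] = []
    for gene_id in sorted(by_gene):
        gene_clusters = by_gene[gene_id]
        if len(gene_clusters) < 2:
            continue
        strand = gene_clusters[0].strand
        ordered = sorted(
            gene_clusters, key=lambda c: c.anchor, reverse=(strand == "-")
        )  # mRNA orientation: first is 5'-most (proximal)
        totals = {
            cond: sum(c.condition_support(cond) for c in gene_clusters)
            for cond in ("control", "stimulated")
        }
        lib = {
            cond: max(totals[cond], 1) for cond in totals
        }
        for i, c in enumerate(ordered):
            pas_c = c.condition_support("control")
            pas_s = c.condition_support("stimulated")
            table = (
                (pas_c, totals["control"] - pas_c),
                (pas_s, totals["stimulated"] - pas_s),
            )
            p = fisher_exact(table)
            rank = (
                "proximal" if i == 0 else "distal" if i == len(ordered) - 1 else "middle"
            )
            shift = math.log2(
                (pas_s / lib["stimulated"] + 0.5) / (pas_c / lib["control"] + 0.5)
            )
            results.append(
                PasUsageResult(
                    pas_id=c.pas_id,
                    gene_id=gene_id,
                    table=table,
                    p_raw=p,
                    p_adj=p,
                    differential=False,
                    rank=rank,
                    log2_shift=shift,
                )
            )
            raw_p.append(p)
    skipped = sum(1 for g in by_gene.values() if len(g) < 2)
    if skipped:
        warnings.warn(f"{skipped} single-PAS genes skipped in usage testing")
    if results:
        adj = bh_adjust(raw_p)
        for r, a in zip(results, adj):
            r.p_adj = float(a)
            r.differential = bool(a <= config.adj_threshold)
    return results


def proximal_distal_shift(
    clusters: Sequence[PasCluster],
    factors: Optional[dict[str, float]] = None,
) -> dict[str, tuple[float, float]]:
    """Per gene: log2 stimulated/control support for the proximal and
    distal PAS, on size-factor-normalised support with a 0.5 pseudo-count."""
    by_gene: dict[str, list[PasCluster]] = {}
    for c in clusters:
        by_gene.setdefault(c.gene_id, []).append(c)
    out: dict[str, tuple[float, float]] = {}
    for gene_id, gene_clusters in sorted(by_gene.items()):
        if len(gene_clusters) < 2:
            continue
        strand = gene_clusters[0].strand
        ordered = sorted(
            gene_clusters, key=lambda c: c.anchor, reverse=(strand == "-")
        )
        shifts = []
        for c in (ordered[0], ordered[-1]):
            norm = {"control": 0.0, "stimulated": 0.0}
            for (sample, condition), v in c.support.items():
                f = factors.get(sample, 1.0) if factors else 1.0
                norm[condition] += v / f
            shifts.append(
                math.log2((norm["stimulated"] + 0.5) / (norm["control"] + 0.5))
            )
        out[gene_id] = (shifts[0], shifts[1])
    return out


@dataclass
class HexamerProfile:
    """Aggregate counts of PAS-signal hexamers by offset from the anchor.

    Offsets are hexamer start minus anchor in mRNA sense (negative =
    upstream).  ``truncated`` counts windows clipped at a contig edge.
    """

    offsets: dict[int, int]
    by_hexamer: dict[str, int]
    n_clusters: int
    truncated: int

    def mode_offset(self) -> Optional[int]:
        if not self.offsets:
            return None
        best = max(self.offsets.values())
        return min(o for o, c in self.offsets.items() if c == best)


def hexamer_enrichment(
    clusters: Sequence[PasCluster],
    genome: GenomeSeqs,
    config: Optional[ApaConfig] = None,
) -> HexamerProfile:
    config = config or ApaConfig()
    w = config.hexamer_window
    offsets: dict[int, int] = {}
    by_hex: dict[str, int] = {h: 0 for h in config.hexamer_set}
    truncated = 0
    for c in clusters:
        seq = genome[c.chrom]
        if c.strand == "+":
            lo = c.anchor - w
            if lo < 0:
                truncated += 1
                lo = 0
            window = seq[lo : c.anchor]
        else:
            hi = c.anchor + 1 + w
            if hi > len(seq):
                truncated += 1
                hi = len(seq)
            window = revcomp(seq[c.anchor + 1 : hi])
        # window reads 5'->3' in mRNA sense and ends just upstream of anchor
        for hexamer in config.hexamer_set:
            start = window.find(hexamer)
            while start != -1:
                offset = start - len(window)  # e.g. -20: starts 20 nt upstream
                offsets[offset] = offsets.get(offset, 0) + 1
                by_hex[hexamer] += 1
                start = window.find(hexamer, start + 1)
    return HexamerProfile(
        offsets=offsets,
        by_hexamer=by_hex,
        n_clusters=len(clusters),
        truncated=truncated,
    )


# ---------------------------------------------------------------------------
# Model-style surface


class PasUsage:
    """APA model: clusters read ends, then fits differential PAS usage."""

    def __init__(self, reads, models, config: Optional[ApaConfig] = None):
        self.reads = list(reads)
        self.models = list(models)
        self.config = config or ApaConfig()

    def fit(self) -> "PasUsageResults":
        clusters = cluster_read_ends(self.reads, self.models, self.config)
        annotate_features(clusters, self.models)
        usage = differential_pas_usage(clusters, self.config)
        shifts = proximal_distal_shift(clusters)
        return PasUsageResults(self, clusters, usage, shifts)


class PasUsageResults:
    def __init__(self, model, clusters, usage, shifts):
        self.model = model
        self.clusters = clusters
        self.usage = usage
        self.shifts = shifts

    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.usage:
            rows.append(
                {
                    "pas_id": r.pas_id,
                    "gene_id": r.gene_id,
                    "pas_control": r.table[0][0],
                    "others_control": r.table[0][1],
                    "pas_stimulated": r.table[1][0],
                    "others_stimulated": r.table[1][1],
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adj,
                    "differential": r.differential,
                    "rank": r.rank,
                    "log2_shift": r.log2_shift,
                }
            )
        return pd.DataFrame(rows)

    def cluster_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "pas_id": c.pas_id,
                    "gene_id": c.gene_id,
                    "chrom": c.chrom,
                    "strand": c.strand,
                    "anchor": c.anchor,
                    "span_start": c.span[0],
                    "span_end": c.span[1],
                    "support": c.total_support(),
                    "feature": c.feature,
                }
                for c in self.clusters
            ]
        )

    def summary(self) -> str:
        n_diff = sum(1 for r in self.usage if r.differential)
        feat = Counter(c.feature for c in self.clusters)
        lines = [
            "Alternative polyadenylation site usage (Fisher exact, BH-adjusted)",
            f"PAS clusters: {len(self.clusters)}",
            f"tested PASs (multi-PAS genes): {len(self.usage)}",
            f"differential (adj p <= {self.model.config.adj_threshold}): {n_diff}",
            "features: "
            + ", ".join(f"{k}={feat[k]}" for k in FEATURES if k in feat),
        ]
        return "\n".join(lines)
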