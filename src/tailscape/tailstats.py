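"""Per-transcript differential poly(A) tail adenylation and composition.

The between-condition test is the two-sample Wilcoxon rank-sum
(Mann-Whitney U): the compared groups are unpaired read populations, so a
two-sample test is what a standard two-group call performs.  P-values are
exact (no ties, min group size <= 8) or normal-approximated with tie and
continuity corrections, adjusted with Benjamini-Hochberg across the
transcripts actually tested.  A transcript is called significantly altered
only under the dual rule: adjusted p below alpha AND an absolute median
tail-length difference above the nt threshold.  Cohen's d bins the effect
into negligible/small/medium/large.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ReadRecord

EFFECT_CLASSES = ("negligible", "small", "medium", "large")


@dataclass
class TailTestConfig:
    min_reads: int = 10
    alpha: float = 0.05
    delta_threshold: float = 5.0  # nt, strict >
    effect_bins: tuple[float, float, float] = (0.2, 0.5, 0.8)
    qc_allowed: tuple[str, ...] = ("PASS", "SUFFCLIP")

    def __post_init__(self) -> None:
        if self.min_reads < 2:
            raise ValueError("min_reads must be >= 2")
        b = self.effect_bins
        if not (b[0] < b[1] < b[2]):
            raise ValueError("effect_bins must be strictly increasing")


@dataclass
class TailTestResult:
    transcript_id: str
    n_control: int
    n_stimulated: int
    median_control: float
    median_stimulated: float
    mean_control: float
    mean_stimulated: float
    delta_median: float
    delta_mean: float
    U: float
    p_raw: float
    p_adj: float
    cohens_d: float
    effect_class: str
    significant: bool
    degenerate_sd: bool = False


def ranksum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U of ``x`` vs ``y`` with a two-sided p-value.

    Exact enumeration when min(|x|, |y|) <= 8 and there are no ties,
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardised mean difference (y - x) / pooled sample SD.

    Returns 0.0 for a zero pooled SD (degenerate groups).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("cohens_d needs >= 2 observations per group")
    nx, ny = x.size, y.size
    s2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if s2 == 0:
        return 0.0
    return float((y.mean() - x.mean()) / math.sqrt(s2))


def classify_effect_size(
    d: float, bins: tuple[float, float, float] = (0.2, 0.5, 0.8)
) -> str:
    """Bin |d|: <b0 negligible, [b0,b1) small, [b1,b2) medium, >=b2 large."""
    a = abs(d)
    if a < bins[0]:
        return "negligible"
    if a < bins[1]:
        return "small"
    if a < bins[2]:
        return "medium"
    return "large"


def differential_adenylation(
    reads: Iterable[ReadRecord], config: Optional[TailTestConfig] = None
) -> list[TailTestResult]:
    """Test every transcript with >= min_reads QC-passing reads per condition."""
    config = config or TailTestConfig()
    groups: dict[str, dict[str, list[int]]] = {}
    for r in reads:
        if r.qc_tag not in config.qc_allowed:
            continue
        g = groups.setdefault(r.transcript_id, {"control": [], "stimulated": []})
        g[r.condition].append(r.tail_length)

    results: list[TailTestResult] = []
    for tid in sorted(groups):
        x = np.asarray(groups[tid]["control"], dtype=float)
        y = np.asarray(groups[tid]["stimulated"], dtype=float)
        if x.size < config.min_reads or y.size < config.min_reads:
            continue
        U, p = ranksum_test(x, y)
        d = cohens_d(x, y)
        degenerate = bool(x.var(ddof=1) == 0 and y.var(ddof=1) == 0)
        results.append(
            TailTestResult(
                transcript_id=tid,
                n_control=int(x.size),
                n_stimulated=int(y.size),
                median_control=float(np.median(x)),
                median_stimulated=float(np.median(y)),
                mean_control=float(x.mean()),
                mean_stimulated=float(y.mean()),
                delta_median=float(np.median(y) - np.median(x)),
                delta_mean=float(y.mean() - x.mean()),
                U=U,
                p_raw=p,
                p_adj=p,  # filled below
                cohens_d=d,
                effect_class=classify_effect_size(d, config.effect_bins),
                significant=False,
                degenerate_sd=degenerate,
            )
        )
    if not results:
        warnings.warn("no transcript passed the min_reads filter in both conditions")
        return results
    adj = bh_adjust([r.p_raw for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
        r.significant = bool(
            a < config.alpha and abs(r.delta_median) > config.delta_threshold
        )
    return results


@dataclass
class CompositionSummary:
    """Non-adenosine content of poly(A) tails for one scope."""

    scope: str
    n_reads: int
    n_decorated: int
    frac_decorated: float
    nona_per_tail: dict[int, int]
    base_counts: dict[str, int]  # keys G, C, U (tails are RNA)
    rate_by_length_bin: dict[str, float]
    n_missing_seq: int = 0


def _summarise(scope: str, tails: list[str], n_missing: int, bin_width: int = 20
               ) -> CompositionSummary:
    nona_hist: dict[int, int] = {}
    base_counts = {"G": 0, "C": 0, "U": 0}
    bins: dict[int, list[int]] = {}
    n_dec = 0
    for t in tails:
        k = sum(1 for b in t if b != "A")
        nona_hist[k] = nona_hist.get(k, 0) + 1
        if k:
            n_dec += 1
            for b in t:
                if b == "G":
                    base_counts["G"] += 1
                elif b == "C":
                    base_counts["C"] += 1
                elif b == "T":
                    base_counts["U"] += 1
        bins.setdefault(len(t) // bin_width, []).append(1 if k else 0)
    rate = {
        f"[{b * bin_width},{(b + 1) * bin_width})": float(np.mean(v))
        for b, v in sorted(bins.items())
    }
    n = len(tails)
    return CompositionSummary(
        scope=scope,
        n_reads=n,
        n_decorated=n_dec,
        frac_decorated=(n_dec / n) if n else 0.0,
        nona_per_tail=nona_hist,
        base_counts=base_counts,
        rate_by_length_bin=rate,
        n_missing_seq=n_missing,
    )


def composition_summary(
    reads: Iterable[ReadRecord],
    group_by: str = "global",
    qc_allowed: tuple[str, ...] = ("PASS", "SUFFCLIP"),
    bin_width: int = 20,
):
    """Decoration statistics, globally or per transcript.

    A tail is decorated iff its sequence contains any base other than A.
    Reads without a tail sequence are excluded and counted in
    ``n_missing_seq``.
    """
    if group_by not in ("global", "transcript"):
        raise ValueError("group_by must be 'global' or 'transcript'")
    tails: dict[str, list[str]] = {}
    missing: dict[str, int] = {}
    for r in reads:
        if r.qc_tag not in qc_allowed:
            continue
        key = "global" if group_by == "global" else r.transcript_id
        if not r.tail_seq:
            missing[key] = missing.get(key, 0) + 1
            continue
        tails.setdefault(key, []).append(r.tail_seq)
    if group_by == "global":
        return _summarise(
            "global", tails.get("global", []), missing.get("global", 0), bin_width
        )
    return {
        key: _summarise(key, seqs, missing.get(key, 0), bin_width)
        for key, seqs in sorted(tails.items())
    }


# ---------------------------------------------------------------------------
# Model-style surface


class DifferentialAdenylation:
    """Differential-adenylation model over a per-read tail table.

    Parameters
    ----------
    reads : iterable of ReadRecord
    config : TailTestConfig, optional

    ``fit()`` returns a :class:`TailResults` carrying one
    :class:`TailTestResult` per tested transcript.
    """

    def __init__(self, reads, config: Optional[TailTestConfig] = None):
        self.reads = list(reads)
        self.config = config or TailTestConfig()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, config=None):
        reads = [
            ReadRecord(
                read_id=str(row.read_id),
                transcript_id=str(row.transcript_id),
                sample_id=str(getattr(row, "sample_id", "s")),
                condition=str(row.condition),
                tail_length=int(row.tail_length),
                tail_seq=str(getattr(row, "tail_seq", "") or ""),
                end_pos=int(getattr(row, "end_pos", 0)),
                qc_tag=str(getattr(row, "qc_tag", "PASS")),
            )
            for row in frame.itertuples(index=False)
        ]
        return cls(reads, config)

    def fit(self) -> "TailResults":
        return TailResults(self, differential_adenylation(self.reads, self.config))


class TailResults:
    """Results of :class:`DifferentialAdenylation`."""

    def __init__(self, model: DifferentialAdenylation, results: list[TailTestResult]):
        self.model = model
        self.results = results

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])

    @property
    def significant(self) -> list[TailTestResult]:
        return [r for r in self.results if r.significant]

    def summary(self) -> str:
        n = len(self.results)
        sig = len(self.significant)
        lines = [
            "Differential poly(A) tail adenylation (Mann-Whitney U, BH-adjusted)",
            f"transcripts tested: {n}",
            f"significant (adj p < {self.model.config.alpha}, "
            f"|delta median| > {self.model.config.delta_threshold} nt): {sig}",
        ]
        by_class: dict[str, int] = {}
        for r in self.significant:
            by_class[r.effect_class] = by_class.get(r.effect_class, 0) + 1
        for c in EFFECT_CLASSES:
            if c in by_class:
                lines.append(f"  effect {c}: {by_class[c]}")
        return "\n".join(lines)
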