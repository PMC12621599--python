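"""Gene-level differential expression: a simplified negative-binomial Wald test.

Counts are normalised with median-of-ratios size factors.  Per gene, the
dispersion is a moment estimate pooled across conditions, the log2 fold
change is computed on pseudo-counted condition means, and its standard
error comes from the NB variance (mu + alpha mu^2) via the delta method.
This is deliberately not a DESeq2 clone: no dispersion shrinkage and no
LFC shrinkage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReadRecord
from .tailstats import bh_adjust

ALPHA_FLOOR = 1e-8
PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts plus a condition map."""

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition: {sorted(missing)}")
        values = set(self.conditions[s] for s in self.counts.columns)
        if not {"control", "stimulated"} <= values:
            raise ValueError("need >= 1 sample per condition")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


@dataclass
class DiffExprResult:
    gene_id: str
    base_mean: float
    log2_fc: float
    se: float
    wald_z: float
    p_raw: float
    p_adj: float
    significant: bool


def count_matrix(
    reads: Iterable[ReadRecord],
    qc_allowed: tuple[str, ...] = ("PASS", "SUFFCLIP"),
) -> CountMatrix:
    """Tally QC-passing reads per transcript and sample."""
    tallies: dict[str, dict[str, int]] = {}
    conditions: dict[str, str] = {}
    for r in reads:
        if r.qc_tag not in qc_allowed:
            continue
        conditions[r.sample_id] = r.condition
        row = tallies.setdefault(r.transcript_id, {})
        row[r.sample_id] = row.get(r.sample_id, 0) + 1
    samples = sorted(conditions)
    frame = pd.DataFrame.from_dict(tallies, orient="index").reindex(
        columns=samples
    ).fillna(0).astype(int)
    frame = frame.sort_index()
    return CountMatrix(frame, conditions)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style median-of-ratios normalisation factors."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "use a pseudo-reference or filter samples"
        )
    logs = np.log(arr[positive])
    log_geomean = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def _pooled_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> float:
    """Per-gene moment dispersion pooled across conditions (df-weighted)."""
    num = 0.0
    den = 0
    for idx in groups:
        vals = norm[idx]
        if vals.size < 2:
            continue
        mu = vals.mean()
        if mu <= 0:
            continue
        alpha = (vals.var(ddof=1) - mu) / mu**2
        num += alpha * (vals.size - 1)
        den += vals.size - 1
    if den == 0:
        return math.nan
    return num / den


def nb_wald_test(
    counts: CountMatrix,
    factors: Optional[pd.Series] = None,
    alpha: float = 0.05,
    alpha_floor: float = ALPHA_FLOOR,
) -> list[DiffExprResult]:
    """Wald test on the log2 ratio of normalised condition means.

    With fewer than two replicates in a condition the per-gene moment
    dispersion is undefined; a single common dispersion (median of per-gene
    moment estimates pooling all samples) is used instead.
    """
    if factors is None:
        factors = size_factors(counts.counts)
    norm = counts.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    cols = list(counts.counts.columns)
    ctrl_idx = np.array([i for i, s in enumerate(cols) if counts.conditions[s] == "control"])
    stim_idx = np.array([i for i, s in enumerate(cols) if counts.conditions[s] == "stimulated"])
    n_c, n_s = len(ctrl_idx), len(stim_idx)
    per_gene_ok = n_c >= 2 and n_s >= 2

    common_alpha = None
    if not per_gene_ok:
        # pool both conditions' samples per gene (valid when most genes are
        # null) and take the median moment estimate across genes
        alphas = []
        for row in norm:
            mu = row.mean()
            if mu > 0 and row.size >= 2:
                alphas.append((row.var(ddof=1) - mu) / mu**2)
        common_alpha = max(alpha_floor, float(np.median(alphas))) if alphas else 0.1

    results: list[DiffExprResult] = []
    raw_p: list[float] = []
    n_allzero = 0
    for gi, gene in enumerate(counts.counts.index):
        row = norm[gi]
        if not row.any():
            n_allzero += 1
            continue
        mu_c = row[ctrl_idx].mean()
        mu_s = row[stim_idx].mean()
        if per_gene_ok:
            disp = _pooled_dispersion(row, [ctrl_idx, stim_idx])
            disp = alpha_floor if math.isnan(disp) else max(alpha_floor, disp)
        else:
            disp = common_alpha
        log2_fc = math.log2((mu_s + PSEUDOCOUNT) / (mu_c + PSEUDOCOUNT))
        # delta method on log2 of each condition mean; NB variance mu+a*mu^2
        var = 0.0
        for mu, n in ((mu_c, n_c), (mu_s, n_s)):
            m = mu + PSEUDOCOUNT
            var += (m + disp * m**2) / (n * m**2)
        se = math.sqrt(var) / math.log(2)
        z = log2_fc / se
        p = float(2 * stats.norm.sf(abs(z)))
        results.append(
            DiffExprResult(
                gene_id=str(gene),
                base_mean=float(row.mean()),
                log2_fc=float(log2_fc),
                se=float(se),
                wald_z=float(z),
                p_raw=min(p, 1.0),
                p_adj=1.0,
                significant=False,
            )
        )
        raw_p.append(min(p, 1.0))
    if n_allzero:
        warnings.warn(f"{n_allzero} all-zero genes excluded from the Wald test")
    if results:
        adj = bh_adjust(raw_p)
        for r, a in zip(results, adj):
            r.p_adj = float(a)
            r.significant = bool(a < alpha)
    return results


# ---------------------------------------------------------------------------
# Model-style surface


class NegativeBinomialExpression:
    """NB Wald differential-expression model.

    Built either from per-read records (``NegativeBinomialExpression(reads)``)
    or directly from a :class:`CountMatrix`.
    """

    def __init__(self, data, alpha: float = 0.05):
        if isinstance(data, CountMatrix):
            self.counts = data
        else:
            self.counts = count_matrix(data)
        self.alpha = alpha

    @classmethod
    def from_counts(cls, frame: pd.DataFrame, conditions: Mapping[str, str],
                    alpha: float = 0.05):
        return cls(CountMatrix(frame, dict(conditions)), alpha=alpha)

    def fit(self) -> "ExpressionResults":
        factors = size_factors(self.counts.counts)
        results = nb_wald_test(self.counts, factors, alpha=self.alpha)
        return ExpressionResults(self, factors, results)


class ExpressionResults:
    def __init__(self, model, factors: pd.Series, results: list[DiffExprResult]):
        self.model = model
        self.size_factors = factors
        self.results = results

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.results])

    @property
    def significant(self) -> list[DiffExprResult]:
        return [r for r in self.results if r.significant]

    def summary(self) -> str:
        up = sum(1 for r in self.significant if r.log2_fc > 0)
        down = sum(1 for r in self.significant if r.log2_fc < 0)
        return "\n".join(
            [
                "Negative-binomial Wald differential expression",
                f"genes tested: {len(self.results)}",
                f"significant (BH adj p < {self.model.alpha}): "
                f"{len(self.significant)} ({up} up, {down} down)",
            ]
        )
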