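"""Orchestration and mechanism discrimination.

Two mechanisms can raise poly(A) tail lengths after stimulation:
transcriptional induction (new, long-tailed molecules enter the pool, so
abundance rises too) and cytoplasmic polyadenylation (preexisting
molecules are elongated with no abundance change).  Crossing the
differential-expression state with the differential-adenylation state
separates them; the label map used here is this package's explicit
operationalisation of that argument:

==========  ==========  =====================================
expression  tail        label
==========  ==========  =====================================
up          elongated   transcriptional_induction
unchanged   elongated   cytoplasmic_polyadenylation_candidate
down        shortened   deadenylation_decay
up/unch.    shortened   translation_deadenylation_like
otherwise               stable
==========  ==========  =====================================

"unchanged" means not significant (the argument runs on significance
flags, not on point estimates).  The expression/adenylation Pearson
correlation is computed, by default, over genes with a significant tail
change only.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .apa import ApaConfig, PasUsage, hexamer_enrichment
from .expression import DiffExprResult, NegativeBinomialExpression
from .io import read_annotation, read_fasta, read_tail_table, write_bed
from .motifs import annotate_cpe, example_cpe_motifs, read_meme_motifs
from .semitemplated import (
    SemiTemplatedConfig,
    call_semitemplated,
    candidate_windows,
)
from .simulate import SimConfig, simulate_dataset
from .tailstats import (
    DifferentialAdenylation,
    TailTestConfig,
    TailTestResult,
    composition_summary,
)

MECHANISM_LABELS = (
    "transcriptional_induction",
    "cytoplasmic_polyadenylation_candidate",
    "deadenylation_decay",
    "translation_deadenylation_like",
    "stable",
)


@dataclass
class CorrelationResult:
    n: int
    r: float
    t_stat: float
    df: int
    p_two_sided: float


@dataclass
class MechanismCall:
    gene_id: str
    expr_state: str  # up | down | unchanged
    tail_state: str  # elongated | shortened | unchanged
    label: str


def pearson_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with the Student-t test (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate input: zero variance")
    n = int(x.size)
    df = n - 2
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-12:
        return CorrelationResult(n=n, r=float(np.sign(r)), t_stat=math.inf * np.sign(r),
                                 df=df, p_two_sided=0.0)
    t = r * math.sqrt(df / (1 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(n=n, r=r, t_stat=float(t), df=df, p_two_sided=min(p, 1.0))


def classify_mechanism(
    de: Optional[DiffExprResult], tail: Optional[TailTestResult]
) -> MechanismCall:
    """Label one gene from its expression and adenylation states.

    A gene absent from either analysis contributes an 'unchanged' state
    for that axis.
    """
    if de is not None:
        expr_state = (
            "up" if de.significant and de.log2_fc > 0
            else "down" if de.significant and de.log2_fc < 0
            else "unchanged"
        )
        gene_id = de.gene_id
    else:
        expr_state = "unchanged"
        gene_id = tail.transcript_id if tail is not None else "?"
    if tail is not None:
        tail_state = (
            "elongated" if tail.significant and tail.delta_median > 0
            else "shortened" if tail.significant and tail.delta_median < 0
            else "unchanged"
        )
    else:
        tail_state = "unchanged"

    if expr_state == "up" and tail_state == "elongated":
        label = "transcriptional_induction"
    elif expr_state == "unchanged" and tail_state == "elongated":
        label = "cytoplasmic_polyadenylation_candidate"
    elif expr_state == "down" and tail_state == "shortened":
        label = "deadenylation_decay"
    elif expr_state in ("unchanged", "up") and tail_state == "shortened":
        label = "translation_deadenylation_like"
    else:
        label = "stable"
    return MechanismCall(
        gene_id=gene_id, expr_state=expr_state, tail_state=tail_state, label=label
    )


def classify_all(
    de_results: Sequence[DiffExprResult],
    tail_results: Sequence[TailTestResult],
    gene_of_transcript: Optional[dict[str, str]] = None,
) -> list[MechanismCall]:
    """Join the two analyses on gene and label every gene seen in either."""
    gene_of = gene_of_transcript or {}
    de_by_gene = {r.gene_id: r for r in de_results}
    tail_by_gene = {
        gene_of.get(r.transcript_id, r.transcript_id): r for r in tail_results
    }
    de_keyed = {gene_of.get(g, g): r for g, r in de_by_gene.items()}
    calls = []
    for gene in sorted(set(de_keyed) | set(tail_by_gene)):
        call = classify_mechanism(de_keyed.get(gene), tail_by_gene.get(gene))
        call.gene_id = gene
        calls.append(call)
    return calls


def correlate_expression_adenylation(
    de_results: Sequence[DiffExprResult],
    tail_results: Sequence[TailTestResult],
    significant_tail_only: bool = True,
    gene_of_transcript: Optional[dict[str, str]] = None,
) -> CorrelationResult:
    """Pearson correlation of log2 expression change vs mean tail change.

    By default restricted to genes whose tail change is significant,
    mirroring how the expression/adenylation relationship is usually
    displayed.
    """
    gene_of = gene_of_transcript or {}
    de_keyed = {gene_of.get(r.gene_id, r.gene_id): r for r in de_results}
    x, y = [], []
    for t in tail_results:
        if significant_tail_only and not t.significant:
            continue
        gene = gene_of.get(t.transcript_id, t.transcript_id)
        de = de_keyed.get(gene)
        if de is None:
            continue
        x.append(de.log2_fc)
        y.append(t.delta_mean)
    if len(x) < 3:
        raise ValueError(
            f"only {len(x)} genes joined across analyses; need >= 3"
        )
    return pearson_test(x, y)


# ---------------------------------------------------------------------------
# End-to-end run


@dataclass
class PipelineConfig:
    outdir: str = "tailscape_out"
    seed: int = 0
    simulate: bool = True
    reads_path: Optional[str] = None
    annotation_path: Optional[str] = None
    genome_path: Optional[str] = None
    motifs_path: Optional[str] = None  # None -> synthetic example matrices
    sim: SimConfig = field(default_factory=SimConfig)
    tails: TailTestConfig = field(default_factory=TailTestConfig)
    apa: ApaConfig = field(default_factory=ApaConfig)
    semi: SemiTemplatedConfig = field(default_factory=SemiTemplatedConfig)
    correlation_significant_only: bool = True


def _float_fmt(frame: pd.DataFrame) -> pd.DataFrame:
    return frame


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and write TSVs plus a JSON report.

    Returns the report dict; all outputs are deterministic for a fixed
    config (including the seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim_config = config.sim
        if sim_config.seed != config.seed:
            sim_config = SimConfig(**{**vars(sim_config), "seed": config.seed})
        paths = simulate_dataset(sim_config, outdir)
        reads = read_tail_table(paths["reads"])
        models = read_annotation(paths["annotation"])
        genome = read_fasta(paths["genome"])
    else:
        if not (config.reads_path and config.annotation_path and config.genome_path):
            raise ValueError("without simulation, reads/annotation/genome paths are required")
        reads = read_tail_table(config.reads_path)
        models = read_annotation(config.annotation_path)
        genome = read_fasta(config.genome_path)

    gene_of = {m.transcript_id: m.gene_id for m in models}
    report: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # differential adenylation
    tail_fit = DifferentialAdenylation(reads, config.tails).fit()
    tail_fit.frame().to_csv(outdir / "tails.tsv", sep="\t", index=False)
    report["stages"]["tails"] = {
        "tested": len(tail_fit.results),
        "significant": len(tail_fit.significant),
    }

    # composition
    comp = composition_summary(reads)
    report["stages"]["composition"] = {
        "n_reads": comp.n_reads,
        "frac_decorated": comp.frac_decorated,
        "base_counts": comp.base_counts,
    }
    with open(outdir / "composition.json", "w") as fh:
        json.dump(vars(comp), fh, sort_keys=True, indent=1, default=str)
        fh.write("\n")

    # expression
    expr_fit = NegativeBinomialExpression(reads).fit()
    expr_fit.frame().to_csv(outdir / "de.tsv", sep="\t", index=False)
    up = sum(1 for r in expr_fit.significant if r.log2_fc > 0)
    report["stages"]["expression"] = {
        "tested": len(expr_fit.results),
        "significant": len(expr_fit.significant),
        "up": up,
    }

    # APA
    apa_fit = PasUsage(reads, models, config.apa).fit()
    write_bed([c.to_bed() for c in apa_fit.clusters], outdir / "pas.bed")
    apa_fit.frame().to_csv(outdir / "usage.tsv", sep="\t", index=False)
    profile = hexamer_enrichment(apa_fit.clusters, genome, config.apa)
    pd.DataFrame(
        sorted(profile.offsets.items()), columns=["offset", "count"]
    ).to_csv(outdir / "hexamer.tsv", sep="\t", index=False)
    report["stages"]["apa"] = {
        "clusters": len(apa_fit.clusters),
        "tested": len(apa_fit.usage),
        "differential": sum(1 for r in apa_fit.usage if r.differential),
        "hexamer_mode_offset": profile.mode_offset(),
    }

    # CPE motifs
    matrices = (
        read_meme_motifs(config.motifs_path)
        if config.motifs_path
        else example_cpe_motifs()
    )
    cpe = annotate_cpe(models, genome, matrices)
    cpe.to_csv(outdir / "cpe.tsv", sep="\t")
    report["stages"]["cpe"] = {
        f"n_{col}": int(cpe[col].sum()) for col in cpe.columns if col.startswith("has_")
    }

    # semi-templated tails
    windows = candidate_windows(models, genome, apa_fit.clusters, config.semi)
    semi_res = call_semitemplated(windows, reads, config.semi)
    semi_res.frame().to_csv(outdir / "semitemplated.tsv", sep="\t", index=False)
    report["stages"]["semitemplated"] = dict(semi_res.counts)

    # mechanism discrimination
    calls = classify_all(expr_fit.results, tail_fit.results, gene_of)
    pd.DataFrame([vars(c) for c in calls]).to_csv(
        outdir / "mechanisms.tsv", sep="\t", index=False
    )
    label_counts: dict[str, int] = {}
    for c in calls:
        label_counts[c.label] = label_counts.get(c.label, 0) + 1
    report["stages"]["mechanisms"] = label_counts

    try:
        corr = correlate_expression_adenylation(
            expr_fit.results,
            tail_fit.results,
            significant_tail_only=config.correlation_significant_only,
            gene_of_transcript=gene_of,
        )
        report["correlation"] = vars(corr)
    except ValueError as exc:
        warnings.warn(str(exc))
        report["correlation"] = None

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return report
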