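"""Synthetic nanopore-style 3'-end data with planted ground truth.

The generator emulates a two-condition (control vs stimulated) direct-RNA
experiment at the per-read level, with the statistical structure the
downstream analyses assume:

* **Expression** — per gene/sample read counts are negative binomial, with
  a condition fold applied by mechanism.
* **Tails** — per-read poly(A) lengths are rounded log-normals.  Five
  mechanisms are planted per gene:

  - ``null``: nothing changes.
  - ``transcriptional_induction``: stimulated counts x fold; the *excess*
    (newly made) molecules enter with longer tails while preexisting
    molecules keep the baseline distribution — a mixture, which is what
    makes induction distinguishable from cytoplasmic elongation.
  - ``cytoplasmic_polyadenylation``: counts unchanged, every stimulated
    tail shifted up.
  - ``deadenylation_decay``: stimulated counts / fold and tails shifted
    down.
  - ``translation_deadenylation``: counts unchanged, tails mildly
    shortened (shift/4).

* **Decoration** — each polymerized tail position mutates to a
  non-adenosine with probability ``misincorporation_rate``, the base drawn
  with G >= C >= T bias, so P(decorated | L) rises with tail length.
* **APA** — a configurable fraction of genes carries two polyadenylation
  sites (proximal 150 nt upstream of the distal end) with a planted usage
  shift between conditions; a canonical AATAAA is planted 20 nt upstream
  of every background-gene PAS anchor.
* **Semi-templated tails** — a fraction of genes gets an extremely
  A/T-rich 3'UTR terminus with a guaranteed >=13-nt terminal A/T run; the
  genomic suffix (carrying a fixed-position G) is fused onto every read's
  tail, so non-adenosines appear at fixed positions.

Background genes are constructed so their terminal windows can *never*
satisfy either semi-templated rule (A/T fraction capped below 0.6 and A/T
runs broken every few nucleotides, with margins covering end-position
jitter), which makes exact recovery assertable.

A single seed fully determines all output; per-gene substreams are derived
by stable hashing of the gene id so enlarging a simulation does not
reshuffle existing genes.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    GenomeSeqs,
    ReadRecord,
    TranscriptModel,
    revcomp,
    write_annotation,
    write_fasta,
    write_tail_table,
)

MECHANISMS = (
    "null",
    "transcriptional_induction",
    "cytoplasmic_polyadenylation",
    "deadenylation_decay",
    "translation_deadenylation",
)

# sense-coordinate layout of every simulated contig
_PAD_UP = 100
_EXON1 = (100, 160)
_INTRON = (160, 200)
_EXON2_START = 200
_TX_END = 600
_UTR3_START = 400
_PAD_DOWN = 30
_CONTIG_LEN = _TX_END + _PAD_DOWN
_PROXIMAL_OFFSET = 150  # proximal PAS this far upstream of the distal end

# genomic suffix fused onto semi-templated tails: fixed G at suffix index 4,
# then a 14-nt terminal A run (>=13 with the last three A/T)
FUSED_SUFFIX = "AAAAG" + "A" * 14


@dataclass
class SimConfig:
    """Study conditions for the generator.

    ``baseline_mean_expression`` is the expected number of reads per gene
    per *condition* at baseline (split across replicates).
    """

    seed: int = 0
    n_genes: int = 500
    n_replicates: int = 4
    baseline_mean_expression: float = 50.0
    nb_dispersion: float = 0.05
    baseline_tail_median: float = 100.0
    tail_sd_log: float = 0.35
    induction_fold: float = 4.0
    tail_shift: float = 40.0
    misincorporation_rate: float = 0.002
    nona_bias: tuple[float, float, float] = (0.5, 0.3, 0.2)  # G, C, T
    frac_induction: float = 0.1
    frac_cytoplasmic: float = 0.1
    frac_decay: float = 0.1
    frac_translation_deadenylation: float = 0.0
    frac_two_pas_genes: float = 0.1
    proximal_usage: tuple[float, float] = (0.3, 0.6)  # control, stimulated
    frac_semitemplated: float = 0.1
    utr_at_fraction_rich: float = 0.85
    utr_at_fraction_background: float = 0.5
    end_jitter_sd: float = 3.0
    frac_suffclip: float = 0.05
    frac_fail: float = 0.02
    mechanism_assignments: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be >= 1")
        if self.baseline_mean_expression <= 0 or self.nb_dispersion <= 0:
            raise ValueError("expression mean and dispersion must be positive")
        if self.baseline_tail_median <= 0 or self.tail_sd_log <= 0:
            raise ValueError("tail median and lognormal sd must be positive")
        if self.induction_fold <= 1:
            raise ValueError("induction_fold must be > 1")
        if not 0 <= self.misincorporation_rate < 1:
            raise ValueError("misincorporation_rate must be in [0, 1)")
        g, c, t = self.nona_bias
        if not (g >= c >= t >= 0) or abs(g + c + t - 1.0) > 1e-9:
            raise ValueError("nona_bias must sum to 1 with G >= C >= T")
        for name in (
            "frac_induction",
            "frac_cytoplasmic",
            "frac_decay",
            "frac_translation_deadenylation",
            "frac_two_pas_genes",
            "frac_semitemplated",
            "frac_suffclip",
            "frac_fail",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not all(0 <= u <= 1 for u in self.proximal_usage):
            raise ValueError("proximal_usage values must be in [0, 1]")
        if not 0.6 < self.utr_at_fraction_rich <= 1:
            raise ValueError("utr_at_fraction_rich must be in (0.6, 1]")
        if not 0 <= self.utr_at_fraction_background < 0.6:
            raise ValueError("utr_at_fraction_background must be in [0, 0.6)")

    # ---- planted layout ---------------------------------------------------

    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(1, self.n_genes + 1)]

    def mechanisms(self) -> dict[str, str]:
        """Mechanism per gene: explicit map if given, else block layout."""
        ids = self.gene_ids()
        if self.mechanism_assignments is not None:
            missing = set(ids) - set(self.mechanism_assignments)
            if missing:
                raise ValueError(f"mechanism_assignments misses {len(missing)} genes")
            bad = set(self.mechanism_assignments.values()) - set(MECHANISMS)
            if bad:
                raise ValueError(f"unknown mechanisms {sorted(bad)}")
            return {g: self.mechanism_assignments[g] for g in ids}
        n = self.n_genes
        blocks = [
            ("transcriptional_induction", round(self.frac_induction * n)),
            ("cytoplasmic_polyadenylation", round(self.frac_cytoplasmic * n)),
            ("deadenylation_decay", round(self.frac_decay * n)),
            ("translation_deadenylation", round(self.frac_translation_deadenylation * n)),
        ]
        out: dict[str, str] = {}
        i = 0
        for mech, k in blocks:
            for _ in range(k):
                if i >= n:
                    raise ValueError("mechanism fractions exceed 1")
                out[ids[i]] = mech
                i += 1
        for j in range(i, n):
            out[ids[j]] = "null"
        return out

    def special_roles(self) -> tuple[set[str], set[str]]:
        """(semi-templated genes, two-PAS genes): disjoint, from the null block."""
        mechs = self.mechanisms()
        nulls = [g for g in self.gene_ids() if mechs[g] == "null"]
        n_semi = round(self.frac_semitemplated * self.n_genes)
        n_two = round(self.frac_two_pas_genes * self.n_genes)
        if n_semi + n_two > len(nulls):
            raise ValueError(
                "not enough null genes for semi-templated + two-PAS roles"
            )
        semi = set(nulls[len(nulls) - n_semi :])
        two = set(nulls[len(nulls) - n_semi - n_two : len(nulls) - n_semi])
        return semi, two


@dataclass
class SimTruth:
    """Planted ground truth, consistent with the emitted reads."""

    genes: dict[str, dict]
    decorated: dict[str, list[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"genes": self.genes, "decorated": self.decorated}

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(genes=d["genes"], decorated=d.get("decorated", {}))


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# RNG plumbing


def _gene_rng(config: SimConfig, gene_id: str, stream: int) -> np.random.Generator:
    # crc32 gives a stable per-gene key, so adding genes never reshuffles
    # the substreams of existing ones
    key = zlib.crc32(gene_id.encode())
    return np.random.default_rng(np.random.SeedSequence((config.seed, key, stream)))


# ---------------------------------------------------------------------------
# Reference construction

_AT = np.array(list("AT"))
_GC = np.array(list("GC"))
_ACGT = np.array(list("ACGT"))


def _uniform_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_ACGT, size=n)


def _constrained_zone(
    rng: np.random.Generator, length: int, plant: dict[int, str]
) -> np.ndarray:
    """A/T-poor zone: every 6-block holds exactly 2 free A/T characters.

    Any 60-nt window fully inside the zone then has A/T fraction <= 0.55
    even with one planted AATAAA, and no A/T run can exceed 10.
    """
    out = np.empty(length, dtype="<U1")
    for b0 in range(0, length, 6):
        block = list(range(b0, min(b0 + 6, length)))
        planted = [i for i in block if i in plant]
        free = [i for i in block if i not in plant]
        for i in planted:
            out[i] = plant[i]
        n_at_planted = sum(1 for i in planted if plant[i] in "AT")
        n_at_free = max(0, 2 - n_at_planted)
        n_at_free = min(n_at_free, len(free))
        order = rng.permutation(len(free))
        for rank, idx in enumerate(order):
            i = free[idx]
            out[i] = rng.choice(_AT) if rank < n_at_free else rng.choice(_GC)
    return out


def _rich_terminal(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    """60-nt A/T-rich terminus ending in the fused suffix (terminal A run)."""
    window = np.empty(60, dtype="<U1")
    suffix = np.array(list(FUSED_SUFFIX))
    n_up = 60 - len(suffix)
    n_at_suffix = int(np.sum(np.isin(suffix, _AT)))
    n_at_up = min(n_up, max(0, math.ceil(config.utr_at_fraction_rich * 60) - n_at_suffix))
    chars = np.concatenate(
        [rng.choice(_AT, size=n_at_up), rng.choice(_GC, size=n_up - n_at_up)]
    )
    window[:n_up] = rng.permutation(chars)
    window[n_up:] = suffix
    return window


def generate_reference(
    config: SimConfig,
) -> tuple[GenomeSeqs, list[TranscriptModel]]:
    """One contig per gene with a two-exon transcript and a 200-nt 3'UTR."""
    mechs = config.mechanisms()
    semi, two_pas = config.special_roles()
    sequences: dict[str, str] = {}
    models: list[TranscriptModel] = []
    for gi, gene_id in enumerate(config.gene_ids()):
        rng = _gene_rng(config, gene_id, stream=1)
        strand = "+" if gi % 2 == 0 else "-"
        sense = _uniform_seq(rng, _CONTIG_LEN)

        a_d = _TX_END - 1  # distal PAS anchor, sense coordinate
        anchors = [a_d]
        if gene_id in two_pas:
            anchors.append(a_d - _PROXIMAL_OFFSET)
        if gene_id in semi:
            sense[a_d - 59 : a_d + 1] = _rich_terminal(rng, config)
        else:
            for a in anchors:
                zone_start = a - 74
                plant = {
                    (a - 20 - zone_start) + k: base
                    for k, base in enumerate("AATAAA")
                }
                zone = _constrained_zone(rng, 81, plant)
                sense[zone_start : a + 7] = zone

        seq = "".join(sense)
        if strand == "-":
            seq = revcomp(seq)
        sequences[gene_id] = seq

        def g_iv(s: int, e: int) -> tuple[int, int]:
            if strand == "+":
                return (s, e)
            return (_CONTIG_LEN - e, _CONTIG_LEN - s)

        exons = sorted([g_iv(*_EXON1), g_iv(_EXON2_START, _TX_END)])
        models.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                chrom=gene_id,
                strand=strand,
                exons=exons,
                utr3=g_iv(_UTR3_START, _TX_END),
            )
        )
    return GenomeSeqs(sequences), models


# ---------------------------------------------------------------------------
# Read generation


def _fold(mechanism: str, condition: str, config: SimConfig) -> float:
    if condition == "control":
        return 1.0
    if mechanism == "transcriptional_induction":
        return config.induction_fold
    if mechanism == "deadenylation_decay":
        return 1.0 / config.induction_fold
    return 1.0


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) :
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _draw_counts(
    rng: np.random.Generator, mechanism: str, config: SimConfig
) -> dict[str, np.ndarray]:
    per_rep = config.baseline_mean_expression / config.n_replicates
    out = {}
    for condition in ("control", "stimulated"):
        mean = per_rep * _fold(mechanism, condition, config)
        out[condition] = _nb_draw(
            rng, mean, config.nb_dispersion, config.n_replicates
        )
    return out


def _stim_medians(
    rng: np.random.Generator, mechanism: str, n: int, config: SimConfig
) -> np.ndarray:
    base = config.baseline_tail_median
    shift = config.tail_shift
    if mechanism == "cytoplasmic_polyadenylation":
        return np.full(n, base + shift)
    if mechanism == "transcriptional_induction":
        # preexisting molecules (prob 1/fold) keep the baseline median;
        # the excess, newly transcribed ones enter with longer tails
        old = rng.random(n) < 1.0 / config.induction_fold
        return np.where(old, base, base + shift)
    if mechanism == "deadenylation_decay":
        return np.full(n, max(5.0, base - shift))
    if mechanism == "translation_deadenylation":
        return np.full(n, max(5.0, base - shift / 4.0))
    return np.full(n, base)


_NONA = np.array(list("GCT"))


def generate_reads(
    config: SimConfig,
    reference: tuple[GenomeSeqs, list[TranscriptModel]],
) -> tuple[list[ReadRecord], SimTruth]:
    genome, models = reference
    by_gene = {m.gene_id: m for m in models}
    mechs = config.mechanisms()
    semi, two_pas = config.special_roles()
    eps = config.misincorporation_rate
    bias = np.asarray(config.nona_bias, dtype=float)

    reads: list[ReadRecord] = []
    truth_genes: dict[str, dict] = {}
    decorated: dict[str, list[int]] = {}

    for gene_id in config.gene_ids():
        model = by_gene[gene_id]
        mech = mechs[gene_id]
        rng = _gene_rng(config, gene_id, stream=2)
        counts = _draw_counts(rng, mech, config)

        a_d_sense = _TX_END - 1
        if gene_id in semi:
            a_d_sense -= len(FUSED_SUFFIX)  # templated part ends before the A run
        anchors_sense = {"distal": a_d_sense}
        if gene_id in two_pas:
            anchors_sense["proximal"] = _TX_END - 1 - _PROXIMAL_OFFSET

        def to_genomic(a_sense: int) -> int:
            if model.strand == "+":
                return a_sense
            return _CONTIG_LEN - 1 - a_sense

        log2fc = (
            math.log2(config.induction_fold)
            if mech == "transcriptional_induction"
            else -math.log2(config.induction_fold)
            if mech == "deadenylation_decay"
            else 0.0
        )
        tail_shift = {
            "null": 0.0,
            "transcriptional_induction": config.tail_shift,
            "cytoplasmic_polyadenylation": config.tail_shift,
            "deadenylation_decay": -config.tail_shift,
            "translation_deadenylation": -config.tail_shift / 4.0,
        }[mech]
        truth_genes[gene_id] = {
            "mechanism": mech,
            "log2_fc": log2fc,
            "tail_shift": tail_shift,
            "is_semitemplated": gene_id in semi,
            "is_two_pas": gene_id in two_pas,
            "pas": {k: to_genomic(v) for k, v in anchors_sense.items()},
            "proximal_usage": {
                "control": config.proximal_usage[0],
                "stimulated": config.proximal_usage[1],
            }
            if gene_id in two_pas
            else None,
            "strand": model.strand,
            "chrom": model.chrom,
        }

        for condition, prefix in (("control", "ctrl"), ("stimulated", "stim")):
            usage_p = (
                config.proximal_usage[0]
                if condition == "control"
                else config.proximal_usage[1]
            )
            for rep in range(config.n_replicates):
                n = int(counts[condition][rep])
                if n == 0:
                    continue
                sample_id = f"{prefix}_{rep + 1}"
                if condition == "stimulated":
                    medians = _stim_medians(rng, mech, n, config)
                else:
                    medians = np.full(n, config.baseline_tail_median)
                lengths = np.maximum(
                    1,
                    np.rint(
                        rng.lognormal(np.log(medians), config.tail_sd_log)
                    ).astype(int),
                )
                jitter = np.rint(
                    np.clip(rng.normal(0.0, config.end_jitter_sd, n), -6, 6)
                ).astype(int)
                use_prox = (
                    rng.random(n) < usage_p if gene_id in two_pas else np.zeros(n, bool)
                )
                qc_u = rng.random(n)
                n_mut = rng.binomial(lengths, eps)
                for i in range(n):
                    read_id = f"{gene_id}:{prefix}{rep + 1}:{i}"
                    L = int(lengths[i])
                    tail = np.full(L, "A", dtype="<U1")
                    positions: list[int] = []
                    if n_mut[i] > 0:
                        pos = rng.choice(L, size=int(n_mut[i]), replace=False)
                        tail[pos] = rng.choice(_NONA, size=len(pos), p=bias)
                        positions = sorted(int(p) for p in pos)
                    if gene_id in semi:
                        tail_seq = FUSED_SUFFIX + "".join(tail)
                        positions = [4] + [p + len(FUSED_SUFFIX) for p in positions]
                    else:
                        tail_seq = "".join(tail)
                    if positions:
                        decorated[read_id] = positions
                    a_sense = (
                        anchors_sense["proximal"]
                        if use_prox[i]
                        else anchors_sense["distal"]
                    )
                    end_pos = to_genomic(a_sense) + (
                        int(jitter[i]) if model.strand == "+" else -int(jitter[i])
                    )
                    end_pos = min(max(end_pos, 0), _CONTIG_LEN - 1)
                    qc = (
                        "FAIL"
                        if qc_u[i] < config.frac_fail
                        else "SUFFCLIP"
                        if qc_u[i] < config.frac_fail + config.frac_suffclip
                        else "PASS"
                    )
                    reads.append(
                        ReadRecord(
                            read_id=read_id,
                            transcript_id=model.transcript_id,
                            sample_id=sample_id,
                            condition=condition,
                            tail_length=len(tail_seq),
                            tail_seq=tail_seq,
                            end_pos=end_pos,
                            qc_tag=qc,
                        )
                    )
    return reads, SimTruth(genes=truth_genes, decorated=decorated)


def generate_counts(config: SimConfig):
    """Count-only fast path: the same count draws as :func:`generate_reads`.

    Returns ``(counts DataFrame genes x samples, condition map, SimTruth)``
    without materialising reads; useful for expression calibration at sizes
    where per-read simulation would be wasteful.
    """
    import pandas as pd

    mechs = config.mechanisms()
    samples = [f"ctrl_{r + 1}" for r in range(config.n_replicates)] + [
        f"stim_{r + 1}" for r in range(config.n_replicates)
    ]
    conditions = {
        s: ("control" if s.startswith("ctrl") else "stimulated") for s in samples
    }
    rows = {}
    truth_genes = {}
    for gene_id in config.gene_ids():
        rng = _gene_rng(config, gene_id, stream=2)
        counts = _draw_counts(rng, mechs[gene_id], config)
        rows[gene_id] = np.concatenate(
            [counts["control"], counts["stimulated"]]
        )
        mech = mechs[gene_id]
        truth_genes[gene_id] = {
            "mechanism": mech,
            "log2_fc": math.log2(config.induction_fold)
            if mech == "transcriptional_induction"
            else -math.log2(config.induction_fold)
            if mech == "deadenylation_decay"
            else 0.0,
        }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return frame, conditions, SimTruth(genes=truth_genes)


def simulate_dataset(config: SimConfig, outdir) -> dict[str, Path]:
    """Generate and write genome.fa, annotation.gtf, reads.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(config)
    reads, truth = generate_reads(config, reference)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gtf",
        "reads": outdir / "reads.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(reference[0], paths["genome"])
    write_annotation(reference[1], paths["annotation"])
    write_tail_table(reads, paths["reads"])
    write_truth(truth, paths["truth"])
    return paths
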