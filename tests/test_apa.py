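import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from tailscape.apa import (
    ApaConfig,
    PasCluster,
    PasUsage,
    assign_feature,
    cluster_read_ends,
    differential_pas_usage,
    fisher_exact,
    hexamer_enrichment,
    proximal_distal_shift,
)
from tailscape.io import GenomeSeqs, ReadRecord, TranscriptModel, revcomp


def fisher_enumeration(table, tol=1e-7):
    """Two-sided Fisher p by full hypergeometric enumeration (oracle)."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        return 1.0
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom.pmf(k, n, col1, row1)
        if pk <= p_obs * (1 + tol):
            total += pk
    return min(total, 1.0)


def _read(tid, end, sample="s1", condition="control"):
    return ReadRecord(
        read_id=f"{tid}:{end}:{sample}:{condition}:{np.random.randint(1 << 30)}",
        transcript_id=tid,
        sample_id=sample,
        condition=condition,
        tail_length=0,
        tail_seq="",
        end_pos=end,
    )


def _model(strand="+", utr3=(60, 100)):
    return TranscriptModel("g", "g.t1", "chr", strand, [(0, 100)], utr3=utr3)


class TestClustering:
    def test_single_cluster_with_modal_anchor(self):
        ends = [100, 100, 101, 103]
        reads = [_read("g.t1", e) for e in ends]
        (c,) = cluster_read_ends(reads, [_model()])
        assert c.anchor == 100
        assert c.span == (100, 104)
        assert c.total_support() == 4

    def test_far_apart_ends_split(self):
        reads = [_read("g.t1", e) for e in [100, 100, 100, 150, 150, 150]]
        clusters = cluster_read_ends(reads, [_model()])
        assert [c.anchor for c in clusters] == [100, 150]

    def test_min_support_discards_weak_clusters(self):
        reads = [_read("g.t1", e) for e in [100, 100, 100, 200, 200]]
        clusters = cluster_read_ends(reads, [_model()])
        assert len(clusters) == 1

    def test_empty_input(self):
        assert cluster_read_ends([], [_model()]) == []

    @pytest.mark.parametrize("strand,expected", [("+", 101), ("-", 100)])
    def test_modal_tie_breaks_three_prime_most(self, strand, expected):
        reads = [_read("g.t1", e) for e in [100, 100, 101, 101]]
        (c,) = cluster_read_ends(reads, [_model(strand=strand)])
        assert c.anchor == expected

    def test_input_order_irrelevant(self):
        rng = np.random.default_rng(0)
        ends = list(rng.integers(0, 500, size=200))
        reads = [_read("g.t1", int(e)) for e in ends]
        a = cluster_read_ends(reads, [_model()])
        b = cluster_read_ends(list(reversed(reads)), [_model()])
        assert [(c.anchor, c.span, c.total_support()) for c in a] == [
            (c.anchor, c.span, c.total_support()) for c in b
        ]


class TestFeatureAssignment:
    MODELS = [
        TranscriptModel(
            "g", "g.t1", "chr", "+", [(0, 50), (100, 200)], utr3=(150, 200)
        )
    ]

    def _cluster(self, anchor):
        return PasCluster("p", "g", "chr", "+", anchor, (anchor, anchor + 1), {})

    @pytest.mark.parametrize(
        "anchor,feature",
        [
            (160, "three_prime_utr"),
            (120, "exon"),
            (75, "intron"),
            (10000, "unassigned"),
        ],
    )
    def test_precedence(self, anchor, feature):
        assert assign_feature(self._cluster(anchor), self.MODELS) == feature

    def test_within_transcript_when_no_utr_annotated(self):
        models = [TranscriptModel("g", "g.t1", "chr", "+", [(0, 200)])]
        assert assign_feature(self._cluster(100), models) == "within_transcript"


class TestFisher:
    def test_hand_enumerated_example(self):
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(34 / 70)

    def test_balanced_table(self):
        assert fisher_exact([[2, 2], [2, 2]]) == 1.0

    def test_zero_margin_degenerate(self):
        assert fisher_exact([[0, 0], [3, 4]]) == 1.0

    def test_symmetry_under_row_and_column_swap(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            p1 = fisher_exact([[a, b], [c, d]])
            p2 = fisher_exact([[d, c], [b, a]])
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_matches_enumeration_small_margins(self):
        for a, b, c, d in itertools.product(range(7), repeat=4):
            if max(a + b, c + d, a + c, b + d) > 6:
                continue
            table = [[a, b], [c, d]]
            assert fisher_exact(table) == pytest.approx(
                fisher_enumeration(table), rel=1e-7, abs=1e-12
            )


def _two_pas_reads(n_prox_ctrl, n_dist_ctrl, n_prox_stim, n_dist_stim):
    reads = []
    for cond, sample, np_, nd in [
        ("control", "ctrl_1", n_prox_ctrl, n_dist_ctrl),
        ("stimulated", "stim_1", n_prox_stim, n_dist_stim),
    ]:
        reads += [_read("g.t1", 100, sample, cond) for _ in range(np_)]
        reads += [_read("g.t1", 400, sample, cond) for _ in range(nd)]
    return reads


class TestUsage:
    MODEL = [TranscriptModel("g", "g.t1", "chr", "+", [(0, 500)], utr3=(50, 500))]

    def test_balanced_usage_not_differential(self):
        reads = _two_pas_reads(50, 50, 50, 50)
        clusters = cluster_read_ends(reads, self.MODEL)
        results = differential_pas_usage(clusters)
        assert all(r.p_raw == 1.0 and not r.differential for r in results)

    def test_planted_shift_detected_with_correct_rank(self):
        reads = _two_pas_reads(60, 140, 120, 80)
        clusters = cluster_read_ends(reads, self.MODEL)
        results = differential_pas_usage(clusters)
        prox = next(r for r in results if r.rank == "proximal")
        dist = next(r for r in results if r.rank == "distal")
        assert prox.pas_id == "g:100" and dist.pas_id == "g:400"
        assert prox.differential and prox.log2_shift > 0

    def test_margins_conserve_gene_totals(self):
        reads = _two_pas_reads(10, 20, 30, 40)
        clusters = cluster_read_ends(reads, self.MODEL)
        for r in differential_pas_usage(clusters):
            assert r.table[0][0] + r.table[0][1] == 30
            assert r.table[1][0] + r.table[1][1] == 70

    def test_single_pas_gene_skipped_with_warning(self):
        reads = [_read("g.t1", 100) for _ in range(5)]
        clusters = cluster_read_ends(reads, self.MODEL)
        with pytest.warns(UserWarning, match="single-PAS"):
            assert differential_pas_usage(clusters) == []


class TestProximalDistalShift:
    def _clusters(self, prox_support, dist_support, strand="+"):
        anchors = (100, 400) if strand == "+" else (400, 100)
        return [
            PasCluster("p", "g", "chr", strand, anchors[0], (0, 1), prox_support),
            PasCluster("d", "g", "chr", strand, anchors[1], (0, 1), dist_support),
        ]

    def test_equal_support_zero_shift(self):
        sup = {("a", "control"): 40, ("b", "stimulated"): 40}
        shifts = proximal_distal_shift(self._clusters(sup, dict(sup)))
        assert shifts["g"] == (0.0, 0.0)

    def test_doubled_proximal(self):
        prox = {("a", "control"): 200, ("b", "stimulated"): 400}
        dist = {("a", "control"): 200, ("b", "stimulated"): 200}
        p, d = proximal_distal_shift(self._clusters(prox, dist))["g"]
        assert p == pytest.approx(1.0, abs=0.01)
        assert d == pytest.approx(0.0, abs=0.01)

    def test_antisymmetric_under_condition_swap(self):
        prox = {("a", "control"): 37, ("b", "stimulated"): 91}
        dist = {("a", "control"): 52, ("b", "stimulated"): 13}
        swapped_prox = {("a", "control"): 91, ("b", "stimulated"): 37}
        swapped_dist = {("a", "control"): 13, ("b", "stimulated"): 52}
        s1 = proximal_distal_shift(self._clusters(prox, dist))["g"]
        s2 = proximal_distal_shift(self._clusters(swapped_prox, swapped_dist))["g"]
        assert s1[0] == pytest.approx(-s2[0])
        assert s1[1] == pytest.approx(-s2[1])


class TestHexamer:
    def test_planted_signal_is_modal_at_minus_20(self, small_sim):
        _, (genome, models), reads, _ = small_sim
        fit = PasUsage(reads, models).fit()
        profile = hexamer_enrichment(fit.clusters, genome)
        assert profile.mode_offset() == -20

    def test_sequence_without_signal_gives_zero_counts(self):
        genome = GenomeSeqs({"chr": "GC" * 200})
        cluster = PasCluster("p", "g", "chr", "+", 300, (300, 301), {})
        profile = hexamer_enrichment([cluster], genome)
        assert profile.offsets == {}

    def test_minus_strand_profile_mirrors_plus_strand(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        seq = seq[:180] + "AATAAA" + seq[186:]
        plus = PasCluster("p", "g", "chr", "+", 200, (200, 201), {})
        minus = PasCluster("p", "g", "chr", "-", 99, (99, 100), {})
        prof_plus = hexamer_enrichment([plus], GenomeSeqs({"chr": seq}))
        prof_minus = hexamer_enrichment([minus], GenomeSeqs({"chr": revcomp(seq)}))
        assert prof_plus.offsets == prof_minus.offsets

    def test_truncated_window_flagged(self):
        genome = GenomeSeqs({"chr": "ACGT" * 5})
        cluster = PasCluster("p", "g", "chr", "+", 10, (10, 11), {})
        profile = hexamer_enrichment([cluster], genome)
        assert profile.truncated == 1
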