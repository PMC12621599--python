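import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailscape.io import ReadRecord
from tailscape.tailstats import (
    DifferentialAdenylation,
    TailTestConfig,
    bh_adjust,
    classify_effect_size,
    cohens_d,
    composition_summary,
    differential_adenylation,
    ranksum_test,
)


def enumerate_ranksum_p(x, y):
    """Exact two-sided p by enumerating all rank assignments (oracle)."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    nx = len(x)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    mean_u = nx * len(y) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        # combo indexes positions of the sorted ranks 1..N
        u = sum(i + 1 for i in combo) - nx * (nx + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
    return count / total


def bh_definitional(p):
    """adjusted_i = min over j with p_(j) >= p_(i) of min(1, p_(j)*m/rank_j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, min(1.0, p[i] * m / rank_from_top))
        adjusted[i] = running
    return adjusted


class TestRanksum:
    def test_fully_separated_groups(self):
        U, p = ranksum_test([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(2 / 20)  # 2 of C(6,3) assignments as extreme

    def test_identical_groups_give_p_one(self):
        _, p = ranksum_test([5, 5, 5, 5], [5, 5, 5, 5])
        assert p == 1.0

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 15))
            y = rng.normal(size=rng.integers(2, 15))
            assert ranksum_test(x, y)[1] == pytest.approx(ranksum_test(y, x)[1])

    @pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 2), (5, 6), (6, 6)])
    def test_exact_path_matches_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        for _ in range(5):
            vals = rng.permutation(rng.normal(size=nx + ny))
            x, y = vals[:nx], vals[nx:]
            _, p = ranksum_test(x, y)
            assert p == pytest.approx(enumerate_ranksum_p(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ranksum_test([], [1.0])


class TestBH:
    def test_all_equal_after_adjustment(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_definitional_computation(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_definitional(p), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(2)
        p = rng.random(100)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_properties_hold_on_arbitrary_vectors(self, p):
        adj = bh_adjust(p)
        assert ((adj >= np.asarray(p) - 1e-15) & (adj <= 1.0)).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()  # monotone on sorted p


class TestCohensD:
    def test_hand_computed_example(self):
        # pooled SD = sqrt(2), mean difference 2
        assert cohens_d([9, 11], [11, 13]) == pytest.approx(2 / math.sqrt(2))

    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=10), rng.normal(1, 1, size=12)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    def test_degenerate_sd_returns_zero(self):
        assert cohens_d([5, 5], [7, 7]) == 0.0


class TestEffectBins:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (0.19, "negligible"),
            (0.2, "small"),
            (0.49, "small"),
            (0.5, "medium"),
            (0.79, "medium"),
            (0.8, "large"),
            (-0.9, "large"),
            (-0.19, "negligible"),
        ],
    )
    def test_boundaries_inclusive_below(self, d, expected):
        assert classify_effect_size(d) == expected

    def test_monotone_in_absolute_d(self):
        order = {"negligible": 0, "small": 1, "medium": 2, "large": 3}
        grid = np.linspace(0, 2, 201)
        classes = [order[classify_effect_size(d)] for d in grid]
        assert classes == sorted(classes)


def _reads(tid, condition, lengths, qc="PASS"):
    return [
        ReadRecord(
            read_id=f"{tid}:{condition}:{i}",
            transcript_id=tid,
            sample_id=f"{condition[:4]}_1",
            condition=condition,
            tail_length=int(v),
            tail_seq="",
            end_pos=0,
            qc_tag=qc,
        )
        for i, v in enumerate(lengths)
    ]


class TestDifferentialAdenylation:
    def test_min_reads_filter_excludes_nine_read_transcripts(self):
        reads = _reads("t9", "control", range(100, 109)) + _reads(
            "t9", "stimulated", range(150, 165)
        )
        reads += _reads("t10", "control", range(100, 110)) + _reads(
            "t10", "stimulated", range(150, 160)
        )
        results = differential_adenylation(reads)
        assert [r.transcript_id for r in results] == ["t10"]

    def test_dual_rule_small_delta_not_significant(self):
        # clearly shifted distribution but median difference of only 4 nt
        ctrl = list(range(100, 110)) * 30
        stim = [v + 4 for v in ctrl]
        reads = _reads("t", "control", ctrl) + _reads("t", "stimulated", stim)
        (r,) = differential_adenylation(reads)
        assert r.p_adj < 0.05 and r.delta_median == 4
        assert not r.significant

    def test_fail_reads_excluded(self):
        reads = _reads("t", "control", range(100, 115)) + _reads(
            "t", "stimulated", range(100, 115)
        )
        reads += _reads("t", "stimulated", [500] * 50, qc="FAIL")
        (r,) = differential_adenylation(reads)
        assert r.n_stimulated == 15

    def test_fields_are_consistent(self):
        ctrl = list(range(80, 100))
        stim = list(range(140, 160))
        reads = _reads("t", "control", ctrl) + _reads("t", "stimulated", stim)
        (r,) = differential_adenylation(reads)
        assert r.delta_median == np.median(stim) - np.median(ctrl)
        assert r.delta_mean == pytest.approx(np.mean(stim) - np.mean(ctrl))
        assert r.p_adj >= r.p_raw
        assert r.significant
        assert r.effect_class == classify_effect_size(r.cohens_d)

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning):
            assert differential_adenylation(_reads("t", "control", [1, 2])) == []

    def test_model_surface(self, small_sim):
        _, _, reads, _ = small_sim
        res = DifferentialAdenylation(reads, TailTestConfig()).fit()
        frame = res.frame()
        assert {"transcript_id", "p_adj", "cohens_d"} <= set(frame.columns)
        assert "transcripts tested" in res.summary()
        for r in res.significant:
            assert r.p_adj < 0.05 and abs(r.delta_median) > 5


class TestComposition:
    def test_blank_and_decorated_tails(self):
        reads = [
            ReadRecord("r1", "t", "s", "control", 4, "AAAA", 0),
            ReadRecord("r2", "t", "s", "control", 6, "AAGACA", 0),
        ]
        comp = composition_summary(reads)
        assert comp.n_reads == 2 and comp.n_decorated == 1
        assert comp.frac_decorated == 0.5
        assert comp.nona_per_tail == {0: 1, 2: 1}
        assert comp.base_counts == {"G": 1, "C": 1, "U": 0}

    def test_missing_tail_seq_audited(self):
        reads = [ReadRecord("r1", "t", "s", "control", 10, "", 0)]
        comp = composition_summary(reads)
        assert comp.n_reads == 0 and comp.n_missing_seq == 1

    def test_per_transcript_grouping(self):
        reads = [
            ReadRecord("r1", "t1", "s", "control", 2, "AG", 0),
            ReadRecord("r2", "t2", "s", "control", 2, "AA", 0),
        ]
        by_tid = composition_summary(reads, group_by="transcript")
        assert by_tid["t1"].n_decorated == 1
        assert by_tid["t2"].n_decorated == 0

    def test_decoration_rate_monotone_on_simulation(self, default_sim):
        _, _, reads, truth = default_sim
        plain = [
            r
            for r in reads
            if not truth.genes[r.transcript_id.split(".")[0]]["is_semitemplated"]
        ]
        comp = composition_summary(plain)
        assert comp.rate_by_length_bin["[100,120)"] > comp.rate_by_length_bin["[20,40)"]
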