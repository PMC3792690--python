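import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirpkit.io import GenomicInterval, PeakSet
from chirpkit.peaks import (
    Thresholds,
    filter_peaks,
    flag_control_proximity,
    pairwise_window_overlap,
    replicate_consensus,
)
from oracle_utils import (
    brute_min_gap_to_set,
    brute_replicate,
    mkpeak,
    random_peakset,
)


def ps(label, *peaks, role="other"):
    return PeakSet(label, role, list(peaks))


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------


def test_thresholds_defaults_match_published_values():
    t = Thresholds()
    assert t.max_fdr == 0.05
    assert t.min_fold == 20.0
    assert t.replication_window == 10_000
    assert t.control_window == 10_000
    assert t.gene_max_dist == 2_000
    assert t.de_alpha == 0.05


@pytest.mark.parametrize("kwargs", [
    {"max_fdr": 0.0}, {"max_fdr": 1.5}, {"de_alpha": -0.1},
    {"replication_window": -1}, {"min_fold": -2.0},
])
def test_thresholds_validation(kwargs):
    with pytest.raises(ValueError):
        Thresholds(**kwargs)


# ---------------------------------------------------------------------------
# filter_peaks
# ---------------------------------------------------------------------------


def test_filter_keeps_and_drops():
    t = Thresholds()
    keep = mkpeak("keep", "chr1", 0, 100, fold=25, fdr=0.01)
    low_fold = mkpeak("lf", "chr1", 200, 300, fold=15, fdr=0.01)
    high_fdr = mkpeak("hf", "chr1", 400, 500, fold=25, fdr=0.06)
    out = filter_peaks(ps("s", keep, low_fold, high_fdr), t)
    assert [p.id for p in out] == ["keep"]


def test_filter_boundary_strict():
    t = Thresholds()
    exact = mkpeak("x", "chr1", 0, 100, fold=20.0, fdr=0.05)
    assert len(filter_peaks(ps("s", exact), t)) == 0


def test_filter_absent_values_fail():
    t = Thresholds()
    no_fdr = mkpeak("a", "chr1", 0, 100, fold=25, fdr=None)
    no_fold = mkpeak("b", "chr1", 200, 300, fold=None, fdr=0.01)
    assert len(filter_peaks(ps("s", no_fdr, no_fold), t)) == 0


def test_filter_empty():
    assert len(filter_peaks(ps("s"), Thresholds())) == 0


def test_filter_preserves_order_and_subset():
    t = Thresholds()
    peaks = [mkpeak(f"p{i}", "chr1", i * 1000, i * 1000 + 100,
                    fold=10 + 5 * i, fdr=0.01) for i in range(8)]
    out = filter_peaks(ps("s", *peaks), t)
    ids = [p.id for p in out]
    assert ids == [p.id for p in peaks if p.fold_enrichment > 20]
    assert ids == sorted(ids, key=lambda i: int(i[1:]))


def test_filter_idempotent():
    t = Thresholds()
    rng = np.random.default_rng(0)
    sets = random_peakset(rng, "s", 100)
    once = filter_peaks(sets, t)
    twice = filter_peaks(once, t)
    assert [p.id for p in once] == [p.id for p in twice]


# ---------------------------------------------------------------------------
# replicate_consensus
# ---------------------------------------------------------------------------


def test_replicated_within_window():
    a = ps("A", mkpeak("a1", "chr1", 5000, 5500))
    b = ps("B", mkpeak("b1", "chr1", 14000, 14400))
    res = replicate_consensus(a, b, 10_000)
    assert res.n_replicated == 1
    assert res.consensus[0].min_partner_gap == 8500
    assert res.consensus[0].support == {"A": ("a1",), "B": ("b1",)}


def test_not_replicated_outside_window():
    a = ps("A", mkpeak("a1", "chr1", 5000, 5500))
    b = ps("B", mkpeak("b1", "chr1", 14000, 14400))
    assert replicate_consensus(a, b, 8_000).n_replicated == 0


def test_identical_sets_all_replicated():
    peaks = [mkpeak(f"p{i}", "chr1", i * 50_000, i * 50_000 + 500)
             for i in range(5)]
    a = ps("A", *peaks)
    b = ps("B", *peaks)
    res = replicate_consensus(a, b, 0)
    assert res.n_replicated == 5
    assert all(c.min_partner_gap == 0 for c in res.consensus)


def test_cross_chromosome_never_matches():
    a = ps("A", mkpeak("a1", "chr1", 0, 100))
    b = ps("B", mkpeak("b1", "chr2", 0, 100))
    assert replicate_consensus(a, b, 10**9).n_replicated == 0


def test_negative_window_error():
    with pytest.raises(ValueError):
        replicate_consensus(ps("A"), ps("B"), -1)


def test_representative_is_anchor_interval():
    a = ps("A", mkpeak("a1", "chr1", 5000, 5500))
    b = ps("B", mkpeak("b1", "chr1", 6000, 9000))
    res = replicate_consensus(a, b, 10_000)
    assert res.consensus[0].interval == GenomicInterval("chr1", 5000, 5500)


def test_representative_union_mode():
    a = ps("A", mkpeak("a1", "chr1", 5000, 5500))
    b = ps("B", mkpeak("b1", "chr1", 6000, 9000))
    res = replicate_consensus(a, b, 10_000, representative="union")
    assert res.consensus[0].interval == GenomicInterval("chr1", 5000, 9000)


def test_anchor_asymmetry():
    """Two A peaks matching one B peak give two consensus entries; swapped,
    only one."""
    a = ps("A", mkpeak("a1", "chr1", 1000, 1100),
           mkpeak("a2", "chr1", 3000, 3100))
    b = ps("B", mkpeak("b1", "chr1", 2000, 2100))
    assert replicate_consensus(a, b, 5_000).n_replicated == 2
    assert replicate_consensus(b, a, 5_000).n_replicated == 1


def test_summit_mode():
    # intervals overlap (gap 0) but summits 3000 apart
    a = ps("A", mkpeak("a1", "chr1", 1000, 5000, summit=100))
    b = ps("B", mkpeak("b1", "chr1", 1000, 5000, summit=3100))
    assert replicate_consensus(a, b, 10_000, mode="summit").n_replicated == 1
    assert replicate_consensus(a, b, 2_000, mode="summit").n_replicated == 0
    assert replicate_consensus(a, b, 2_000, mode="gap").n_replicated == 1


@pytest.mark.parametrize("mode", ["gap", "summit"])
def test_consensus_matches_bruteforce(mode):
    rng = np.random.default_rng(42)
    for trial in range(30):
        n_a = int(rng.integers(0, 200))
        n_b = int(rng.integers(0, 200))
        a = random_peakset(rng, "A", n_a)
        b = random_peakset(rng, "B", n_b)
        window = int(rng.integers(0, 20_000))
        res = replicate_consensus(a, b, window, mode=mode)
        expect = brute_replicate(a, b, window, mode=mode)
        got = {
            c.id: (sorted(c.support["B"]), c.min_partner_gap)
            for c in res.consensus
        }
        assert got == expect


def test_conservation_invariant():
    rng = np.random.default_rng(3)
    a = random_peakset(rng, "A", 150)
    b = random_peakset(rng, "B", 150)
    res = replicate_consensus(a, b, 5_000)
    matched = {c.id for c in res.consensus}
    unmatched = [p for p in a if p.id not in matched]
    assert res.n_replicated + len(unmatched) == res.n_repA_in == len(a)


@given(st.integers(0, 30_000), st.integers(0, 30_000), st.integers(0, 999))
@settings(max_examples=40, deadline=None)
def test_window_monotonicity(w1, w2, seed):
    w_small, w_big = min(w1, w2), max(w1, w2)
    rng = np.random.default_rng(seed)
    a = random_peakset(rng, "A", 40)
    b = random_peakset(rng, "B", 40)
    small = {c.id for c in replicate_consensus(a, b, w_small).consensus}
    big = {c.id for c in replicate_consensus(a, b, w_big).consensus}
    assert small <= big


# ---------------------------------------------------------------------------
# flag_control_proximity
# ---------------------------------------------------------------------------


def _consensus_of(*peaks):
    a = ps("A", *peaks)
    b = ps("B", *[mkpeak(p.id + "_b", p.interval.chrom, p.interval.start,
                         p.interval.end) for p in peaks])
    return replicate_consensus(a, b, 0)


def test_control_far_not_flagged():
    res = _consensus_of(mkpeak("c1", "chr1", 5000, 5500))
    controls = [ps("ctrl", mkpeak("k1", "chr1", 20_000, 20_100))]
    out = flag_control_proximity(res, controls, 10_000)
    c = out.consensus[0]
    assert not c.control_proximal
    assert c.nearest_control_gap == 14_500
    assert out.n_controls_in_window == 0


def test_control_overlapping_flagged():
    res = _consensus_of(mkpeak("c1", "chr1", 5000, 5500))
    controls = [ps("ctrl", mkpeak("k1", "chr1", 5100, 5200))]
    out = flag_control_proximity(res, controls, 10_000)
    assert out.consensus[0].control_proximal
    assert out.consensus[0].nearest_control_gap == 0
    assert out.n_controls_in_window == 1


def test_control_other_chromosome():
    res = _consensus_of(mkpeak("c1", "chr1", 5000, 5500))
    controls = [ps("ctrl", mkpeak("k1", "chr2", 5000, 5500))]
    out = flag_control_proximity(res, controls, 10_000)
    assert out.consensus[0].nearest_control_gap == math.inf
    assert not out.consensus[0].control_proximal


def test_controls_pooled_across_sets():
    res = _consensus_of(mkpeak("c1", "chr1", 5000, 5500),
                        mkpeak("c2", "chr2", 5000, 5500))
    controls = [ps("ctrl1", mkpeak("k1", "chr1", 6000, 6100)),
                ps("ctrl2", mkpeak("k2", "chr2", 100_000, 100_100))]
    out = flag_control_proximity(res, controls, 10_000)
    flags = {c.id: c.control_proximal for c in out.consensus}
    assert flags == {"c1": True, "c2": False}
    assert out.n_control_proximal == 1
    assert [c.id for c in out.specific] == ["c2"]


def test_specific_count_identity():
    rng = np.random.default_rng(5)
    a = random_peakset(rng, "A", 120)
    b = random_peakset(rng, "B", 120)
    ctrl = random_peakset(rng, "C", 60)
    res = flag_control_proximity(
        replicate_consensus(a, b, 5_000), [ctrl], 5_000
    )
    assert len(res.specific) == res.n_replicated - res.n_control_proximal


def test_control_gap_matches_bruteforce():
    rng = np.random.default_rng(9)
    for _ in range(30):
        a = random_peakset(rng, "A", int(rng.integers(1, 150)))
        b = random_peakset(rng, "B", int(rng.integers(1, 150)))
        ctrl = random_peakset(rng, "C", int(rng.integers(1, 100)))
        window = int(rng.integers(0, 15_000))
        res = flag_control_proximity(
            replicate_consensus(a, b, window), [ctrl], window
        )
        for c in res.consensus:
            expect = brute_min_gap_to_set(c.interval, ctrl)
            assert c.nearest_control_gap == expect
            assert c.control_proximal == (expect <= window)
        expect_hits = sum(
            1 for p in ctrl
            if any(
                brute_min_gap_to_set(p.interval, [q]) <= window
                for q in res.consensus
            )
        )
        assert res.n_controls_in_window == expect_hits


def test_control_empty_error():
    res = _consensus_of(mkpeak("c1", "chr1", 5000, 5500))
    with pytest.raises(ValueError):
        flag_control_proximity(res, [], 10_000)


def test_control_negative_window_error():
    res = _consensus_of(mkpeak("c1", "chr1", 5000, 5500))
    with pytest.raises(ValueError):
        flag_control_proximity(res, [ps("c")], -5)


# ---------------------------------------------------------------------------
# pairwise_window_overlap
# ---------------------------------------------------------------------------


def test_pairwise_disjoint_sets():
    a = ps("A", mkpeak("a1", "chr1", 0, 100))
    b = ps("B", mkpeak("b1", "chr1", 500_000, 500_100))
    m = pairwise_window_overlap([a, b], 10_000)
    assert m.loc["A", "B"] == 0
    assert m.loc["B", "A"] == 0
    assert m.loc["A", "A"] == 1
    assert m.loc["B", "B"] == 1


def test_pairwise_identical_sets():
    peaks = [mkpeak(f"p{i}", "chr1", i * 50_000, i * 50_000 + 100)
             for i in range(4)]
    a = ps("A", *peaks)
    b = PeakSet("B", "other", list(peaks))
    m = pairwise_window_overlap([a, b], 1_000)
    assert (m.values == 1).all()


def test_pairwise_quarter_fraction():
    a_peaks = [mkpeak(f"a{i}", "chr1", i * 100_000, i * 100_000 + 100)
               for i in range(4)]
    b = ps("B", mkpeak("b1", "chr1", 1_000, 1_100))  # near a0 only
    m = pairwise_window_overlap([ps("A", *a_peaks), b], 10_000)
    assert m.loc["A", "B"] == 0.25
    assert m.loc["B", "A"] == 1.0


def test_pairwise_empty_set_row_undefined():
    a = ps("A", mkpeak("a1", "chr1", 0, 100))
    empty = ps("E")
    m = pairwise_window_overlap([a, empty], 1_000)
    assert m.loc["E"].isna().all()
    assert m.loc["A", "A"] == 1


def test_pairwise_needs_two_sets():
    with pytest.raises(ValueError):
        pairwise_window_overlap([ps("A")], 1_000)
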