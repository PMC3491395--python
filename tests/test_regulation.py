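import numpy as np
import pytest

from psidr.datamodel import GenomicInterval, Peak, PseudogeneRecord
from psidr.regulation import (
    UpstreamWindow,
    call_pol2_active,
    call_promoter_active,
    count_tfbs,
    derive_pol2_thresholds,
    filter_near_coding_tss,
    fisher_enrichment,
    rank_sum_test,
    upstream_window,
)
from psidr.simulate import simulate_null_pol2_peaks


def rec(start, end, strand="+", chrom="chr1", name="p"):
    return PseudogeneRecord(name, GenomicInterval(chrom, start, end, strand))


def peak(start, end, factor="Pol2", signal=1.0, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), factor, signal)


# ------------------------------------------------------------- windows


def test_upstream_window_plus_strand():
    w = upstream_window(rec(5000, 8000, "+"))
    assert (w.region.start, w.region.end) == (3000, 5000)


def test_upstream_window_minus_strand():
    w = upstream_window(rec(5000, 8000, "-"))
    assert (w.region.start, w.region.end) == (8000, 10000)


def test_upstream_window_clipped_at_chromosome_start():
    w = upstream_window(rec(500, 2000, "+"))
    assert (w.region.start, w.region.end) == (0, 500)


def test_upstream_window_clipped_at_chromosome_end():
    w = upstream_window(rec(5000, 9500, "-"), chrom_length=10_000)
    assert (w.region.start, w.region.end) == (9500, 10_000)


# ------------------------------------------------------------- exclusion


def test_coding_tss_exclusion_boundary():
    tss = [("chr1", 10_000)]
    near = rec(13_999, 15_000, "+", name="near")  # 3,999 bp away
    exact = rec(14_000, 15_000, "+", name="exact")  # exactly 4,000 bp
    kept, excluded = filter_near_coding_tss([near, exact], tss)
    assert [r.id for r in excluded] == ["near"]
    assert [r.id for r in kept] == ["exact"]


def test_no_coding_gene_on_chromosome_keeps_all():
    kept, excluded = filter_near_coding_tss([rec(100, 900, "+")], [("chr9", 50)])
    assert len(kept) == 1 and not excluded


def test_exclusion_partitions_input(corpus, decoration, surveyed_truth):
    excluded_truth = set(surveyed_truth[surveyed_truth.near_coding].index)
    coding_tss = [(g.locus.chrom, g.five_prime_end) for g in corpus.genes]
    kept, excluded = filter_near_coding_tss(decoration.surveyed, coding_tss)
    assert {r.id for r in excluded} == excluded_truth
    assert len(kept) + len(excluded) == len(decoration.surveyed)
    assert not ({r.id for r in kept} & {r.id for r in excluded})


# ------------------------------------------------------------------ TFBS


def test_majority_rule_counts_75_percent_peak():
    window = UpstreamWindow("p", GenomicInterval("chr1", 1000, 3000))
    n, factors = count_tfbs([peak(950, 1150, "Myc")], window)
    assert n == 1 and factors == {"Myc"}


def test_exactly_half_overlap_does_not_count():
    window = UpstreamWindow("p", GenomicInterval("chr1", 1000, 3000))
    n, _ = count_tfbs([peak(900, 1100, "Myc")], window)  # 100 of 200 inside
    assert n == 0


def _brute_majority(p, w):
    ov = 0
    if p.region.chrom == w.chrom:
        ov = max(0, min(p.region.end, w.end) - max(p.region.start, w.start))
    return ov > p.width / 2


def test_count_tfbs_matches_brute_force_on_random_peaks():
    rng = np.random.default_rng(21)
    window = UpstreamWindow("p", GenomicInterval("chr1", 10_000, 12_000))
    peaks = []
    for _ in range(1000):
        s = int(rng.integers(8_000, 13_000))
        w = int(rng.integers(50, 900))
        chrom = "chr1" if rng.random() < 0.9 else "chr2"
        peaks.append(peak(s, s + w, str(rng.choice(["A", "B", "C"])), chrom=chrom))
    n, factors = count_tfbs(peaks, window)
    expected = [p for p in peaks if _brute_majority(p, window.region)]
    assert n == len(expected)
    assert factors == {p.factor for p in expected}


def test_count_tfbs_monotone_under_adding_peaks():
    window = UpstreamWindow("p", GenomicInterval("chr1", 1000, 3000))
    inside = peak(1500, 1700, "Myc")
    n1, _ = count_tfbs([inside], window)
    n2, _ = count_tfbs([inside, peak(1800, 2000, "Jun")], window)
    assert n2 >= n1


# ------------------------------------------------------------------ Pol2


WINDOW = UpstreamWindow("p", GenomicInterval("chr1", 1000, 3000))


def test_pol2_wide_strong_peak_is_active():
    active, crit = call_pol2_active([peak(1200, 1800, signal=3.0)], [], WINDOW)
    assert active and crit == 12


def test_pol2_wide_weak_peak_is_inactive():
    active, crit = call_pol2_active([peak(1200, 1800, signal=1.0)], [], WINDOW)
    assert not active and crit == 0


def test_pol2_criteria_must_hold_for_same_peak():
    peaks = [peak(1200, 1800, signal=1.0), peak(1500, 1700, signal=5.0)]
    active, _ = call_pol2_active(peaks, [], WINDOW)
    assert not active  # wide peak weak, strong peak narrow


def test_pol2_cofactor_rescues_weak_signal():
    cof = [peak(1500, 1700, "Taf1", 1.0)]
    active, crit = call_pol2_active([peak(1200, 1350, signal=1.0)], cof, WINDOW)
    assert active and crit == 3


def test_non_cofactor_peak_does_not_rescue():
    active, _ = call_pol2_active([], [peak(1500, 1700, "Myc", 9.0)], WINDOW)
    assert not active


def test_boundary_thresholds_are_strict():
    active, _ = call_pol2_active([peak(1200, 1719, signal=3.0)], [], WINDOW)  # width 519
    assert not active
    active, _ = call_pol2_active([peak(1200, 1720, signal=2.38)], [], WINDOW)  # signal 2.38
    assert not active


# ---------------------------------------------------- derived thresholds


def test_derive_thresholds_percentile():
    peaks = [peak(0, w, signal=w / 10) for w in range(1, 101)]
    wt, st_ = derive_pol2_thresholds(peaks)
    assert wt == pytest.approx(np.percentile(np.arange(1, 101), 95))
    assert st_ == pytest.approx(np.percentile(np.arange(1, 101) / 10, 95))


def test_derive_thresholds_all_equal():
    wt, st_ = derive_pol2_thresholds([peak(0, 200, signal=1.0)] * 30)
    assert wt == 200 and st_ == 1.0


def test_derive_thresholds_monotone_in_percentile():
    peaks = simulate_null_pol2_peaks(500, np.random.default_rng(3))
    w90, s90 = derive_pol2_thresholds(peaks, 90)
    w99, s99 = derive_pol2_thresholds(peaks, 99)
    assert w90 <= w99 and s90 <= s99


def test_derive_thresholds_requires_enough_peaks():
    with pytest.raises(ValueError):
        derive_pol2_thresholds([peak(0, 100)] * 5)


def test_percentile_rule_flags_five_percent_of_null_peaks():
    rng = np.random.default_rng(42)
    peaks = simulate_null_pol2_peaks(2000, rng)
    wt, st_ = derive_pol2_thresholds(peaks)
    flagged = sum(1 for p in peaks if p.width > wt and p.signal > st_)
    # binomial(2000, 0.05): mean 100, sd ~9.7
    assert abs(flagged - 100) <= 30


# -------------------------------------------------------------- promoter


def test_promoter_one_bp_overlap_is_active():
    assert call_promoter_active([GenomicInterval("chr1", 999, 1001)], WINDOW)
    assert not call_promoter_active([GenomicInterval("chr1", 11_000, 12_000)], WINDOW)
    assert not call_promoter_active([GenomicInterval("chr2", 1500, 1700)], WINDOW)


def test_promoter_recovery_on_corpus(decoration, surveyed_truth):
    for ctx, records in decoration.records.items():
        called = {r.pseudogene_id for r in records if r.active_promoter}
        planted = set(surveyed_truth[surveyed_truth[f"promoter_{ctx}"]].index)
        assert called == planted


def test_pol2_recovery_on_corpus(decoration, surveyed_truth):
    for ctx, records in decoration.records.items():
        called = {r.pseudogene_id for r in records if r.active_pol2}
        planted = set(surveyed_truth[surveyed_truth[f"pol2_{ctx}"]].index)
        assert called == planted


# ------------------------------------------------------------ enrichment


def _hypergeom_tail(a, b, c, d):
    """P(X >= a) for the 2x2 table margins, by direct enumeration."""
    from math import comb

    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = comb(n, col1)
    return sum(
        comb(row1, x) * comb(n - row1, col1 - x)
        for x in range(a, min(row1, col1) + 1)
    ) / denom


def test_fisher_matches_hypergeometric_enumeration():
    assert fisher_enrichment(6, 10, 9, 90) == pytest.approx(
        _hypergeom_tail(6, 4, 9, 81), rel=1e-10
    )


def test_fisher_detects_planted_enrichment():
    # active rate 0.5 in transcribed (n=100) vs 0.05 in others (n=900)
    assert fisher_enrichment(50, 100, 45, 900) < 1e-6


def test_fisher_rejects_empty_group():
    with pytest.raises(ValueError):
        fisher_enrichment(0, 0, 1, 10)


def test_rank_sum_identical_groups():
    assert rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0, abs=0.05)


def test_rank_sum_detects_shift():
    rng = np.random.default_rng(31)
    a = rng.poisson(5, 200)
    b = rng.poisson(1, 200)
    assert rank_sum_test(a, b) < 1e-10
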