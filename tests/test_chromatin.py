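import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from psidr.chromatin import (
    aggregate_profile,
    call_active_chromatin,
    dnase_accessible,
    genome_label_fractions,
    label_frequencies,
)
from psidr.datamodel import (
    REPRESSIVE_LABELS,
    SEGMENTATION_LABELS,
    CoverageTrack,
    GenomicInterval,
    SegmentationTrack,
)
from psidr.simulate import evaluation_region


def _track(values, chrom="chr1"):
    return {chrom: CoverageTrack(chrom, np.asarray(values, dtype=float), "t")}


# ----------------------------------------------------------------- profiles


def test_constant_track_gives_flat_profile():
    tracks = _track(np.full(20_000, 2.5))
    prof = aggregate_profile(tracks, [("chr1", 10_000, "+")], half_window=4000, bin_size=50)
    assert prof.offsets.size == 160
    np.testing.assert_allclose(prof.mean_signal, 2.5)


def test_minus_strand_profile_mirrors_plus():
    values = np.zeros(20_000)
    values[9_000:10_000] = 1.0  # step upstream of a + strand anchor at 10k
    plus = aggregate_profile(_track(values), [("chr1", 10_000, "+")])
    mirrored = values[::-1].copy()
    minus = aggregate_profile(_track(mirrored), [("chr1", 20_000 - 10_000, "-")])
    np.testing.assert_allclose(plus.mean_signal, minus.mean_signal)


def test_profile_mean_is_linear_over_loci():
    rng = np.random.default_rng(6)
    values = rng.uniform(0, 3, size=40_000)
    tracks = _track(values)
    a = aggregate_profile(tracks, [("chr1", 10_000, "+")])
    b = aggregate_profile(tracks, [("chr1", 25_000, "+")])
    both = aggregate_profile(tracks, [("chr1", 10_000, "+"), ("chr1", 25_000, "+")])
    np.testing.assert_allclose(both.mean_signal, (a.mean_signal + b.mean_signal) / 2)


def test_profile_requires_anchors():
    with pytest.raises(ValueError):
        aggregate_profile(_track(np.zeros(100)), [])


def test_clipped_anchor_warns():
    with pytest.warns(UserWarning, match="clipped"):
        aggregate_profile(_track(np.ones(5000)), [("chr1", 1000, "+")])


# ------------------------------------------------------- label frequencies


def _uniform_track(length=10_000, chrom="chr1"):
    """Every label covers an equal share of the genome."""
    labels = sorted(SEGMENTATION_LABELS)
    seg = length // len(labels)
    segments = [
        (GenomicInterval(chrom, i * seg, (i + 1) * seg), lab)
        for i, lab in enumerate(labels)
    ]
    return SegmentationTrack(segments=segments)


def test_single_label_region_normalization():
    track = SegmentationTrack(
        segments=[
            (GenomicInterval("chr1", 0, 500), "TSS"),
            (GenomicInterval("chr1", 500, 1000), "LOW"),
        ]
    )
    fr = genome_label_fractions(track)
    assert fr["TSS"] == 0.5
    freqs = label_frequencies(track, GenomicInterval("chr1", 0, 500), fr)
    assert freqs["TSS"] == pytest.approx(2.0)
    assert freqs["LOW"] == 0.0


def test_uniform_genome_gives_unit_frequencies():
    track = _uniform_track()
    fr = genome_label_fractions(track)
    freqs = label_frequencies(track, GenomicInterval("chr1", 0, 10_000), fr)
    for lab in SEGMENTATION_LABELS:
        assert freqs[lab] == pytest.approx(1.0)


def test_label_frequencies_match_per_base_counting():
    rng = np.random.default_rng(8)
    labels = sorted(SEGMENTATION_LABELS)
    arr = rng.integers(0, len(labels), size=10_000)
    segments = []
    start = 0
    for i in range(1, 10_000):
        if arr[i] != arr[i - 1]:
            segments.append((GenomicInterval("chr1", start, i), labels[arr[start]]))
            start = i
    segments.append((GenomicInterval("chr1", start, 10_000), labels[arr[start]]))
    track = SegmentationTrack(segments=segments)
    fr = genome_label_fractions(track)
    region = GenomicInterval("chr1", 2_345, 7_123)
    freqs = label_frequencies(track, region, fr)
    window = arr[region.start : region.end]
    for i, lab in enumerate(labels):
        raw = (window == i).mean()
        genome = (arr == i).mean()
        expected = raw / genome if genome > 0 else 0.0
        assert freqs[lab] == pytest.approx(expected)


# ------------------------------------------------------------- classifier


def _freqs(**kw):
    freqs = {lab: 0.0 for lab in SEGMENTATION_LABELS}
    freqs.update(kw)
    return freqs


def test_criterion_1_tss_three_times_repressive():
    freqs = _freqs(TSS=0.30, CTCF=0.09, LOW=0.05)
    assert call_active_chromatin(freqs) == (True, 1)
    # just under the 3x bar
    freqs = _freqs(TSS=0.26, CTCF=0.09)
    assert call_active_chromatin(freqs) == (False, 0)


def test_criterion_2_gene_body_twice_repressive():
    freqs = _freqs(GS=0.20, GM=0.20, GE=0.20, CTCF=0.09)
    assert call_active_chromatin(freqs) == (True, 2)
    # all three gene-body labels must clear the bar
    freqs = _freqs(GS=0.20, GM=0.20, GE=0.10, CTCF=0.09)
    assert call_active_chromatin(freqs) == (False, 0)


def test_all_equal_frequencies_inactive():
    freqs = {lab: 0.7 for lab in SEGMENTATION_LABELS}
    assert call_active_chromatin(freqs) == (False, 0)


def test_criterion_1_takes_precedence():
    freqs = _freqs(TSS=1.0, GS=1.0, GM=1.0, GE=1.0, CTCF=0.01)
    assert call_active_chromatin(freqs) == (True, 1)


@settings(derandomize=True, max_examples=100)
@given(
    st.floats(min_value=1e-3, max_value=1e3),
    st.integers(min_value=0, max_value=2**32 - 1),
)
def test_classifier_scale_invariance(scale, seed):
    rng = np.random.default_rng(seed)
    freqs = {lab: float(rng.uniform(0, 1)) for lab in SEGMENTATION_LABELS}
    scaled = {lab: v * scale for lab, v in freqs.items()}
    assert call_active_chromatin(freqs) == call_active_chromatin(scaled)


def test_corpus_chromatin_recovery_with_criterion_attribution(corpus, surveyed_truth):
    from psidr.datamodel import Thresholds

    th = Thresholds()
    for ctx, seg in corpus.segmentation.items():
        fr = genome_label_fractions(seg)
        by_id = {r["id"]: r for _, r in surveyed_truth.reset_index().iterrows()}
        for rec in corpus.manual:
            row = by_id.get(rec.id)
            if row is None:
                continue
            freqs = label_frequencies(seg, evaluation_region(rec), fr)
            active, crit = call_active_chromatin(freqs, th.tss_ratio, th.genebody_ratio)
            assert active == bool(row["chromatin_active"])
            assert crit == int(row["chromatin_criterion"])


# ------------------------------------------------------------------ DNase


def test_dnase_accessibility_fold_rule():
    values = np.full(20_000, 1.0)
    values[9_000:11_000] += 8.0
    tracks = _track(values)
    assert dnase_accessible(tracks, ("chr1", 10_000), genome_mean=1.0)
    assert not dnase_accessible(tracks, ("chr1", 2_000), genome_mean=1.0)
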