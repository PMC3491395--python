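"""Chromatin activity: 5'-anchored signal profiles, segmentation label
frequencies, and the frequency-ratio active-chromatin classifier.

The classifier mirrors the segmentation behaviour of active genes: a locus
has active chromatin when either (1) its TSS-label frequency is at least
three times the frequency of every repressive label, or (2) all three
gene-body labels (GS, GM, GE) are at least twice every repressive label.
Frequencies are the fraction of the evaluation region covered by a label,
normalized by that label's genome-wide coverage fraction, so the calls are
invariant to how common a label is genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .datamodel import (
    GENE_BODY_LABELS,
    REPRESSIVE_LABELS,
    SEGMENTATION_LABELS,
    CoverageTrack,
    GenomicInterval,
    SegmentationTrack,
)

__all__ = [
    "SignalProfile",
    "aggregate_profile",
    "genome_label_fractions",
    "label_frequencies",
    "call_active_chromatin",
    "dnase_accessible",
]


@dataclass
class SignalProfile:
    """Mean signal in uniform bins around the 5' ends of a locus group."""

    offsets: np.ndarray
    mean_signal: np.ndarray
    n_loci: int
    group: str = ""


def aggregate_profile(
    tracks: dict[str, CoverageTrack],
    anchors: list[tuple[str, int, str]],
    half_window: int = 4000,
    bin_size: int = 50,
    group: str = "",
) -> SignalProfile:
    """Average signal in bins over +/-half_window around 5'-end anchors.

    ``anchors`` are (chrom, position, strand); minus-strand profiles are
    reversed so upstream is always to the left.  Anchors whose window runs
    off the chromosome are clipped (out-of-bounds bins excluded from the
    mean).
    """
    if not anchors:
        raise ValueError("no anchor positions supplied")
    n_bins = 2 * half_window // bin_size
    offsets = -half_window + bin_size * (np.arange(n_bins) + 0.5)
    total = np.zeros(n_bins)
    count = np.zeros(n_bins)
    clipped = 0
    for chrom, pos, strand in anchors:
        track = tracks.get(chrom)
        if track is None:
            continue
        values = np.asarray(track.values, dtype=float)
        lo, hi = pos - half_window, pos + half_window
        if lo < 0 or hi > values.size:
            clipped += 1
        for b in range(n_bins):
            s, e = lo + b * bin_size, lo + (b + 1) * bin_size
            s2, e2 = max(s, 0), min(e, values.size)
            if s2 >= e2:
                continue
            target = b if strand != "-" else n_bins - 1 - b
            total[target] += values[s2:e2].mean()
            count[target] += 1
    if clipped:
        warnings.warn(f"{clipped} anchor window(s) clipped at chromosome bounds")
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return SignalProfile(offsets=offsets, mean_signal=mean, n_loci=len(anchors), group=group)


def _label_bp_in(segments, region: GenomicInterval) -> dict[str, int]:
    bp: dict[str, int] = {}
    for iv, label in segments:
        if iv.chrom != region.chrom:
            continue
        ov = min(iv.end, region.end) - max(iv.start, region.start)
        if ov > 0:
            bp[label] = bp.get(label, 0) + ov
    return bp


def genome_label_fractions(track: SegmentationTrack) -> dict[str, float]:
    """Genome-wide fraction of segmented bases carrying each label."""
    bp: dict[str, int] = {}
    total = 0
    for iv, label in track.segments:
        bp[label] = bp.get(label, 0) + iv.length
        total += iv.length
    if total == 0:
        raise ValueError("empty segmentation")
    return {label: bp.get(label, 0) / total for label in SEGMENTATION_LABELS}


def label_frequencies(
    track: SegmentationTrack,
    region: GenomicInterval,
    genome_fractions: dict[str, float],
) -> dict[str, float]:
    """Normalized label frequencies over a region.

    For each label: (bp of label in region / region bp) divided by the
    label's genome-wide bp fraction.  Labels absent genome-wide get 0
    (normalization undefined) with a warning.
    """
    if region.length <= 0:
        raise ValueError("empty region")
    in_region = _label_bp_in(track.segments, region)
    freqs = {}
    for label in SEGMENTATION_LABELS:
        raw = in_region.get(label, 0) / region.length
        gf = genome_fractions.get(label, 0.0)
        if gf <= 0:
            if raw > 0:
                warnings.warn(f"label {label} absent genome-wide; frequency set to 0")
            freqs[label] = 0.0
        else:
            freqs[label] = raw / gf
    return freqs


def call_active_chromatin(
    freqs: dict[str, float],
    tss_ratio: float = 3.0,
    genebody_ratio: float = 2.0,
    repressive_agg: str = "max",
) -> tuple[bool, int]:
    """Active-chromatin call from normalized label frequencies.

    Criterion 1: TSS frequency >= tss_ratio x the (aggregated) repressive
    frequency; criterion 2: min(GS, GM, GE) >= genebody_ratio x the
    repressive frequency.  Active iff either; returns (active, criterion)
    with criterion in {1, 2, 0} and 1 taking precedence.  Both criteria
    require a strictly positive numerator so an all-zero region is
    inactive.  Scale-invariant: multiplying all frequencies by c > 0 does
    not change the call.
    """
    rep_values = [freqs.get(lab, 0.0) for lab in REPRESSIVE_LABELS]
    agg = max(rep_values) if repressive_agg == "max" else float(np.mean(rep_values))
    tss = freqs.get("TSS", 0.0)
    if tss > 0 and tss >= tss_ratio * agg:
        return True, 1
    body = min(freqs.get(lab, 0.0) for lab in GENE_BODY_LABELS)
    if body > 0 and body >= genebody_ratio * agg:
        return True, 2
    return False, 0


def dnase_accessible(
    tracks: dict[str, CoverageTrack],
    anchor: tuple[str, int],
    half_window: int = 4000,
    fold: float = 2.0,
    genome_mean: float | None = None,
) -> bool:
    """DNaseI accessibility call at a 5' end.

    Accessible iff the mean track signal within +/-half_window of the
    anchor is at least ``fold`` times the genome-wide mean signal.
    """
    chrom, pos = anchor
    track = tracks.get(chrom)
    if track is None:
        return False
    values = np.asarray(track.values, dtype=float)
    if genome_mean is None:
        genome_mean = float(
            np.mean([np.asarray(t.values, dtype=float).mean() for t in tracks.values()])
        )
    lo, hi = max(pos - half_window, 0), min(pos + half_window, values.size)
    if lo >= hi or genome_mean <= 0:
        return False
    return float(values[lo:hi].mean()) >= fold * genome_mean
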