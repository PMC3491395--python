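"""Upstream regulatory activity: 2 kb upstream windows, TFBS assignment by
the majority-of-peak rule, Pol2 and promoter activity calls, and enrichment
statistics contrasting transcribed with non-transcribed pseudogenes.

Loci whose 5' ends lie within 4 kb of a protein-coding TSS are excluded
from upstream analysis — their windows would absorb the coding gene's own
regulatory signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import GenomicInterval, Peak, PseudogeneRecord

__all__ = [
    "UpstreamWindow",
    "RegulationCall",
    "upstream_window",
    "filter_near_coding_tss",
    "count_tfbs",
    "call_pol2_active",
    "derive_pol2_thresholds",
    "call_promoter_active",
    "fisher_enrichment",
    "rank_sum_test",
]


@dataclass(frozen=True)
class UpstreamWindow:
    pseudogene_id: str
    region: GenomicInterval


@dataclass
class RegulationCall:
    pseudogene_id: str
    context: str
    tfbs_count: int = 0
    factors: frozenset = frozenset()
    pol2_active: bool = False
    pol2_criterion: int = 0
    promoter_active: bool = False
    excluded_near_coding_tss: bool = False


def upstream_window(
    record: PseudogeneRecord, length: int = 2000, chrom_length: int | None = None
) -> UpstreamWindow:
    """The strand-aware window immediately 5' of a locus.

    Plus strand: [five_prime_end - length, five_prime_end); minus strand:
    the ``length`` bases just past the locus end.  Clipped at chromosome
    edges (the window may be shorter than ``length``).
    """
    fp = record.five_prime_end
    chrom = record.locus.chrom
    if record.locus.effective_strand() == "+":
        start, end = max(fp - length, 0), fp
    else:
        start, end = fp + 1, fp + 1 + length
    if chrom_length is not None:
        end = min(end, chrom_length)
    if start >= end:
        # locus starts at the chromosome edge; degenerate 1 bp-less window
        start, end = max(end - 1, 0), max(end, 1)
    return UpstreamWindow(record.id, GenomicInterval(chrom, start, end, record.locus.strand))


def filter_near_coding_tss(
    records: list[PseudogeneRecord],
    coding_tss: list[tuple[str, int]],
    dist: int = 4000,
) -> tuple[list[PseudogeneRecord], list[PseudogeneRecord]]:
    """Split records into (kept, excluded) by distance of the pseudogene
    5' end to the nearest coding TSS on the same chromosome.

    Excluded iff the absolute distance is strictly below ``dist``;
    chromosomes with no coding gene keep all their loci.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in coding_tss:
        tss_by_chrom.setdefault(chrom, []).append(pos)
    tss_by_chrom = {c: np.sort(np.asarray(p)) for c, p in tss_by_chrom.items()}
    kept, excluded = [], []
    for rec in records:
        positions = tss_by_chrom.get(rec.locus.chrom)
        if positions is None or positions.size == 0:
            kept.append(rec)
            continue
        fp = rec.five_prime_end
        i = np.searchsorted(positions, fp)
        nearest = min(
            abs(fp - positions[j]) for j in (i - 1, i) if 0 <= j < positions.size
        )
        (excluded if nearest < dist else kept).append(rec)
    return kept, excluded


def _majority_inside(peak: Peak, window: GenomicInterval) -> bool:
    ov = 0
    if peak.region.chrom == window.chrom:
        ov = max(0, min(peak.region.end, window.end) - max(peak.region.start, window.start))
    return ov > peak.width / 2


def count_tfbs(peaks: list[Peak], window: UpstreamWindow) -> tuple[int, frozenset]:
    """Count peaks whose majority (strictly more than half the width) lies
    inside the upstream window; returns (peak count, factor set)."""
    counting = [p for p in peaks if _majority_inside(p, window.region)]
    return len(counting), frozenset(p.factor for p in counting)


def call_pol2_active(
    pol2_peaks: list[Peak],
    cofactor_peaks: list[Peak],
    window: UpstreamWindow,
    width_threshold: float = 519.0,
    signal_threshold: float = 2.38,
    cofactors: frozenset = frozenset({"Taf1", "Taf7", "Tbp", "Nelfe", "Gtf2f1", "Gtf2b", "Ccnt2"}),
) -> tuple[bool, int]:
    """Active Pol2 binding in the upstream window.

    Active iff some Pol2 peak in the window is simultaneously wider than
    the width threshold and stronger than the signal threshold (criteria
    1+2, same peak), or some cofactor peak lies in the window (criterion
    3).  Peaks are assigned to the window by the majority rule.  Returns
    (active, criterion) with criterion 12 or 3 (0 when inactive).
    """
    for p in pol2_peaks:
        if (
            _majority_inside(p, window.region)
            and p.width > width_threshold
            and p.signal > signal_threshold
        ):
            return True, 12
    for p in cofactor_peaks:
        if p.factor in cofactors and _majority_inside(p, window.region):
            return True, 3
    return False, 0


def derive_pol2_thresholds(peaks: list[Peak], percentile: float = 95.0) -> tuple[float, float]:
    """Data-driven Pol2 thresholds: the given percentile of peak widths and
    of signal values over the pooled peak set (linear interpolation)."""
    if len(peaks) < 20:
        raise ValueError("need at least 20 peaks to derive thresholds")
    widths = np.array([p.width for p in peaks], dtype=float)
    signals = np.array([p.signal for p in peaks], dtype=float)
    return (
        float(np.percentile(widths, percentile)),
        float(np.percentile(signals, percentile)),
    )


def call_promoter_active(promoters: list[GenomicInterval], window: UpstreamWindow) -> bool:
    """Active promoter iff any promoter region overlaps the window >=1 bp."""
    w = window.region
    return any(
        p.chrom == w.chrom and min(p.end, w.end) - max(p.start, w.start) >= 1
        for p in promoters
    )


def fisher_enrichment(transcribed_active: int, transcribed_total: int,
                      other_active: int, other_total: int) -> float:
    """One-sided Fisher exact p for enrichment of an activity flag in the
    transcribed group."""
    if transcribed_total == 0 or other_total == 0:
        raise ValueError("degenerate group (empty)")
    table = [
        [transcribed_active, transcribed_total - transcribed_active],
        [other_active, other_total - other_active],
    ]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def rank_sum_test(counts_a, counts_b) -> float:
    """Two-sided Wilcoxon rank-sum p comparing count distributions.

    Exact enumeration for small samples without ties; normal approximation
    with tie correction otherwise.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("degenerate group (empty)")
    small = a.size <= 50 and b.size <= 50
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (small and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
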