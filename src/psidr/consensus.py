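"""Consensus merging of pseudogene call-sets and genome-count extrapolation.

A manually annotated locus is *supported* by an automated caller when some
call of that caller overlaps it by at least 50 bp (one-way test, strand
ignored).  Loci supported by both automated pipelines are evidence level 1;
manual-only loci are level 2.  Pipeline-pipeline consensus calls absent
from the manual set form the "delta 2-way" tier, and unsupported
single-pipeline calls fall into per-pipeline tiers.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .datamodel import GenomicInterval, PseudogeneRecord

__all__ = ["overlap_bp", "assign_levels", "surveyed_set", "extrapolate_count", "LevelAssignment"]


@dataclass(frozen=True)
class LevelAssignment:
    pseudogene_id: str
    level: str
    supporting_callers: frozenset


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp between two intervals; 0 across chromosomes.

    Half-open convention: abutting intervals overlap by 0.  Strand is
    ignored (degraded automated calls may be strand-ambiguous).
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _trees(calls) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for rec in calls:
        iv = rec.locus if isinstance(rec, PseudogeneRecord) else rec
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _supported(locus: GenomicInterval, trees, min_overlap: int) -> bool:
    tree = trees.get(locus.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(locus.start, locus.end):
        if min(hit.end, locus.end) - max(hit.begin, locus.start) >= min_overlap:
            return True
    return False


def assign_levels(manual_set, pipeA_set, pipeB_set, min_overlap: int = 50):
    """Partition call-sets into consensus evidence levels.

    Returns a list of :class:`LevelAssignment`: every manual locus becomes
    level ``1`` (supported by both pipelines) or ``2``; pipeline-pipeline
    consensus calls not in the manual set become ``delta-2way``; remaining
    unsupported single-pipeline calls become ``A-P`` / ``A-R``.  Support is
    boolean per caller — several overlapping calls count once.
    """
    if min_overlap <= 0:
        raise ValueError("min_overlap must be positive")
    manual = list(manual_set)
    pipeA = list(pipeA_set)
    pipeB = list(pipeB_set)
    trees_m = _trees(manual)
    trees_a = _trees(pipeA)
    trees_b = _trees(pipeB)

    out: list[LevelAssignment] = []
    for rec in manual:
        sup = {"manual"}
        if _supported(rec.locus, trees_a, min_overlap):
            sup.add("pipeA")
        if _supported(rec.locus, trees_b, min_overlap):
            sup.add("pipeB")
        level = "1" if {"pipeA", "pipeB"} <= sup else "2"
        out.append(LevelAssignment(rec.id, level, frozenset(sup)))

    for rec in pipeA:
        in_b = _supported(rec.locus, trees_b, min_overlap)
        in_m = _supported(rec.locus, trees_m, min_overlap)
        if in_b and not in_m:
            out.append(LevelAssignment(rec.id, "delta-2way", frozenset({"pipeA", "pipeB"})))
        elif not in_b and not in_m:
            out.append(LevelAssignment(rec.id, "A-P", frozenset({"pipeA"})))
    for rec in pipeB:
        in_a = _supported(rec.locus, trees_a, min_overlap)
        in_m = _supported(rec.locus, trees_m, min_overlap)
        if not in_a and not in_m:
            out.append(LevelAssignment(rec.id, "A-R", frozenset({"pipeB"})))
    return out


def surveyed_set(manual_records, assignments) -> list[PseudogeneRecord]:
    """The surveyed pseudogene set: manual levels 1 and 2, polymorphic
    biotype excluded (such loci may retain coding potential)."""
    by_id = {a.pseudogene_id: a for a in assignments}
    out = []
    for rec in manual_records:
        a = by_id.get(rec.id)
        if a is None or a.level not in {"1", "2"}:
            continue
        if rec.biotype == "polymorphic":
            continue
        rec.level = a.level
        out.append(rec)
    return out


def extrapolate_count(method: str, n_manual: int, denominator: int, numerator: int) -> int:
    """Extrapolate the genome-wide manually-annotatable pseudogene count.

    ``pipeline_ratio`` scales the manual count in the fully annotated
    region by the genome-wide/in-region automated-call ratio:
    ``n_manual * n_pipe_genome / n_pipe_in_region``.  ``length_ratio``
    scales by genome length over annotated length:
    ``n_manual * genome_nt / annotated_nt``.  Rounded to the nearest
    integer, ties away from zero.
    """
    if method not in {"pipeline_ratio", "length_ratio"}:
        raise ValueError(f"unknown extrapolation method {method!r}")
    if n_manual <= 0 or denominator <= 0 or numerator <= 0:
        raise ValueError("all extrapolation inputs must be positive")
    value = n_manual * numerator / denominator
    # round half away from zero
    import math

    return int(math.floor(value + 0.5))
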