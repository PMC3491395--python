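"""Transcription calling from three evidence pipelines (EST/mRNA,
total RNA-seq, multi-tissue BodyMap coverage), merged with an OR gate.

A pseudogene is called transcribed when at least one pipeline accepts it;
the per-source tags are kept so the provenance of every call is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "HitCategory",
    "TranscriptionCall",
    "categorize_similarity",
    "call_est",
    "call_total_rna",
    "call_bodymap",
    "merge_calls",
]


@dataclass(frozen=True)
class HitCategory:
    """Count of non-self high-identity genomic alignments, binned."""

    pseudogene_id: str
    n_similar_regions: int
    category: str


@dataclass
class TranscriptionCall:
    pseudogene_id: str
    transcribed: bool
    evidence: frozenset = frozenset()
    tissues: frozenset = frozenset()

    def __post_init__(self):
        if self.transcribed != bool(self.evidence):
            raise ValueError("transcribed flag must mirror non-empty evidence")


def categorize_similarity(pseudogene_id: str, n_hits: int) -> HitCategory:
    """Bin the number of similar genomic regions into {0, 1, 2-5, >5}."""
    if n_hits < 0:
        raise ValueError("hit count must be >= 0")
    if n_hits == 0:
        cat = "0"
    elif n_hits == 1:
        cat = "1"
    elif n_hits <= 5:
        cat = "2-5"
    else:
        cat = ">5"
    return HitCategory(pseudogene_id, n_hits, cat)


def call_est(evidence_records) -> bool:
    """Locus-specific EST/mRNA evidence: some transcript with a
    best-in-genome alignment at the pseudogene locus AND clear differences
    from the parent locus."""
    return any(best and differs for best, differs in evidence_records)


def call_total_rna(pseudo_cov: float, parent_cov: float, pair_identity: float) -> bool:
    """Total RNA-seq rule: reads on the pseudogene with none on the parent,
    or reads on both with parent similarity strictly below 90%."""
    if pseudo_cov < 0 or parent_cov < 0:
        raise ValueError("coverages must be >= 0")
    if pseudo_cov <= 0:
        return False
    if parent_cov == 0:
        return True
    return pair_identity < 90.0


def call_bodymap(
    per_tissue_depth: dict[str, np.ndarray],
    n_similar_regions: int,
    parent_expression: dict[str, float] | None = None,
    min_depth: int = 2,
    min_frac: float = 0.5,
    discordance_max_spearman: float = 0.5,
) -> tuple[bool, frozenset]:
    """Multi-tissue coverage rule with a parent-discordance guard.

    Coverage rule: in at least one tissue, at least ``min_frac`` of the
    locus is covered at depth >= ``min_depth``.  For loci with similar
    regions elsewhere in the genome (mapping ambiguity), the call
    additionally requires the pseudogene's per-tissue expression profile to
    be discordant from the parent's (Spearman rho <= threshold); loci with
    no similar region need no guard.  Returns (called, passing tissues).
    """
    if not per_tissue_depth:
        raise ValueError("at least one tissue track required")
    passing = set()
    for tissue, depth in per_tissue_depth.items():
        depth = np.asarray(depth)
        if depth.size == 0:
            raise ValueError("zero-length locus")
        if (depth >= min_depth).mean() >= min_frac:
            passing.add(tissue)
    if not passing:
        return False, frozenset()
    if n_similar_regions == 0 or parent_expression is None:
        return True, frozenset(passing)
    tissues = sorted(set(per_tissue_depth) & set(parent_expression))
    pg_expr = [float(np.mean(per_tissue_depth[t])) for t in tissues]
    pa_expr = [parent_expression[t] for t in tissues]
    if len(tissues) < 3 or np.std(pg_expr) == 0 or np.std(pa_expr) == 0:
        # degenerate profiles cannot demonstrate discordance
        return False, frozenset()
    rho = stats.spearmanr(pg_expr, pa_expr).statistic
    if rho <= discordance_max_spearman:
        return True, frozenset(passing)
    return False, frozenset()


def merge_calls(
    pseudogene_id: str,
    est: bool,
    total_rna: bool,
    bodymap: bool,
    bodymap_tissues=frozenset(),
    rtpcr: bool = False,
) -> TranscriptionCall:
    """OR gate over the evidence pipelines; externally supplied RT-PCR
    validation passes through as an additional tag."""
    evidence = set()
    if est:
        evidence.add("EST")
    if total_rna:
        evidence.add("TotalRNA")
    if bodymap:
        evidence.add("BodyMap")
    if rtpcr:
        evidence.add("RT-PCR")
    return TranscriptionCall(
        pseudogene_id=pseudogene_id,
        transcribed=bool(evidence),
        evidence=frozenset(evidence),
        tissues=frozenset(bodymap_tissues) if bodymap else frozenset(),
    )
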