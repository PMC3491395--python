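"""Assembly of the per-pseudogene decoration table, cross-context
tissue-specificity matrices, and partial-activity classification.

Partial-activity classes formalize two narratives: "dying" genes — not
transcribed, yet with active chromatin, a live upstream apparatus and
sequence still under negative selection — and "resurrected" ones —
transcribed with active chromatin gained independently of the parent's
upstream elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DecorationRecord, GenomicInterval

__all__ = [
    "PartialActivityClass",
    "decorate",
    "jaccard",
    "specificity_matrix",
    "classify_partial_activity",
]

PARTIAL_ACTIVITY_CLASSES = (
    "dying",
    "resurrected",
    "fully_active",
    "dead",
    "partially_active",
)


@dataclass(frozen=True)
class PartialActivityClass:
    pseudogene_id: str
    label: str


def decorate(
    surveyed,
    context: str,
    parent_info: dict[str, dict] | None = None,
    identity_class: dict[str, str] | None = None,
    transcription: dict | None = None,
    conserved: dict[str, bool] | None = None,
    chromatin: dict[str, bool] | None = None,
    dnase: dict[str, bool] | None = None,
    regulation: dict | None = None,
) -> list[DecorationRecord]:
    """Build one decoration record per surveyed pseudogene for a context.

    Components are keyed by pseudogene id; a missing component leaves its
    flag 0.  Ids present in a component but absent from the surveyed set
    are dropped with a warning.
    """
    surveyed_ids = {r.id for r in surveyed}
    for name, comp in [
        ("transcription", transcription),
        ("conserved", conserved),
        ("chromatin", chromatin),
        ("regulation", regulation),
    ]:
        if comp:
            stray = set(comp) - surveyed_ids
            if stray:
                warnings.warn(
                    f"{len(stray)} {name} id(s) absent from the surveyed set; dropped"
                )
    records = []
    for rec in surveyed:
        pid = rec.id
        parent = (parent_info or {}).get(pid, {})
        tcall = (transcription or {}).get(pid)
        rcall = (regulation or {}).get(pid)
        excluded = bool(rcall.excluded_near_coding_tss) if rcall else False
        records.append(
            DecorationRecord(
                pseudogene_id=pid,
                context=context,
                parent_protein_id=parent.get("protein_id", "."),
                parent_gene_id=parent.get("gene_id", rec.parent_id or "."),
                parent_locus=parent.get("locus"),
                sequence_similarity_class=(identity_class or {}).get(pid, "."),
                transcribed=int(bool(tcall and tcall.transcribed)),
                transcription_evidence=(
                    tcall.evidence if (tcall and tcall.transcribed) else frozenset({"None"})
                ),
                dnase_accessible=int(bool((dnase or {}).get(pid, False))),
                active_chromatin=int(bool((chromatin or {}).get(pid, False))),
                active_pol2=int(bool(rcall and not excluded and rcall.pol2_active)),
                active_promoter=int(bool(rcall and not excluded and rcall.promoter_active)),
                conserved=int(bool((conserved or {}).get(pid, False))),
                excluded_near_coding_tss=int(excluded),
            )
        )
    return records


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def specificity_matrix(active_sets: dict[str, set]) -> pd.DataFrame:
    """Pairwise Jaccard similarity of active-pseudogene sets across
    contexts (symmetric, unit diagonal)."""
    if len(active_sets) < 2:
        raise ValueError("need at least two contexts")
    contexts = sorted(active_sets)
    n = len(contexts)
    mat = np.ones((n, n))
    for i, a in enumerate(contexts):
        for j in range(i + 1, n):
            v = jaccard(active_sets[a], active_sets[contexts[j]])
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=contexts, columns=contexts)


def classify_partial_activity(
    record: DecorationRecord, parent_upstream_retained: bool
) -> PartialActivityClass:
    """Classify a decoration record by its activity pattern.

    Rule order (first match wins):
      dying            not transcribed, active chromatin, live upstream
                       apparatus (Pol2 or promoter), conserved;
      resurrected      transcribed, active chromatin, upstream elements not
                       inherited from the parent;
      fully_active     transcribed, active chromatin, Pol2 or promoter;
      dead             every activity flag 0;
      partially_active anything else.
    """
    required = (
        record.transcribed,
        record.active_chromatin,
        record.active_pol2,
        record.active_promoter,
        record.conserved,
    )
    if any(f is None for f in required):
        raise ValueError("incomplete decoration record")
    t, chrom = record.transcribed, record.active_chromatin
    upstream = record.active_pol2 or record.active_promoter
    if not t and chrom and upstream and record.conserved:
        label = "dying"
    elif t and chrom and not parent_upstream_retained:
        label = "resurrected"
    elif t and chrom and upstream:
        label = "fully_active"
    elif not any(
        (t, chrom, record.active_pol2, record.active_promoter,
         record.conserved, record.dnase_accessible)
    ):
        label = "dead"
    else:
        label = "partially_active"
    return PartialActivityClass(record.pseudogene_id, label)


def parent_upstream_retained(
    biotype: str, pseudogene_factors: frozenset, parent_factors: frozenset
) -> bool:
    """Proxy for retention of the parent's upstream regulatory region:
    duplicated biotype and at least one TF bound upstream of both the
    pseudogene and its parent."""
    return biotype == "duplicated" and bool(pseudogene_factors & parent_factors)
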