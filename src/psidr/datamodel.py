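"""Core domain types shared across the pseudogene-decoration pipeline.

Coordinates are 0-based half-open throughout the package; GTF input/output
is converted at the I/O boundary (1-based inclusive on disk).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomicInterval",
    "PseudogeneRecord",
    "Peak",
    "CoverageTrack",
    "SegmentationTrack",
    "VariantRecord",
    "Thresholds",
    "DecorationRecord",
    "ACTIVE_LABELS",
    "REPRESSIVE_LABELS",
    "SEGMENTATION_LABELS",
    "GENE_BODY_LABELS",
    "BIOTYPES",
    "LEVELS",
    "EVIDENCE_TAGS",
]

BIOTYPES = {"processed", "duplicated", "unitary", "polymorphic", "ambiguous", "coding"}
LEVELS = {"1", "2", "A-P", "A-R", "2-way", "delta-2way", "unassigned"}
EVIDENCE_TAGS = {"EST", "BodyMap", "TotalRNA", "RT-PCR", "None"}

# A 25-state chromatin segmentation vocabulary, partitioned into labels that
# indicate genomic activity (promoter/TSS, gene body, enhancer, open
# chromatin) and repressive/quiescent labels.  TSS and the gene-body labels
# GS (start), GM (middle), e/GM (enhancer/middle) and GE (end) drive the
# active-chromatin classifier.
ACTIVE_LABELS = frozenset(
    {
        "TSS", "TSSF", "PROM", "PROMF", "GS", "GM", "e/GM", "GE",
        "ENH", "ENHF", "ENHW", "OPEN", "FAIRE",
    }
)
REPRESSIVE_LABELS = frozenset(
    {
        "CTCF", "REP1", "REP2", "REP3", "REP4", "REP5",
        "QUI1", "QUI2", "QUI3", "QUI4", "QUI5", "LOW",
    }
)
SEGMENTATION_LABELS = ACTIVE_LABELS | REPRESSIVE_LABELS
GENE_BODY_LABELS = ("GS", "GM", "GE")

assert len(SEGMENTATION_LABELS) == 25
assert not (ACTIVE_LABELS & REPRESSIVE_LABELS)

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def effective_strand(self) -> str:
        """Strand used for 5'-anchored computations; '.' falls back to '+'."""
        if self.strand == ".":
            warnings.warn(
                f"unstranded interval {self.chrom}:{self.start}-{self.end} "
                "treated as '+' for strand-aware computation",
                stacklevel=2,
            )
            return "+"
        return self.strand


@dataclass
class PseudogeneRecord:
    """One annotated pseudogene (or coding-gene) locus."""

    id: str
    locus: GenomicInterval
    biotype: str = "ambiguous"
    level: str = "unassigned"
    parent_id: str | None = None
    parent_source: str = "none"
    caller: str = "manual"

    def __post_init__(self):
        if self.biotype not in BIOTYPES:
            warnings.warn(f"unknown biotype {self.biotype!r} for {self.id}; flagged ambiguous")
            self.biotype = "ambiguous"
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.parent_source not in {"manual", "alignment", "automated", "none"}:
            raise ValueError(f"unknown parent source {self.parent_source!r}")

    @property
    def five_prime_end(self) -> int:
        """Strand-aware TSS-equivalent single-base position."""
        if self.locus.effective_strand() == "+":
            return self.locus.start
        return self.locus.end - 1


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak (narrowPeak row) with factor name and signal value."""

    region: GenomicInterval
    factor: str
    signal: float

    def __post_init__(self):
        if self.signal < 0:
            raise ValueError("peak signal must be >= 0")

    @property
    def width(self) -> int:
        return self.region.length


@dataclass
class CoverageTrack:
    """Per-base read depth over one chromosome for one tissue/sample."""

    chrom: str
    values: np.ndarray
    tissue: str

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if (self.values < 0).any():
            raise ValueError("coverage values must be nonnegative")


@dataclass
class SegmentationTrack:
    """Non-overlapping labeled chromatin-state segments for one context."""

    segments: list[tuple[GenomicInterval, str]]
    context: str = ""

    def __post_init__(self):
        bad = {lab for _, lab in self.segments} - SEGMENTATION_LABELS
        if bad:
            raise ValueError(f"labels outside the 25-label set: {sorted(bad)}")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv, _ in self.segments:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (s0, e0), (s1, _) in zip(spans, spans[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping segments on {chrom} at {s1}")


@dataclass(frozen=True)
class VariantRecord:
    """A population variant with its derived allele frequency."""

    position: GenomicInterval
    vclass: str
    daf: float

    def __post_init__(self):
        if self.vclass not in {"SNP", "indel", "SV"}:
            raise ValueError(f"unknown variant class {self.vclass!r}")
        if not (0.0 <= self.daf <= 1.0):
            raise ValueError("DAF must lie in [0, 1]")


@dataclass(frozen=True)
class Thresholds:
    """Every numeric constant used by the decoration rules.

    Defaults are the operating points of the published analysis: the 50 bp
    consensus-overlap rule, the 80%/60% identity bins, the <90% parent
    similarity cut of the total-RNA rule, the 2 kb 3' extension and 100 bp
    identity window, the >=2-reads-over-half-length coverage rule, 1.5%/5%
    chimp/mouse background substitution rates, FDR 0.05, the 3x TSS and 2x
    gene-body segmentation criteria, the 519 bp / 2.38 Pol2 peak thresholds
    with the seven-cofactor rescue, the 2 kb upstream window, the 4 kb
    coding-TSS exclusion and the +/-4 kb profile half-window.
    """

    consensus_overlap_bp: int = 50
    identity_high: float = 80.0
    identity_low: float = 60.0
    parent_similarity_cut: float = 90.0
    utr_extension_bp: int = 2000
    utr_window_bp: int = 100
    bodymap_min_depth: int = 2
    bodymap_min_frac: float = 0.5
    background_rate_chimp: float = 0.015
    background_rate_mouse: float = 0.05
    fdr: float = 0.05
    tss_ratio: float = 3.0
    genebody_ratio: float = 2.0
    pol2_width_bp: float = 519.0
    pol2_signal: float = 2.38
    cofactors: frozenset = frozenset(
        {"Taf1", "Taf7", "Tbp", "Nelfe", "Gtf2f1", "Gtf2b", "Ccnt2"}
    )
    upstream_bp: int = 2000
    coding_tss_exclusion_bp: int = 4000
    profile_halfwindow_bp: int = 4000
    discordance_max_spearman: float = 0.5
    dnase_fold: float = 2.0

    def __post_init__(self):
        numeric = {
            k: v
            for k, v in self.__dict__.items()
            if isinstance(v, (int, float)) and not isinstance(v, bool)
        }
        for name, value in numeric.items():
            if value <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")
        if not self.identity_low < self.identity_high:
            raise ValueError("identity_low must be < identity_high")


#: Table column order of the per-pseudogene decoration (psiDR) file.
PSIDR_FIELDS = [
    "pseudogene_id",
    "context",
    "parent_protein_id",
    "parent_gene_id",
    "parent_chrom",
    "parent_start",
    "parent_end",
    "parent_strand",
    "sequence_similarity_class",
    "transcribed",
    "transcription_evidence",
    "dnase_accessible",
    "active_chromatin",
    "active_pol2",
    "active_promoter",
    "conserved",
    "excluded_near_coding_tss",
]


@dataclass
class DecorationRecord:
    """One psiDR row: per-pseudogene activity flags in one cell context."""

    pseudogene_id: str
    context: str = "."
    parent_protein_id: str = "."
    parent_gene_id: str = "."
    parent_locus: GenomicInterval | None = None
    sequence_similarity_class: str = "."
    transcribed: int = 0
    transcription_evidence: frozenset = frozenset({"None"})
    dnase_accessible: int = 0
    active_chromatin: int = 0
    active_pol2: int = 0
    active_promoter: int = 0
    conserved: int = 0
    excluded_near_coding_tss: int = 0

    def __post_init__(self):
        flags = (
            self.transcribed,
            self.dnase_accessible,
            self.active_chromatin,
            self.active_pol2,
            self.active_promoter,
            self.conserved,
            self.excluded_near_coding_tss,
        )
        if any(f not in (0, 1) for f in flags):
            raise ValueError("decoration flags must be 0/1")
        tags = frozenset(self.transcription_evidence)
        if not tags:
            tags = frozenset({"None"})
        bad = tags - EVIDENCE_TAGS
        if bad:
            raise ValueError(f"unknown evidence tags {sorted(bad)}")
        if (tags != {"None"}) != bool(self.transcribed):
            raise ValueError(
                "transcribed flag must be 1 exactly when evidence tags != {None}"
            )
        self.transcription_evidence = tags


def copy_with(obj, **kw):
    """Dataclass copy helper (re-export of dataclasses.replace)."""
    return replace(obj, **kw)
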