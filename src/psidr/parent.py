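"""Parent assignment and pseudogene-parent sequence identity.

A pseudogene's parent is the functional paralog it derives from; when
several evidence sources disagree, the highest-ranked source wins in the
order manual annotation > one-to-one genomic alignment > automated
curation.  Identity to the parent is scored separately over the CDS and the
3' UTR (the parent transcript extended 2 kb past its stop for UTR
coverage); the 3' UTR is summarized by the best 100-column sliding window
so short preserved islands (for example small-RNA target sites) are not
diluted by surrounding decay.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

__all__ = [
    "PARENT_SOURCE_PRIORITY",
    "AlignmentPair",
    "IdentityClass",
    "assign_parent",
    "align_pair",
    "cds_identity",
    "utr3_window_identity",
    "classify_identity_group",
]

PARENT_SOURCE_PRIORITY = ("manual", "alignment", "automated")

#: alignment scoring: match +1, mismatch -1, gap open -5 (covers the first
#: gapped column), each further gapped column -1.
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, -5.0, -1.0


@dataclass
class AlignmentPair:
    """Columns of a pairwise global alignment, split by parent region.

    ``columns[region]`` is a string over {'M' match, 'X' mismatch,
    'G' gap} per aligned column, regions keyed 'CDS' and 'UTR3'.
    """

    pseudogene_id: str
    parent_id: str
    columns: dict[str, str]
    score: float


@dataclass(frozen=True)
class IdentityClass:
    cds_identity: float
    utr3_identity: float
    group: str


def assign_parent(candidates_by_source: dict[str, str]) -> tuple[str | None, str]:
    """Pick the parent candidate from the highest-priority evidence source."""
    for source in PARENT_SOURCE_PRIORITY:
        if source in candidates_by_source and candidates_by_source[source]:
            return candidates_by_source[source], source
    return None, "none"


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def align_pair(
    pseudo_seq: str,
    parent_seq: str,
    parent_cds_len: int | None = None,
    pseudogene_id: str = "",
    parent_id: str = "",
) -> AlignmentPair:
    """Globally align a pseudogene to its parent (affine gap penalties).

    ``parent_cds_len`` splits parent positions into CDS (< cds_len) and
    UTR3 (>= cds_len) and assigns every alignment column to a region;
    columns gapped in the parent inherit the region of the last parent
    position consumed.  With ``parent_cds_len=None`` all columns are CDS.
    Deterministic: of co-optimal alignments the aligner's first is taken.
    """
    if not pseudo_seq or not parent_seq:
        raise ValueError("cannot align empty sequences")
    if parent_cds_len is None:
        parent_cds_len = len(parent_seq)
    aln = _aligner().align(pseudo_seq.upper(), parent_seq.upper())
    best = aln[0]
    pseudo_row, parent_row = str(best[0]), str(best[1])
    cols = {"CDS": [], "UTR3": []}
    parent_pos = 0
    for p_char, q_char in zip(pseudo_row, parent_row):
        region = "CDS" if parent_pos < parent_cds_len else "UTR3"
        if p_char == "-" or q_char == "-":
            state = "G"
        elif p_char == q_char:
            state = "M"
        else:
            state = "X"
        cols[region].append(state)
        if q_char != "-":
            parent_pos += 1
    return AlignmentPair(
        pseudogene_id=pseudogene_id,
        parent_id=parent_id,
        columns={k: "".join(v) for k, v in cols.items()},
        score=best.score,
    )


def _identity(columns: str) -> float:
    """Percent matches over all columns (gap columns in the denominator)."""
    if not columns:
        raise ValueError("identity undefined on zero aligned columns")
    return 100.0 * columns.count("M") / len(columns)


def cds_identity(pair: AlignmentPair) -> float:
    """Percent identity over the aligned CDS columns."""
    return _identity(pair.columns["CDS"])


def utr3_window_identity(pair: AlignmentPair, window: int = 100) -> float:
    """Best local identity over 100-column sliding windows of the 3' UTR.

    The window slides one column at a time; regions shorter than the
    window are scored whole.
    """
    cols = pair.columns["UTR3"]
    if not cols:
        raise ValueError("identity undefined on zero aligned UTR3 columns")
    if len(cols) <= window:
        return _identity(cols)
    # rolling match count
    best = matches = cols[:window].count("M")
    for i in range(window, len(cols)):
        matches += (cols[i] == "M") - (cols[i - window] == "M")
        best = max(best, matches)
    return 100.0 * best / window


def _bin(value: float, low: float, high: float) -> str:
    if value < low:
        return "low"
    if value > high:
        return "high"
    return "mid"


def classify_identity_group(
    cds_id: float, utr_id: float, low: float = 60.0, high: float = 80.0
) -> IdentityClass:
    """Bin CDS and 3'UTR identities into the 3x3 = 9 identity groups.

    'low' is strictly below 60%, 'high' strictly above 80%, 'mid' is the
    closed interval between.  The group label is '<cds bin>CDS-<utr
    bin>UTR', e.g. 'highCDS-lowUTR' for the decayed-UTR class.
    """
    for v in (cds_id, utr_id):
        if not (0.0 <= v <= 100.0):
            raise ValueError("identities must lie in [0, 100]")
    group = f"{_bin(cds_id, low, high)}CDS-{_bin(utr_id, low, high)}UTR"
    return IdentityClass(cds_identity=cds_id, utr3_identity=utr_id, group=group)
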