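"""Readers and writers for the standard formats the pipeline touches.

Conventions: GTF is 1-based inclusive on disk and converted to the package's
0-based half-open intervals on read (and back on write); BED, narrowPeak and
bedGraph are already 0-based half-open.  Divergence and variant inputs are
plain TSV (see the column lists below) because multiple-alignment
construction and variant calling are upstream of this package.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    PSIDR_FIELDS,
    SEGMENTATION_LABELS,
    CoverageTrack,
    DecorationRecord,
    GenomicInterval,
    Peak,
    PseudogeneRecord,
    SegmentationTrack,
    VariantRecord,
)

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
    "read_segmentation",
    "write_segmentation",
    "read_divergence",
    "read_variants",
    "write_psidr",
    "read_psidr",
]


class ParseError(ValueError):
    """Malformed input line; message carries file and line number."""


def _attr_dict(attr_field: str) -> dict[str, str]:
    out = {}
    for piece in attr_field.strip().split(";"):
        piece = piece.strip()
        if not piece:
            continue
        key, _, value = piece.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_annotation(path, format: str = "GTF") -> list[PseudogeneRecord]:
    """Read gene/pseudogene records from a GTF or BED6 file.

    GTF records use attributes ``gene_id``, ``transcript_type`` (biotype),
    and optionally ``parent_id``/``parent_source``/``level``/``caller``.
    BED6 uses name/strand only; biotype defaults to ambiguous.
    """
    path = Path(path)
    records: list[PseudogeneRecord] = []
    fmt = format.upper()
    if fmt not in {"GTF", "BED"}:
        raise ValueError(f"unknown annotation format {format!r}")
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "GTF":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated GTF fields")
                    chrom, _, _, start, end, _, strand, _, attrs = fields[:9]
                    iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
                    a = _attr_dict(attrs)
                    rec = PseudogeneRecord(
                        id=a.get("gene_id", f"rec{lineno}"),
                        locus=iv,
                        biotype=a.get("transcript_type", "ambiguous"),
                        level=a.get("level", "unassigned"),
                        parent_id=a.get("parent_id") or None,
                        parent_source=a.get("parent_source", "none"),
                        caller=a.get("caller", "manual"),
                    )
                else:
                    if len(fields) < 4:
                        raise ValueError("expected >=4 BED fields")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3]
                    strand = fields[5] if len(fields) >= 6 else "."
                    rec = PseudogeneRecord(
                        id=name, locus=GenomicInterval(chrom, start, end, strand)
                    )
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    if not records:
        warnings.warn(f"{path}: empty annotation file")
    return records


def write_annotation(records, path, format: str = "GTF", source: str = "psidr") -> None:
    path = Path(path)
    fmt = format.upper()
    with open(path, "w") as fh:
        for r in records:
            iv = r.locus
            if fmt == "GTF":
                attrs = (
                    f'gene_id "{r.id}"; transcript_type "{r.biotype}"; '
                    f'level "{r.level}"; parent_id "{r.parent_id or ""}"; '
                    f'parent_source "{r.parent_source}"; caller "{r.caller}";'
                )
                fh.write(
                    f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{attrs}\n"
                )
            else:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.id}\t0\t{iv.strand}\n"
                )


def read_narrowpeak(path, default_factor: str | None = None) -> list[Peak]:
    """Read an ENCODE narrowPeak (10-column BED6+4) file.

    The peak name column carries the factor name unless ``default_factor``
    overrides it; signalValue is column 7.
    """
    path = Path(path)
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ParseError(f"{path}:{lineno}: expected 10 narrowPeak columns")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5] if f[5] in "+-" else ".")
            factor = default_factor or f[3].split("_")[0]
            peaks.append(Peak(region=iv, factor=factor, signal=float(f[6])))
    return peaks


def write_narrowpeak(peaks, path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            iv = p.region
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.factor}_{i}\t0\t{iv.strand}\t"
                f"{p.signal:.6g}\t-1\t-1\t-1\n"
            )


def read_bedgraph(path, chrom_lengths: dict[str, int], tissue: str = "") -> dict[str, CoverageTrack]:
    """Expand a bedGraph into dense per-base coverage tracks.

    Intervals must be non-overlapping (bedGraph dialect); uncovered bases
    are zero.
    """
    arrays = {c: np.zeros(n, dtype=np.float32) for c, n in chrom_lengths.items()}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            if chrom not in arrays:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if start < last_end.get(chrom, 0):
                raise ParseError(
                    f"{path}:{lineno}: overlapping bedGraph intervals on {chrom}"
                )
            last_end[chrom] = end
            arrays[chrom][start:end] = value
    return {
        c: CoverageTrack(chrom=c, values=v, tissue=tissue) for c, v in arrays.items()
    }


def write_bedgraph(tracks: dict[str, CoverageTrack], path) -> None:
    """Run-length encode dense tracks back to bedGraph (zero runs omitted)."""
    with open(path, "w") as fh:
        for chrom in sorted(tracks):
            v = np.asarray(tracks[chrom].values)
            if v.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [v.size]))
            for s, e in zip(starts, ends):
                if v[s] != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:.6g}\n")


def read_segmentation(path, context: str = "") -> SegmentationTrack:
    """Read a 4-column BED (chrom, start, end, label) segmentation file."""
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 segmentation columns")
            label = f[3]
            if label not in SEGMENTATION_LABELS:
                raise ParseError(
                    f"{path}:{lineno}: label {label!r} outside the 25-label set"
                )
            segments.append((GenomicInterval(f[0], int(f[1]), int(f[2])), label))
    return SegmentationTrack(segments=segments, context=context)


def write_segmentation(track: SegmentationTrack, path) -> None:
    with open(path, "w") as fh:
        for iv, label in sorted(track.segments, key=lambda t: (t[0].chrom, t[0].start)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


#: divergence TSV columns
DIVERGENCE_COLUMNS = ["pseudogene_id", "species", "aligned_bp", "substitutions", "length"]
#: variant TSV columns
VARIANT_COLUMNS = ["chrom", "start", "end", "vclass", "daf", "pseudogene_id"]


def read_divergence(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DIVERGENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: divergence TSV missing columns {sorted(missing)}")
    bad = df[(df.aligned_bp > df.length) | (df.substitutions > df.aligned_bp)]
    if len(bad):
        raise ParseError(
            f"{path}: {len(bad)} rows violate substitutions <= aligned_bp <= length"
        )
    return df


def read_variants(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: variant TSV missing columns {sorted(missing)}")
    return [
        VariantRecord(
            position=GenomicInterval(r.chrom, int(r.start), int(r.end)),
            vclass=r.vclass,
            daf=float(r.daf),
        )
        for r in df.itertuples()
    ]


def _tag_cell(tags) -> str:
    order = ["EST", "TotalRNA", "BodyMap", "RT-PCR", "None"]
    present = [t for t in order if t in tags]
    return ",".join(present) if present else "None"


def write_psidr(records: list[DecorationRecord], path) -> None:
    """Serialize decoration records as the psiDR TSV (one row per
    pseudogene per cell context; flags as 0/1, evidence tags
    comma-separated)."""
    seen = set()
    rows = []
    for r in records:
        key = (r.pseudogene_id, r.context)
        if key in seen:
            raise ValueError(f"duplicate (pseudogene, context) key {key}")
        seen.add(key)
        pl = r.parent_locus
        rows.append(
            {
                "pseudogene_id": r.pseudogene_id,
                "context": r.context,
                "parent_protein_id": r.parent_protein_id,
                "parent_gene_id": r.parent_gene_id,
                "parent_chrom": pl.chrom if pl else ".",
                "parent_start": pl.start if pl else -1,
                "parent_end": pl.end if pl else -1,
                "parent_strand": pl.strand if pl else ".",
                "sequence_similarity_class": r.sequence_similarity_class,
                "transcribed": r.transcribed,
                "transcription_evidence": _tag_cell(r.transcription_evidence),
                "dnase_accessible": r.dnase_accessible,
                "active_chromatin": r.active_chromatin,
                "active_pol2": r.active_pol2,
                "active_promoter": r.active_promoter,
                "conserved": r.conserved,
                "excluded_near_coding_tss": r.excluded_near_coding_tss,
            }
        )
    pd.DataFrame(rows, columns=PSIDR_FIELDS).to_csv(path, sep="\t", index=False)


def read_psidr(path) -> list[DecorationRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"sequence_similarity_class": str}, keep_default_na=False
    )
    records = []
    for r in df.itertuples():
        parent_locus = None
        if r.parent_chrom != "." and int(r.parent_start) >= 0:
            parent_locus = GenomicInterval(
                str(r.parent_chrom), int(r.parent_start), int(r.parent_end),
                str(r.parent_strand),
            )
        records.append(
            DecorationRecord(
                pseudogene_id=str(r.pseudogene_id),
                context=str(r.context),
                parent_protein_id=str(r.parent_protein_id),
                parent_gene_id=str(r.parent_gene_id),
                parent_locus=parent_locus,
                sequence_similarity_class=str(r.sequence_similarity_class),
                transcribed=int(r.transcribed),
                transcription_evidence=frozenset(
                    str(r.transcription_evidence).split(",")
                ),
                dnase_accessible=int(r.dnase_accessible),
                active_chromatin=int(r.active_chromatin),
                active_pol2=int(r.active_pol2),
                active_promoter=int(r.active_promoter),
                conserved=int(r.conserved),
                excluded_near_coding_tss=int(r.excluded_near_coding_tss),
            )
        )
    return records
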