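"""Synthetic miniature genome with planted pseudogene activity.

Generates a toy annotation (coding genes, pseudogenes, three caller
call-sets) together with every functional-genomics input the decoration
pipeline consumes — sequences, per-tissue coverage, chromatin
segmentations, ChIP-seq peaks, promoter calls, DNase tracks, divergence
and variant tables — with known planted "transcribed", "conserved",
"active-chromatin", "Pol2-active", "promoter-active" and
"DNase-accessible" subsets recorded in a truth table, so that every
pipeline stage is scoreable without external data.

Default scale is deliberately small (2 chromosomes x 2 Mb, 60 coding
genes, 200 pseudogenes, 4 tissues, 2 cell contexts) so the full pipeline
runs in seconds.  Generation is a pure function of (config, seed); each
stage draws from its own named RNG stream so one stage's output is stable
when another stage's parameters change.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    CoverageTrack,
    GenomicInterval,
    Peak,
    PseudogeneRecord,
    SegmentationTrack,
    REPRESSIVE_LABELS,
    SEGMENTATION_LABELS,
)

__all__ = [
    "SimulationConfig",
    "SimulatedCorpus",
    "simulate_corpus",
    "simulate_annotation",
    "simulate_sequences",
    "simulate_coverage",
    "simulate_functional_genomics",
    "simulate_divergence_and_variants",
    "simulate_null_pol2_peaks",
]

_BASES = np.array(list("ACGT"))
_TF_FACTORS = ("Ctcf", "Myc", "Jun", "Fos", "Egr1", "Sp1", "Yy1", "Max")
_COFACTORS = ("Taf1", "Taf7", "Tbp", "Nelfe", "Gtf2f1", "Gtf2b", "Ccnt2")
_MARGIN = 3500  # bp of clear space flanking every locus inside its slot


@dataclass
class SimulationConfig:
    """Knobs of the synthetic corpus; defaults define the study conditions."""

    n_chromosomes: int = 2
    chrom_length_bp: int = 2_000_000
    n_coding_genes: int = 60
    n_pseudogenes: int = 200
    processed_frac: float = 0.65
    duplicated_frac: float = 0.30
    polymorphic_count: int = 4
    # consensus structure
    level1_frac: float = 0.75
    subthreshold_decoy_frac: float = 0.5
    n_delta_two_way: int = 10
    n_pipe_only: int = 5
    # planted activity
    transcribed_frac: float = 0.20
    conserved_frac: float = 0.10
    conserved_multiplier: float = 0.1
    active_chromatin_frac: float = 0.15
    chromatin_transcribed_bias: float = 0.4
    pol2_frac: float = 0.10
    pol2_transcribed_bias: float = 0.5
    promoter_frac: float = 0.10
    dnase_frac: float = 0.10
    shared_context_frac: float = 0.5
    n_near_coding: int = 8
    # effect parameters
    coverage_depth: int = 4
    covered_frac: float = 0.7
    noise_depth: float = 0.0
    discordance: float = 1.0
    aligned_frac: tuple = (("chimp", 0.95), ("mouse", 0.55))
    background_rates: tuple = (("chimp", 0.015), ("mouse", 0.05))
    variant_density_per_bp: float = 0.008
    contexts: tuple = ("K562", "Gm12878")
    tissues: tuple = ("adipose", "brain", "liver", "testis")
    seed: int = 0

    def __post_init__(self):
        fracs = (
            self.processed_frac,
            self.duplicated_frac,
            self.transcribed_frac,
            self.conserved_frac,
            self.active_chromatin_frac,
            self.pol2_frac,
            self.promoter_frac,
            self.dnase_frac,
        )
        if any(not (0 <= f <= 1) for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.processed_frac + self.duplicated_frac > 1:
            raise ValueError("biotype fractions must sum to <= 1")


@dataclass
class SimulatedCorpus:
    """Everything the pipeline consumes, plus the planted truth table."""

    config: SimulationConfig
    chrom_lengths: dict
    genes: list
    manual: list
    pipeA: list
    pipeB: list
    parent_candidates: dict
    sequences: dict  # id -> (pseudo_seq, parent_seq, parent_cds_len)
    est_evidence: dict
    total_rna: dict  # id -> (pseudo_cov, parent_cov)
    coverage: dict  # tissue -> chrom -> CoverageTrack
    parent_expression: dict  # id -> tissue -> float
    n_similar: dict
    segmentation: dict  # context -> SegmentationTrack
    pol2_peaks: dict
    cofactor_peaks: dict
    tf_peaks: dict
    parent_tf_peaks: dict  # context -> gene_id -> factor frozenset
    promoters: dict  # context -> list[GenomicInterval]
    dnase: dict  # context -> chrom -> CoverageTrack
    divergence: pd.DataFrame
    variants: pd.DataFrame
    truth: pd.DataFrame


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, zlib.crc32(stage.encode())])


# ---------------------------------------------------------------- annotation


def simulate_annotation(config: SimulationConfig):
    """Place non-overlapping loci and build the three caller call-sets.

    Returns (chrom_lengths, genes, manual, pipeA, pipeB, parent_candidates,
    truth_rows).  Slots are sized per locus kind with >=3.5 kb of clear
    flank; `n_near_coding` pseudogenes are deliberately placed < 4 kb from
    a coding TSS to exercise the upstream exclusion filter.
    """
    rng = _rng(config, "annotation")
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chromosomes)
    }
    n_pairs = min(config.n_near_coding, config.n_coding_genes, config.n_pseudogenes)
    slots = (
        [("pair", 16_000)] * n_pairs
        + [("gene", 11_000)] * (config.n_coding_genes - n_pairs)
        + [("pg", 10_000)] * (config.n_pseudogenes - n_pairs)
        + [("delta", 10_000)] * config.n_delta_two_way
        + [("aonly", 10_000)] * config.n_pipe_only
        + [("bonly", 10_000)] * config.n_pipe_only
    )
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    chroms = list(chrom_lengths)
    positions = []  # (kind, chrom, slot_start, slot_size)
    ci, pos = 0, 10_000
    for kind, size in slots:
        while ci < len(chroms) and pos + size > chrom_lengths[chroms[ci]] - _MARGIN:
            ci += 1
            pos = 10_000
        if ci >= len(chroms):
            raise ValueError(
                "cannot place loci without overlap at this density; "
                "increase chrom_length_bp or n_chromosomes"
            )
        positions.append((kind, chroms[ci], pos, size))
        pos += size

    genes, manual, pipeA, pipeB = [], [], [], []
    near_coding_ids = []
    gi = pi = 0

    def new_gene(chrom, start, strand=None, max_len=3500):
        nonlocal gi
        glen = int(rng.integers(1500, max_len))
        strand = strand or rng.choice(["+", "-"])
        gene = PseudogeneRecord(
            id=f"GENE{gi:04d}",
            locus=GenomicInterval(chrom, start, start + glen, str(strand)),
            biotype="coding",
        )
        gi += 1
        genes.append(gene)
        return gene

    def new_pg(chrom, start, strand=None):
        nonlocal pi
        plen = int(rng.integers(600, 3000))
        strand = strand or rng.choice(["+", "-"])
        pg = PseudogeneRecord(
            id=f"PG{pi:04d}",
            locus=GenomicInterval(chrom, start, start + plen, str(strand)),
        )
        pi += 1
        manual.append(pg)
        return pg

    decoy_records = {"delta": [], "aonly": [], "bonly": []}
    for kind, chrom, s, size in positions:
        anchor = s + _MARGIN
        if kind == "pair":
            # gene must end before the pseudogene starts at anchor + 2500
            gene = new_gene(chrom, anchor, strand="+", max_len=2400)
            pg = new_pg(chrom, anchor + 2500, strand="+")
            # distance pg 5' end to gene TSS = 2500 bp < 4 kb
            near_coding_ids.append(pg.id)
        elif kind == "gene":
            new_gene(chrom, anchor)
        elif kind == "pg":
            new_pg(chrom, anchor)
        else:
            plen = int(rng.integers(600, 3000))
            iv = GenomicInterval(chrom, anchor, anchor + plen, "+")
            decoy_records[kind].append(iv)

    # caller call-sets: level-1 loci recovered by both pipelines with
    # jittered boundaries; a fraction of level-2 loci get sub-threshold
    # (<50 bp overlap) decoy calls
    truth_rows = {}
    for pg in manual:
        level1 = rng.random() < config.level1_frac
        iv = pg.locus
        if level1:
            for target, tag in ((pipeA, "A"), (pipeB, "B")):
                j0, j1 = rng.integers(-200, 201, size=2)
                start = max(int(iv.start + j0), iv.start - 200)
                end = max(start + 60, int(iv.end + j1))
                target.append(
                    PseudogeneRecord(
                        id=f"{tag}-{pg.id}",
                        locus=GenomicInterval(iv.chrom, start, end, iv.strand),
                        caller=f"pipe{tag}",
                    )
                )
            level = "1"
        else:
            level = "2"
            if rng.random() < config.subthreshold_decoy_frac:
                # overlaps the manual locus by only 20 bp
                start = iv.end - 20
                pipeA.append(
                    PseudogeneRecord(
                        id=f"A-decoy-{pg.id}",
                        locus=GenomicInterval(iv.chrom, start, start + 300, iv.strand),
                        caller="pipeA",
                    )
                )
        truth_rows[pg.id] = {"id": pg.id, "level": level}

    for iv in decoy_records["delta"]:
        j = int(rng.integers(-100, 101))
        pipeA.append(
            PseudogeneRecord(
                id=f"A-2w-{iv.start}", locus=iv, caller="pipeA"
            )
        )
        pipeB.append(
            PseudogeneRecord(
                id=f"B-2w-{iv.start}",
                locus=GenomicInterval(iv.chrom, max(0, iv.start + j), iv.end + j, iv.strand),
                caller="pipeB",
            )
        )
    for iv in decoy_records["aonly"]:
        pipeA.append(PseudogeneRecord(id=f"A-only-{iv.start}", locus=iv, caller="pipeA"))
    for iv in decoy_records["bonly"]:
        pipeB.append(PseudogeneRecord(id=f"B-only-{iv.start}", locus=iv, caller="pipeB"))

    # biotypes: polymorphic_count sampled first, remainder split by fraction
    ids = [pg.id for pg in manual]
    poly = set(rng.choice(ids, size=config.polymorphic_count, replace=False))
    for pg in manual:
        if pg.id in poly:
            pg.biotype = "polymorphic"
        else:
            u = rng.random()
            if u < config.processed_frac:
                pg.biotype = "processed"
            elif u < config.processed_frac + config.duplicated_frac:
                pg.biotype = "duplicated"
            else:
                pg.biotype = "unitary"
        truth_rows[pg.id]["biotype"] = pg.biotype
        truth_rows[pg.id]["near_coding"] = pg.id in near_coding_ids

    # parent candidates by evidence source; highest-priority source is truth
    parent_candidates = {}
    gene_ids = [g.id for g in genes]
    for pg in manual:
        true_parent = str(rng.choice(gene_ids))
        cand = {"automated": true_parent}
        if rng.random() < 0.6:
            cand["manual"] = true_parent
        if rng.random() < 0.3:
            cand["alignment"] = true_parent
        if rng.random() < 0.1:  # automated curation disagrees
            cand["automated"] = str(rng.choice(gene_ids))
            cand.setdefault("manual", true_parent)
        for source in ("manual", "alignment", "automated"):
            if source in cand:
                truth_rows[pg.id]["parent"] = cand[source]
                break
        pg.parent_id = truth_rows[pg.id]["parent"]
        parent_candidates[pg.id] = cand
    return chrom_lengths, genes, manual, pipeA, pipeB, parent_candidates, truth_rows


# ----------------------------------------------------------------- sequences


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _mutate(rng, seq: str, target_identity: float) -> str:
    """Substitute evenly spaced positions so realized identity equals the
    target within a point even under window statistics."""
    n = len(seq)
    n_sub = int(round((1.0 - target_identity / 100.0) * n))
    if n_sub == 0:
        return seq
    positions = np.linspace(0, n - 1, n_sub).astype(int)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = str(rng.choice(choices))
    return "".join(out)


def simulate_sequences(manual, config: SimulationConfig, targets: dict | None = None):
    """Parent CDS+3'UTR sequences and mutated pseudogene copies.

    ``targets`` maps id -> (cds_identity, utr_identity) percent; ids not
    listed draw CDS targets from U(62, 98) and UTR from U(56, 94).
    Returns (sequences, realized_targets): sequences maps id ->
    (pseudo_seq, parent_seq, parent_cds_len).
    """
    rng = _rng(config, "sequences")
    targets = dict(targets or {})
    sequences = {}
    used_targets = {}
    for pg in manual:
        cds_len = int(rng.integers(400, 700))
        utr_len = int(rng.integers(300, 600))
        t_cds, t_utr = targets.get(
            pg.id,
            (float(rng.uniform(62, 98)), float(rng.uniform(56, 94))),
        )
        for t in (t_cds, t_utr):
            if not (0 <= t <= 100):
                raise ValueError("target identity must lie in [0, 100]")
        parent_cds = _random_seq(rng, cds_len)
        parent_utr = _random_seq(rng, utr_len)
        pseudo = _mutate(rng, parent_cds, t_cds) + _mutate(rng, parent_utr, t_utr)
        sequences[pg.id] = (pseudo, parent_cds + parent_utr, cds_len)
        used_targets[pg.id] = (t_cds, t_utr)
    return sequences, used_targets


# ------------------------------------------------------------------ coverage


def _planted_subsets(config: SimulationConfig, truth_rows: dict):
    """Draw the planted activity subsets from the surveyed ids."""
    rng = _rng(config, "subsets")
    surveyed = [
        r["id"]
        for r in truth_rows.values()
        if r["level"] in {"1", "2"} and r["biotype"] != "polymorphic"
    ]
    n = len(surveyed)
    transcribed = sorted(
        rng.choice(surveyed, size=int(round(config.transcribed_frac * n)), replace=False)
    )
    sources = ["EST", "TotalRNA", "BodyMap"]
    evidence = {pid: sources[i % 3] for i, pid in enumerate(transcribed)}
    conserved = sorted(
        rng.choice(surveyed, size=int(round(config.conserved_frac * n)), replace=False)
    )
    # active chromatin is enriched in transcribed pseudogenes, as observed
    # in real segmentation data; the bias plants that dependence
    n_chrom = int(round(config.active_chromatin_frac * n))
    non_transcribed = [p for p in surveyed if p not in set(transcribed)]
    n_from_t = min(
        int(round(config.chromatin_transcribed_bias * n_chrom)), len(transcribed)
    )
    chromatin = sorted(
        list(rng.choice(list(transcribed), size=n_from_t, replace=False))
        + list(rng.choice(non_transcribed, size=n_chrom - n_from_t, replace=False))
    )
    criterion = {pid: 1 if i % 2 == 0 else 2 for i, pid in enumerate(chromatin)}
    eligible = [
        pid for pid in surveyed if not truth_rows[pid]["near_coding"]
    ]
    non_transcribed_eligible = [p for p in eligible if p not in set(transcribed)]
    transcribed_eligible = [p for p in eligible if p in set(transcribed)]

    def _context_sets(frac, bias_to_transcribed, stream):
        r = _rng(config, stream)
        n_active = int(round(frac * n))
        n_from_t = min(int(round(bias_to_transcribed * n_active)), len(transcribed_eligible))
        base_t = list(r.choice(transcribed_eligible, size=n_from_t, replace=False))
        base_nt = list(
            r.choice(non_transcribed_eligible, size=n_active - n_from_t, replace=False)
        )
        pool = base_t + base_nt
        n_shared = int(round(config.shared_context_frac * n_active))
        shared = pool[:n_shared]
        rest = [p for p in eligible if p not in set(pool)]
        sets = {}
        per_ctx_extra = n_active - n_shared
        offset = 0
        for ctx in config.contexts:
            extra = rest[offset : offset + per_ctx_extra]
            offset += per_ctx_extra
            sets[ctx] = sorted(set(shared) | set(extra))
        return sets

    pol2 = _context_sets(config.pol2_frac, config.pol2_transcribed_bias, "pol2-sets")
    promoter = _context_sets(config.promoter_frac, 0.4, "promoter-sets")
    dnase = sorted(
        rng.choice(surveyed, size=int(round(config.dnase_frac * n)), replace=False)
    )
    pol2_criterion = {}
    for ctx, ids in pol2.items():
        for i, pid in enumerate(sorted(ids)):
            pol2_criterion[(ctx, pid)] = 12 if i % 2 == 0 else 3
    return {
        "surveyed": surveyed,
        "transcribed": list(transcribed),
        "evidence": evidence,
        "conserved": list(conserved),
        "chromatin": list(chromatin),
        "chromatin_criterion": criterion,
        "pol2": pol2,
        "pol2_criterion": pol2_criterion,
        "promoter": promoter,
        "dnase": list(dnase),
    }


def simulate_coverage(manual, chrom_lengths, config: SimulationConfig, subsets):
    """Per-tissue coverage tracks plus parent expression profiles.

    BodyMap-planted pseudogenes are covered at depth >= 2 over 70% of their
    length in at least one tissue, with a graded multi-tissue profile;
    their parent expression profile is rank-reversed (discordance 1.0) or
    identical (0.0).  Everything else gets `noise_depth` background.
    """
    rng = _rng(config, "coverage")
    tissues = list(config.tissues)
    coverage = {
        t: {
            c: np.zeros(n, dtype=np.int16)
            for c, n in chrom_lengths.items()
        }
        for t in tissues
    }
    parent_expression = {}
    n_similar = {}
    est_evidence = {}
    total_rna = {}
    evidence = subsets["evidence"]
    bodymap_ids = [p for p, s in evidence.items() if s == "BodyMap"]
    ranks = np.array([float(config.coverage_depth), 2.0, 1.0, 0.0])

    for i, pg in enumerate(manual):
        pid = pg.id
        source = evidence.get(pid)
        # similarity-hit structure: alternate 0 hits / >=1 hit for BodyMap
        # ids so both arms of the discordance guard are exercised
        if source == "BodyMap":
            n_similar[pid] = 0 if bodymap_ids.index(pid) % 2 == 0 else int(rng.integers(1, 6))
        else:
            n_similar[pid] = int(rng.integers(0, 7))
        # EST pipeline input
        if source == "EST":
            est_evidence[pid] = [(True, True)]
        else:
            est_evidence[pid] = [(True, False)] if rng.random() < 0.4 else []
        # total RNA pipeline input
        if source == "TotalRNA":
            total_rna[pid] = (float(rng.integers(5, 50)), 0.0)
        else:
            total_rna[pid] = (0.0, float(rng.integers(0, 50)))
        # BodyMap tracks
        order = rng.permutation(len(tissues))
        profile = {tissues[j]: ranks[k] for k, j in enumerate(order)}
        if source == "BodyMap":
            iv = pg.locus
            covered = int(config.covered_frac * iv.length)
            for t in tissues:
                depth = int(profile[t])
                if depth > 0:
                    coverage[t][iv.chrom][iv.start : iv.start + covered] = depth
            if config.discordance >= 0.5:
                parent_expression[pid] = {
                    tissues[j]: float(ranks[::-1][k]) for k, j in enumerate(order)
                }
            else:
                parent_expression[pid] = {t: float(v) for t, v in profile.items()}
        else:
            parent_expression[pid] = {t: float(rng.uniform(0, 2)) for t in tissues}
        if config.noise_depth > 0 and source != "BodyMap":
            iv = pg.locus
            frac = min(0.4, config.covered_frac)  # stays below the half-length rule
            covered = int(frac * iv.length)
            t = tissues[int(rng.integers(len(tissues)))]
            coverage[t][iv.chrom][iv.start : iv.start + covered] = int(config.noise_depth)

    tracks = {
        t: {c: CoverageTrack(chrom=c, values=v, tissue=t) for c, v in per.items()}
        for t, per in coverage.items()
    }
    return tracks, parent_expression, n_similar, est_evidence, total_rna


# ------------------------------------------------------- functional genomics


def evaluation_region(record: PseudogeneRecord, upstream_bp: int = 2000) -> GenomicInterval:
    """Locus span plus the strand-aware 2 kb upstream strip (the region over
    which segmentation label frequencies are evaluated)."""
    iv = record.locus
    if iv.effective_strand() == "+":
        return GenomicInterval(iv.chrom, max(0, iv.start - upstream_bp), iv.end, iv.strand)
    return GenomicInterval(iv.chrom, iv.start, iv.end + upstream_bp, iv.strand)


def _upstream_span(record: PseudogeneRecord, length: int = 2000) -> tuple[int, int]:
    fp = record.five_prime_end
    if record.locus.effective_strand() == "+":
        return max(0, fp - length), fp
    return fp + 1, fp + 1 + length


def simulate_null_pol2_peaks(n: int, rng: np.random.Generator, chrom: str = "chr1") -> list[Peak]:
    """Background Pol2 peaks: lognormal widths with signal a fixed monotone
    function of width (signal = width/250), mimicking the strong
    width-signal dependence of real Pol2 peaks."""
    widths = np.exp(rng.normal(np.log(180.0), 0.35, size=n))
    widths = np.maximum(widths.astype(int), 30)
    starts = rng.integers(0, 1_000_000, size=n)
    return [
        Peak(
            region=GenomicInterval(chrom, int(s), int(s + w)),
            factor="Pol2",
            signal=float(w) / 250.0,
        )
        for s, w in zip(starts, widths)
    ]


def simulate_functional_genomics(genes, manual, chrom_lengths, config: SimulationConfig, subsets):
    """Segmentations, peak sets, promoter regions and DNase tracks.

    Chromatin-planted loci get a TSS-rich (criterion 1) or gene-body-rich
    (criterion 2) layout over locus+2kb-upstream; Pol2-planted loci get a
    wide strong peak (criteria 1+2) or a cofactor peak (criterion 3) in
    the upstream window; promoter-planted loci an overlapping promoter
    region; DNase-planted loci an accessibility bump at the 5' end.
    """
    label_list = sorted(SEGMENTATION_LABELS)
    label_index = {lab: i for i, lab in enumerate(label_list)}
    rep_labels = sorted(REPRESSIVE_LABELS)

    segmentation, pol2_peaks, cofactor_peaks, tf_peaks = {}, {}, {}, {}
    promoters, dnase, parent_tf = {}, {}, {}
    chromatin_ids = set(subsets["chromatin"])
    criterion = subsets["chromatin_criterion"]
    transcribed = set(subsets["transcribed"])
    dnase_ids = set(subsets["dnase"])
    genes_by_id = {g.id: g for g in genes}
    retained_truth = {}

    for ctx in config.contexts:
        rng = _rng(config, f"fg-{ctx}")
        # --- segmentation: repressive background + planted active layouts
        arrays = {}
        for chrom, length in chrom_lengths.items():
            arr = np.empty(length, dtype=np.uint8)
            pos = 0
            while pos < length:
                seg_len = int(rng.integers(500, 3000))
                arr[pos : pos + seg_len] = label_index[
                    rep_labels[int(rng.integers(len(rep_labels)))]
                ]
                pos += seg_len
            # reserved strip keeps every label present genome-wide
            for i, lab in enumerate(label_list):
                s = 320 * i
                arr[s : s + 320] = label_index[lab]
            arrays[chrom] = arr
        for pg in manual:
            if pg.id not in chromatin_ids:
                continue
            region = evaluation_region(pg)
            arr = arrays[region.chrom]
            n = region.length
            s = region.start
            if criterion[pg.id] == 1:
                arr[s : s + int(0.3 * n)] = label_index["TSS"]
                arr[s + int(0.3 * n) : s + n] = label_index["LOW"]
            else:
                b = [int(0.2 * n), int(0.4 * n), int(0.6 * n), int(0.7 * n)]
                arr[s : s + b[0]] = label_index["GS"]
                arr[s + b[0] : s + b[1]] = label_index["GM"]
                arr[s + b[1] : s + b[2]] = label_index["GE"]
                arr[s + b[2] : s + b[3]] = label_index["e/GM"]
                arr[s + b[3] : s + n] = label_index["LOW"]
        segments = []
        for chrom, arr in arrays.items():
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for st, en in zip(starts, ends):
                segments.append(
                    (GenomicInterval(chrom, int(st), int(en)), label_list[arr[st]])
                )
        segmentation[ctx] = SegmentationTrack(segments=segments, context=ctx)

        # --- Pol2 / cofactor peaks
        p2, cf = [], []
        pol2_ids = set(subsets["pol2"][ctx])
        for pg in manual:
            lo, hi = _upstream_span(pg)
            chrom = pg.locus.chrom
            center = (lo + hi) // 2
            if pg.id in pol2_ids:
                if subsets["pol2_criterion"][(ctx, pg.id)] == 12:
                    p2.append(
                        Peak(GenomicInterval(chrom, center - 300, center + 300), "Pol2", 3.0)
                    )
                else:
                    cof = _COFACTORS[int(rng.integers(len(_COFACTORS)))]
                    cf.append(
                        Peak(GenomicInterval(chrom, center - 100, center + 100), cof, 1.5)
                    )
                    p2.append(
                        Peak(GenomicInterval(chrom, center - 75, center + 75), "Pol2", 0.5)
                    )
            elif rng.random() < 0.5:
                w = int(np.clip(np.exp(rng.normal(np.log(180.0), 0.35)), 50, 500))
                s0 = int(rng.integers(lo, max(lo + 1, hi - w)))
                p2.append(Peak(GenomicInterval(chrom, s0, s0 + w), "Pol2", w / 250.0))
        pol2_peaks[ctx], cofactor_peaks[ctx] = p2, cf

        # --- TF peaks for the pseudogenes and their parents
        tfs = []
        parent_factors: dict[str, frozenset] = {}
        for pg in manual:
            lo, hi = _upstream_span(pg)
            chrom = pg.locus.chrom
            lam = 3.0 if pg.id in transcribed else 0.7
            n_peaks = int(rng.poisson(lam))
            factors = []
            for _ in range(n_peaks):
                w = int(rng.integers(150, 400))
                s0 = int(rng.integers(lo, max(lo + 1, hi - w)))
                fac = _TF_FACTORS[int(rng.integers(len(_TF_FACTORS)))]
                factors.append(fac)
                tfs.append(Peak(GenomicInterval(chrom, s0, s0 + w), fac, 1.0))
            # parent upstream: duplicated pseudogenes may retain the
            # parent's factors (the retention proxy)
            retained = pg.biotype == "duplicated" and bool(factors) and rng.random() < 0.7
            parent = genes_by_id.get(pg.parent_id)
            if parent is not None:
                pf = set(parent_factors.get(parent.id, frozenset()))
                if retained:
                    pf.update(factors)
                parent_factors[parent.id] = frozenset(pf)
            retained_truth[(ctx, pg.id)] = retained
        for gene in genes:
            glo, ghi = _upstream_span(gene)
            for fac in parent_factors.get(gene.id, frozenset()):
                w = int(rng.integers(150, 400))
                s0 = int(rng.integers(glo, max(glo + 1, ghi - w)))
                tfs.append(Peak(GenomicInterval(gene.locus.chrom, s0, s0 + w), fac, 1.0))
        tf_peaks[ctx] = tfs
        parent_tf[ctx] = parent_factors

        # --- promoter regions
        proms = []
        for pg in manual:
            if pg.id in set(subsets["promoter"][ctx]):
                lo, hi = _upstream_span(pg)
                proms.append(GenomicInterval(pg.locus.chrom, lo + 500, lo + 1500))
        promoters[ctx] = proms

        # --- DNase accessibility tracks
        tracks = {}
        for chrom, length in chrom_lengths.items():
            tracks[chrom] = np.full(length, 0.1, dtype=np.float32)
        for gene in genes:
            fp = gene.five_prime_end
            arr = tracks[gene.locus.chrom]
            lo, hi = max(0, fp - 1500), min(arr.size, fp + 1500)
            arr[lo:hi] += 3.0
        for pg in manual:
            fp = pg.five_prime_end
            arr = tracks[pg.locus.chrom]
            lo, hi = max(0, fp - 1500), min(arr.size, fp + 1500)
            if pg.id in dnase_ids:
                arr[lo:hi] += 2.0
            if pg.id in transcribed:
                arr[lo:hi] += 0.3
        dnase[ctx] = {
            c: CoverageTrack(chrom=c, values=v, tissue=ctx) for c, v in tracks.items()
        }
    return segmentation, pol2_peaks, cofactor_peaks, tf_peaks, parent_tf, promoters, dnase, retained_truth


# ------------------------------------------------------ divergence, variants


def simulate_divergence_and_variants(manual, config: SimulationConfig, subsets):
    """Ortholog substitution counts under the Poisson null (conserved ids at
    a reduced rate) and population variants with a configured DAF spectrum."""
    rng = _rng(config, "divergence")
    conserved = set(subsets["conserved"])
    aligned_frac = dict(config.aligned_frac)
    rates = dict(config.background_rates)
    div_rows = []
    for pg in manual:
        L = pg.locus.length
        for species, rate in rates.items():
            aligned = int(
                np.clip(rng.normal(aligned_frac[species], 0.02), 0.05, 1.0) * L
            )
            lam = rate * L * (config.conserved_multiplier if pg.id in conserved else 1.0)
            subs = min(int(rng.poisson(lam)), aligned)
            div_rows.append(
                {
                    "pseudogene_id": pg.id,
                    "species": species,
                    "aligned_bp": aligned,
                    "substitutions": subs,
                    "length": L,
                }
            )
    rng_v = _rng(config, "variants")
    var_rows = []
    vclasses = np.array(["SNP", "indel", "SV"])
    for pg in manual:
        iv = pg.locus
        n_var = int(rng_v.poisson(config.variant_density_per_bp * iv.length))
        for _ in range(n_var):
            pos = int(rng_v.integers(iv.start, iv.end))
            vclass = str(rng_v.choice(vclasses, p=[0.85, 0.10, 0.05]))
            daf = float(rng_v.beta(0.4, 1.2))
            var_rows.append(
                {
                    "chrom": iv.chrom,
                    "start": pos,
                    "end": pos + 1,
                    "vclass": vclass,
                    "daf": daf,
                    "pseudogene_id": pg.id,
                }
            )
    return pd.DataFrame(div_rows), pd.DataFrame(var_rows)


# ------------------------------------------------------------------ corpus


def simulate_corpus(config: SimulationConfig | None = None) -> SimulatedCorpus:
    """Run every generator stage and assemble the truth table."""
    config = config or SimulationConfig()
    (
        chrom_lengths,
        genes,
        manual,
        pipeA,
        pipeB,
        parent_candidates,
        truth_rows,
    ) = simulate_annotation(config)
    subsets = _planted_subsets(config, truth_rows)
    sequences, targets = simulate_sequences(manual, config)
    coverage, parent_expression, n_similar, est_evidence, total_rna = simulate_coverage(
        manual, chrom_lengths, config, subsets
    )
    (
        segmentation,
        pol2_peaks,
        cofactor_peaks,
        tf_peaks,
        parent_tf,
        promoters,
        dnase,
        retained_truth,
    ) = simulate_functional_genomics(genes, manual, chrom_lengths, config, subsets)
    divergence, variants = simulate_divergence_and_variants(manual, config, subsets)

    transcribed = set(subsets["transcribed"])
    conserved = set(subsets["conserved"])
    chromatin = set(subsets["chromatin"])
    dnase_ids = set(subsets["dnase"])
    for pid, row in truth_rows.items():
        surveyed = row["level"] in {"1", "2"} and row["biotype"] != "polymorphic"
        row["surveyed"] = surveyed
        row["transcribed"] = surveyed and pid in transcribed
        row["evidence"] = subsets["evidence"].get(pid, "") if row["transcribed"] else ""
        row["n_similar"] = n_similar.get(pid, 0)
        row["conserved"] = surveyed and pid in conserved
        row["chromatin_active"] = surveyed and pid in chromatin
        row["chromatin_criterion"] = (
            subsets["chromatin_criterion"].get(pid, 0) if row["chromatin_active"] else 0
        )
        row["dnase"] = surveyed and pid in dnase_ids
        row["cds_target"], row["utr_target"] = targets[pid]
        for ctx in config.contexts:
            row[f"pol2_{ctx}"] = surveyed and pid in set(subsets["pol2"][ctx])
            row[f"pol2_criterion_{ctx}"] = (
                subsets["pol2_criterion"].get((ctx, pid), 0) if row[f"pol2_{ctx}"] else 0
            )
            row[f"promoter_{ctx}"] = surveyed and pid in set(subsets["promoter"][ctx])
            row[f"retained_{ctx}"] = bool(retained_truth.get((ctx, pid), False))
    truth = pd.DataFrame(sorted(truth_rows.values(), key=lambda r: r["id"]))

    return SimulatedCorpus(
        config=config,
        chrom_lengths=chrom_lengths,
        genes=genes,
        manual=manual,
        pipeA=pipeA,
        pipeB=pipeB,
        parent_candidates=parent_candidates,
        sequences=sequences,
        est_evidence=est_evidence,
        total_rna=total_rna,
        coverage=coverage,
        parent_expression=parent_expression,
        n_similar=n_similar,
        segmentation=segmentation,
        pol2_peaks=pol2_peaks,
        cofactor_peaks=cofactor_peaks,
        tf_peaks=tf_peaks,
        parent_tf_peaks=parent_tf,
        promoters=promoters,
        dnase=dnase,
        divergence=divergence,
        variants=variants,
        truth=truth,
    )
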