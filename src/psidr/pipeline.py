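"""End-to-end decoration: consensus -> parents -> identity -> transcription
-> conservation -> chromatin -> upstream regulation -> psiDR assembly.

`decorate_corpus` runs the whole pipeline on an in-memory synthetic corpus
(or any object exposing the same attributes) and returns a
:class:`DecorationSet` with the per-context records, per-stage summaries
and the specificity matrices.  `write_corpus`/`read_corpus` round-trip a
corpus through the on-disk formats the readers in :mod:`psidr.io` accept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .chromatin import (
    call_active_chromatin,
    dnase_accessible,
    genome_label_fractions,
    label_frequencies,
)
from .consensus import assign_levels, surveyed_set
from .constraint import conservation_pipeline, daf_spectra
from .datamodel import DecorationRecord, GenomicInterval, Thresholds
from .integrate import (
    classify_partial_activity,
    decorate,
    parent_upstream_retained,
    specificity_matrix,
)
from .parent import (
    align_pair,
    assign_parent,
    cds_identity,
    classify_identity_group,
    utr3_window_identity,
)
from .regulation import (
    RegulationCall,
    call_pol2_active,
    call_promoter_active,
    count_tfbs,
    filter_near_coding_tss,
    upstream_window,
)
from .simulate import SimulatedCorpus, SimulationConfig, evaluation_region
from .transcription import call_bodymap, call_est, call_total_rna, merge_calls

__all__ = ["DecorationSet", "decorate_corpus", "write_corpus", "read_corpus"]


@dataclass
class DecorationSet:
    """Pipeline output: psiDR records per context plus reporting tables."""

    records: dict  # context -> list[DecorationRecord]
    levels: list
    surveyed: list
    identity: pd.DataFrame
    transcription: dict
    conservation: dict  # id -> bool
    daf_comparisons: dict
    partial_activity: dict  # context -> id -> label
    pol2_matrix: pd.DataFrame | None
    promoter_matrix: pd.DataFrame | None
    summary: dict = field(default_factory=dict)


def _transcription_calls(corpus, surveyed, identity_pct, thresholds: Thresholds):
    calls = {}
    for rec in surveyed:
        pid = rec.id
        est = call_est(corpus.est_evidence.get(pid, []))
        pseudo_cov, parent_cov = corpus.total_rna.get(pid, (0.0, 0.0))
        total = call_total_rna(pseudo_cov, parent_cov, identity_pct.get(pid, 100.0))
        iv = rec.locus
        per_tissue = {
            tissue: tracks[iv.chrom].values[iv.start : iv.end]
            for tissue, tracks in corpus.coverage.items()
        }
        bodymap, tissues = call_bodymap(
            per_tissue,
            corpus.n_similar.get(pid, 0),
            corpus.parent_expression.get(pid),
            min_depth=thresholds.bodymap_min_depth,
            min_frac=thresholds.bodymap_min_frac,
            discordance_max_spearman=thresholds.discordance_max_spearman,
        )
        calls[pid] = merge_calls(pid, est, total, bodymap, tissues)
    return calls


def decorate_corpus(corpus: SimulatedCorpus, thresholds: Thresholds | None = None) -> DecorationSet:
    th = thresholds or Thresholds()
    cfg = corpus.config

    # 1. consensus levels and the surveyed set
    levels = assign_levels(corpus.manual, corpus.pipeA, corpus.pipeB, th.consensus_overlap_bp)
    surveyed = surveyed_set(corpus.manual, levels)

    # 2. parent assignment and sequence identity
    identity_rows = []
    identity_pct = {}
    identity_class = {}
    parent_info = {}
    genes_by_id = {g.id: g for g in corpus.genes}
    for rec in surveyed:
        parent_id, source = assign_parent(corpus.parent_candidates.get(rec.id, {}))
        rec.parent_id, rec.parent_source = parent_id, source
        parent = genes_by_id.get(parent_id)
        parent_info[rec.id] = {
            "protein_id": f"{parent_id}.p" if parent_id else ".",
            "gene_id": parent_id or ".",
            "locus": parent.locus if parent else None,
        }
        seqs = corpus.sequences.get(rec.id)
        if seqs is None:
            continue
        pseudo, parent_seq, cds_len = seqs
        pair = align_pair(pseudo, parent_seq, cds_len, rec.id, parent_id or "")
        cid = cds_identity(pair)
        uid = utr3_window_identity(pair, th.utr_window_bp)
        group = classify_identity_group(cid, uid, th.identity_low, th.identity_high)
        identity_pct[rec.id] = cid
        identity_class[rec.id] = group.group
        identity_rows.append(
            {
                "pseudogene_id": rec.id,
                "parent_id": parent_id,
                "cds_identity": cid,
                "utr3_identity": uid,
                "group": group.group,
            }
        )
    identity = pd.DataFrame(identity_rows)

    # 3. transcription (OR over the three evidence pipelines)
    transcription = _transcription_calls(corpus, surveyed, identity_pct, th)

    # 4. conservation + DAF spectra
    surveyed_ids = {r.id for r in surveyed}
    div = corpus.divergence[corpus.divergence.pseudogene_id.isin(surveyed_ids)]
    rates = {"chimp": th.background_rate_chimp, "mouse": th.background_rate_mouse}
    _, conserved = conservation_pipeline(div, rates=rates, fdr=th.fdr)
    transcribed_ids = {pid for pid, c in transcription.items() if c.transcribed}
    daf_groups = {}
    if len(corpus.variants):
        var = corpus.variants[corpus.variants.pseudogene_id.isin(surveyed_ids)]
        for vclass in ("SNP", "indel", "SV"):
            sub = var[var.vclass == vclass]
            t_mask = sub.pseudogene_id.isin(transcribed_ids)
            daf_groups[f"{vclass}/transcribed"] = sub.daf[t_mask].to_numpy()
            daf_groups[f"{vclass}/non-transcribed"] = sub.daf[~t_mask].to_numpy()
    _, daf_comparisons = daf_spectra(daf_groups) if daf_groups else ({}, {})

    # 5-7. per-context chromatin, DNase and upstream-regulation calls
    coding_tss = [(g.locus.chrom, g.five_prime_end) for g in corpus.genes]
    kept, excluded = filter_near_coding_tss(surveyed, coding_tss, th.coding_tss_exclusion_bp)
    excluded_ids = {r.id for r in excluded}
    records_by_ctx = {}
    partial_by_ctx = {}
    pol2_sets, promoter_sets = {}, {}
    chromatin_by_ctx = {}
    for ctx in cfg.contexts:
        seg = corpus.segmentation[ctx]
        genome_fracs = genome_label_fractions(seg)
        chromatin_calls = {}
        for rec in surveyed:
            freqs = label_frequencies(seg, evaluation_region(rec, th.upstream_bp), genome_fracs)
            active, _crit = call_active_chromatin(
                freqs, th.tss_ratio, th.genebody_ratio
            )
            chromatin_calls[rec.id] = active
        chromatin_by_ctx[ctx] = chromatin_calls
        dnase_tracks = corpus.dnase[ctx]
        genome_mean = float(
            np.mean([np.asarray(t.values).mean() for t in dnase_tracks.values()])
        )
        dnase_calls = {
            rec.id: dnase_accessible(
                dnase_tracks,
                (rec.locus.chrom, rec.five_prime_end),
                th.profile_halfwindow_bp,
                th.dnase_fold,
                genome_mean,
            )
            for rec in surveyed
        }
        regulation = {}
        pol2 = corpus.pol2_peaks[ctx]
        cof = corpus.cofactor_peaks[ctx]
        tfs = corpus.tf_peaks[ctx]
        chrom_len = corpus.chrom_lengths
        for rec in surveyed:
            if rec.id in excluded_ids:
                regulation[rec.id] = RegulationCall(
                    rec.id, ctx, excluded_near_coding_tss=True
                )
                continue
            window = upstream_window(rec, th.upstream_bp, chrom_len.get(rec.locus.chrom))
            n_tf, factors = count_tfbs(tfs, window)
            p_active, p_crit = call_pol2_active(
                pol2, cof, window, th.pol2_width_bp, th.pol2_signal, th.cofactors
            )
            regulation[rec.id] = RegulationCall(
                rec.id,
                ctx,
                tfbs_count=n_tf,
                factors=factors,
                pol2_active=p_active,
                pol2_criterion=p_crit,
                promoter_active=call_promoter_active(corpus.promoters[ctx], window),
            )
        records = decorate(
            surveyed,
            ctx,
            parent_info=parent_info,
            identity_class=identity_class,
            transcription=transcription,
            conserved=conserved,
            chromatin=chromatin_calls,
            dnase=dnase_calls,
            regulation=regulation,
        )
        records_by_ctx[ctx] = records
        pol2_sets[ctx] = {r.pseudogene_id for r in records if r.active_pol2}
        promoter_sets[ctx] = {r.pseudogene_id for r in records if r.active_promoter}

        # partial-activity classification needs the retention proxy
        parent_factors = corpus.parent_tf_peaks.get(ctx, {})
        partial = {}
        for rec, dr in zip(surveyed, records):
            reg = regulation[rec.id]
            retained = parent_upstream_retained(
                rec.biotype, reg.factors, parent_factors.get(rec.parent_id, frozenset())
            )
            partial[rec.id] = classify_partial_activity(dr, retained).label
        partial_by_ctx[ctx] = partial

    pol2_mat = specificity_matrix(pol2_sets) if len(pol2_sets) >= 2 else None
    prom_mat = specificity_matrix(promoter_sets) if len(promoter_sets) >= 2 else None

    summary = {
        "n_manual": len(corpus.manual),
        "n_level1": sum(1 for a in levels if a.level == "1"),
        "n_level2": sum(1 for a in levels if a.level == "2"),
        "n_delta_2way": sum(1 for a in levels if a.level == "delta-2way"),
        "n_surveyed": len(surveyed),
        "n_transcribed": len(transcribed_ids),
        "n_conserved": sum(bool(v) for v in conserved.values()),
        "n_excluded_near_coding_tss": len(excluded_ids),
        "n_active_chromatin": {
            ctx: sum(bool(v) for v in calls.values())
            for ctx, calls in chromatin_by_ctx.items()
        },
        "n_pol2_active": {ctx: len(s) for ctx, s in pol2_sets.items()},
        "n_promoter_active": {ctx: len(s) for ctx, s in promoter_sets.items()},
        "partial_activity_counts": {
            ctx: pd.Series(list(v.values())).value_counts().to_dict()
            for ctx, v in partial_by_ctx.items()
        },
    }
    return DecorationSet(
        records=records_by_ctx,
        levels=levels,
        surveyed=surveyed,
        identity=identity,
        transcription=transcription,
        conservation=conserved,
        daf_comparisons=daf_comparisons,
        partial_activity=partial_by_ctx,
        pol2_matrix=pol2_mat,
        promoter_matrix=prom_mat,
        summary=summary,
    )


# ------------------------------------------------------------- corpus on disk


def write_corpus(corpus: SimulatedCorpus, outdir) -> None:
    """Write every pipeline input in its standard on-disk format."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = corpus.config
    pio.write_annotation(corpus.genes + corpus.manual, out / "annotation.gtf", "GTF")
    pio.write_annotation(corpus.pipeA, out / "pipeA.bed", "BED")
    pio.write_annotation(corpus.pipeB, out / "pipeB.bed", "BED")
    with open(out / "sequences.fa", "w") as fh:
        for pid, (pseudo, parent, cds_len) in corpus.sequences.items():
            fh.write(f">{pid}|pseudo\n{pseudo}\n>{pid}|parent cds_len={cds_len}\n{parent}\n")
    for tissue, tracks in corpus.coverage.items():
        pio.write_bedgraph(tracks, out / f"coverage_{tissue}.bedgraph")
    for ctx in cfg.contexts:
        pio.write_segmentation(corpus.segmentation[ctx], out / f"segmentation_{ctx}.bed")
        pio.write_narrowpeak(corpus.pol2_peaks[ctx], out / f"pol2_{ctx}.narrowPeak")
        pio.write_narrowpeak(corpus.cofactor_peaks[ctx], out / f"cofactors_{ctx}.narrowPeak")
        pio.write_narrowpeak(corpus.tf_peaks[ctx], out / f"tfs_{ctx}.narrowPeak")
        with open(out / f"promoters_{ctx}.bed", "w") as fh:
            for iv in corpus.promoters[ctx]:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tpromoter\n")
        pio.write_bedgraph(corpus.dnase[ctx], out / f"dnase_{ctx}.bedgraph")
    corpus.divergence.to_csv(out / "divergence.tsv", sep="\t", index=False)
    corpus.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
    corpus.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    aux = {
        "chrom_lengths": corpus.chrom_lengths,
        "parent_candidates": corpus.parent_candidates,
        "est_evidence": {k: [list(map(bool, t)) for t in v] for k, v in corpus.est_evidence.items()},
        "total_rna": {k: list(v) for k, v in corpus.total_rna.items()},
        "parent_expression": corpus.parent_expression,
        "n_similar": corpus.n_similar,
        "parent_tf_peaks": {
            ctx: {g: sorted(f) for g, f in per.items()}
            for ctx, per in corpus.parent_tf_peaks.items()
        },
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(cfg).items()
        },
    }
    with open(out / "corpus.yaml", "w") as fh:
        yaml.safe_dump(aux, fh, default_flow_style=None, sort_keys=True)


def read_corpus(indir) -> SimulatedCorpus:
    """Reconstruct a corpus from the files written by :func:`write_corpus`."""
    ind = Path(indir)
    with open(ind / "corpus.yaml") as fh:
        aux = yaml.safe_load(fh)
    raw_cfg = aux["config"]
    cfg = SimulationConfig(
        **{
            k: (tuple(tuple(x) if isinstance(x, list) else x for x in v) if isinstance(v, list) else v)
            for k, v in raw_cfg.items()
        }
    )
    chrom_lengths = {str(k): int(v) for k, v in aux["chrom_lengths"].items()}
    annotation = pio.read_annotation(ind / "annotation.gtf", "GTF")
    genes = [r for r in annotation if r.biotype == "coding"]
    manual = [r for r in annotation if r.biotype != "coding"]
    pipeA = pio.read_annotation(ind / "pipeA.bed", "BED")
    pipeB = pio.read_annotation(ind / "pipeB.bed", "BED")
    sequences = {}
    with open(ind / "sequences.fa") as fh:
        entries = {}
        name = None
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:]
                entries[name] = ""
            else:
                entries[name] += line
    for header, seq in entries.items():
        pid, _, rest = header.partition("|")
        if rest.startswith("pseudo"):
            sequences.setdefault(pid, ["", "", 0])[0] = seq
        else:
            cds_len = int(rest.split("cds_len=")[1])
            entry = sequences.setdefault(pid, ["", "", 0])
            entry[1], entry[2] = seq, cds_len
    sequences = {k: tuple(v) for k, v in sequences.items()}
    coverage = {
        t: pio.read_bedgraph(ind / f"coverage_{t}.bedgraph", chrom_lengths, t)
        for t in cfg.tissues
    }
    segmentation, pol2_peaks, cofactor_peaks, tf_peaks, promoters, dnase = (
        {}, {}, {}, {}, {}, {},
    )
    for ctx in cfg.contexts:
        segmentation[ctx] = pio.read_segmentation(ind / f"segmentation_{ctx}.bed", ctx)
        pol2_peaks[ctx] = pio.read_narrowpeak(ind / f"pol2_{ctx}.narrowPeak")
        cofactor_peaks[ctx] = pio.read_narrowpeak(ind / f"cofactors_{ctx}.narrowPeak")
        tf_peaks[ctx] = pio.read_narrowpeak(ind / f"tfs_{ctx}.narrowPeak")
        proms = []
        with open(ind / f"promoters_{ctx}.bed") as fh:
            for line in fh:
                f = line.split("\t")
                proms.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
        promoters[ctx] = proms
        dnase[ctx] = pio.read_bedgraph(ind / f"dnase_{ctx}.bedgraph", chrom_lengths, ctx)
    return SimulatedCorpus(
        config=cfg,
        chrom_lengths=chrom_lengths,
        genes=genes,
        manual=manual,
        pipeA=pipeA,
        pipeB=pipeB,
        parent_candidates=aux["parent_candidates"],
        sequences=sequences,
        est_evidence={
            k: [tuple(t) for t in v] for k, v in aux["est_evidence"].items()
        },
        total_rna={k: tuple(v) for k, v in aux["total_rna"].items()},
        coverage=coverage,
        parent_expression=aux["parent_expression"],
        n_similar=aux["n_similar"],
        segmentation=segmentation,
        pol2_peaks=pol2_peaks,
        cofactor_peaks=cofactor_peaks,
        tf_peaks=tf_peaks,
        parent_tf_peaks={
            ctx: {g: frozenset(f) for g, f in per.items()}
            for ctx, per in aux.get("parent_tf_peaks", {}).items()
        },
        promoters=promoters,
        dnase=dnase,
        divergence=pio.read_divergence(ind / "divergence.tsv"),
        variants=pd.read_csv(ind / "variants.tsv", sep="\t"),
        truth=pd.read_csv(ind / "truth.tsv", sep="\t"),
    )
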