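"""End-to-end wiring: annotation -> bias/coverage -> junctions -> scores."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .annotation import AnnotationCatalog, GenomicInterval, parse_gtf
from .bias import (
    BiasModel,
    CoverageProfile,
    FragmentRecord,
    fit_bias_model,
    predict_coverage_profile,
    read_fragments_tsv,
    read_transcript_fasta,
    scale_profile,
)
from .junctions import (
    ObservedJunction,
    count_region_reads,
    match_observed,
    predict_junction_coverage,
    read_star_sj,
)
from .scoring import ScoreConfig, score_all_genes

logger = logging.getLogger(__name__)

#: mean fragment length assumed when no bias model or fragment evidence is
#: available (uniform-profile mode); with beta = 1 the within-gene scaling
#: makes the score invariant to this constant.
DEFAULT_MEAN_FRAG_LEN = 250.0


def read_abundance_tsv(path: str | Path) -> dict[str, float]:
    """Transcript abundance table: columns transcript_id, est_count[, TPM],
    header required."""
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns or "est_count" not in df.columns:
        raise ValueError(
            f"{path}: abundance TSV must have transcript_id and est_count "
            "columns"
        )
    counts = {}
    for row in df.itertuples(index=False):
        c = float(row.est_count)
        if c < 0:
            raise ValueError(f"{path}: negative count for {row.transcript_id}")
        counts[str(row.transcript_id)] = c
    return counts


@dataclass
class ScoreRun:
    """Everything a scoring run produced."""

    gene_table: pd.DataFrame
    junction_table: pd.DataFrame
    novel_junctions: pd.DataFrame
    status_counts: dict[str, int] = field(default_factory=dict)
    bias_model: BiasModel | None = None


def compute_profiles(
    catalog: AnnotationCatalog,
    model: BiasModel | None,
    seqs: Mapping[str, str] | None,
    fragments: list[FragmentRecord] | None,
) -> dict[str, CoverageProfile]:
    """Normalized coverage profiles for every transcript.

    Uniform profiles are used when no model is available, when a transcript
    has no sequence, or when fragment evidence is present but assigns the
    transcript no reads (the uniform-fallback rule).
    """
    import numpy as np

    n_frags: dict[str, int] = {}
    if fragments is not None:
        for fr in fragments:
            n_frags[fr.transcript_id] = n_frags.get(fr.transcript_id, 0) + 1
    profiles: dict[str, CoverageProfile] = {}
    for tx_id in sorted(catalog.transcripts):
        tx = catalog.transcripts[tx_id]
        seq = seqs.get(tx_id) if seqs else None
        if model is None or seq is None:
            profiles[tx_id] = CoverageProfile(
                tx_id, np.full(tx.length, 1.0 / tx.length),
                normalized=True, fallback_uniform=True,
            )
            continue
        no_reads = fragments is not None and n_frags.get(tx_id, 0) == 0
        profiles[tx_id] = predict_coverage_profile(
            tx, model, seq, no_reads=no_reads
        )
    return profiles


def intron_exon_ratios(
    catalog: AnnotationCatalog,
    fragments: list[FragmentRecord],
) -> dict[str, float]:
    """Per-gene intron/exon fragment count ratio.

    Fragments are placed on the genome by the span of their transcript
    coordinates (first to last base); counting uses the flattened exonic and
    intronic regions of the fragment's own gene.
    """
    from .annotation import flatten_gene_regions

    by_gene: dict[str, list[GenomicInterval]] = {}
    for fr in fragments:
        tx = catalog.transcripts.get(fr.transcript_id)
        if tx is None:
            continue
        g1 = tx.transcript_to_genomic(fr.tstart)
        g2 = tx.transcript_to_genomic(fr.tend - 1)
        lo, hi = min(g1, g2), max(g1, g2) + 1
        by_gene.setdefault(tx.gene_id, []).append(
            GenomicInterval(tx.chrom, lo, hi, tx.strand)
        )
    ratios: dict[str, float] = {}
    for gene_id, frs in by_gene.items():
        exonic, intronic = flatten_gene_regions(catalog, gene_id)
        _, _, ratio = count_region_reads(frs, exonic, intronic)
        if ratio is not None:
            ratios[gene_id] = ratio
    return ratios


def run_score(
    gtf: str | Path | AnnotationCatalog,
    sj: str | Path | Mapping,
    abundance: str | Path | Mapping[str, float],
    *,
    tx_fasta: str | Path | None = None,
    fragments: str | Path | list[FragmentRecord] | None = None,
    bias_model: str | Path | BiasModel | None = None,
    config: ScoreConfig | None = None,
    unstranded: bool = False,
) -> ScoreRun:
    """Run the full scoring pipeline.

    A bias model can be supplied directly (JSON path or object) or fitted
    from fragment evidence plus transcript sequences; with neither, uniform
    coverage profiles are assumed (with a warning).
    """
    config = config or ScoreConfig()
    catalog = gtf if isinstance(gtf, AnnotationCatalog) else parse_gtf(gtf)
    observed_all = sj if isinstance(sj, Mapping) else read_star_sj(sj)
    abundances = (
        dict(abundance)
        if isinstance(abundance, Mapping)
        else read_abundance_tsv(abundance)
    )

    seqs = read_transcript_fasta(tx_fasta) if tx_fasta is not None else None
    frags: list[FragmentRecord] | None
    if fragments is None:
        frags = None
    elif isinstance(fragments, (str, Path)):
        frags = read_fragments_tsv(fragments)
    else:
        frags = list(fragments)

    if isinstance(bias_model, (str, Path)):
        model: BiasModel | None = BiasModel.from_json(bias_model)
    else:
        model = bias_model
    if model is None and frags is not None and seqs is not None:
        model = fit_bias_model(frags, catalog, seqs)
    if model is None or seqs is None:
        logger.warning(
            "no bias model or transcript sequences: uniform coverage "
            "profiles assumed"
        )

    mean_frag_len = model.mean_frag_len if model else DEFAULT_MEAN_FRAG_LEN
    profiles = compute_profiles(catalog, model, seqs, frags)
    scaled = {
        tid: scale_profile(profiles[tid], abundances.get(tid, 0.0), mean_frag_len)
        for tid in profiles
    }
    predicted = predict_junction_coverage(scaled, catalog)
    matched, novel = match_observed(observed_all, catalog, unstranded=unstranded)
    ratios = intron_exon_ratios(catalog, frags) if frags else {}

    gene_table = score_all_genes(
        catalog, abundances, matched, predicted, ratios, config
    )
    status_counts = gene_table["status"].value_counts().to_dict()
    for status, n in sorted(status_counts.items()):
        logger.info("genes with status %s: %d", status, n)

    jrows = []
    for key in sorted(catalog.junctions):
        chrom, s, e, strand = key
        obs = matched.get(key)
        pred = predicted.get(key)
        C = pred.predicted if pred else 0.0
        jrows.append((
            chrom, s, e, strand,
            obs.unique_count if obs else 0.0,
            obs.multi_count if obs else 0.0,
            obs.omega if obs else 1.0,
            C,
        ))
    junction_table = pd.DataFrame(
        jrows,
        columns=["chrom", "intron_start", "intron_end", "strand",
                 "unique_reads", "multi_reads", "omega", "predicted"],
    )
    nrows = [
        (o.key[0], o.key[1], o.key[2], o.key[3], o.unique_count, o.multi_count)
        for o in sorted(novel, key=lambda o: o.key)
    ]
    novel_table = pd.DataFrame(
        nrows,
        columns=["chrom", "intron_start", "intron_end", "strand",
                 "unique_reads", "multi_reads"],
    )
    return ScoreRun(
        gene_table=gene_table,
        junction_table=junction_table,
        novel_junctions=novel_table,
        status_counts=status_counts,
        bias_model=model,
    )
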