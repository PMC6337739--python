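"""Self-contained synthetic fixtures: toy genomes, annotation catalogs,
bias models, fragments, junction counts and abundance tables.

The generator emulates the quantities the score consumes rather than raw
reads: expected junction counts are derived from the same bias-model
coverage profiles used for prediction, so a noise-free run with the true
abundances reproduces the observations exactly (the null case). It also
builds the 3'UTR-swap misannotation scenario: for genes carrying two
same-start 3'UTRs whose lengths differ by more than a threshold, reads are
generated from an artificial hybrid transcript (internal structure of one
isoform, 3'UTR of the other) that is absent from the catalog handed to
scoring.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotation import (
    AnnotationCatalog,
    GenomicInterval,
    TranscriptModel,
    replace_utr3,
    transcript_jaccard,
    utr3_length,
    utr3_start,
    write_gtf,
)
from .bias import (
    BiasModel,
    FragmentRecord,
    predict_coverage_profile,
    sample_fragments,
    scale_profile,
    write_fragments_tsv,
)
from .junctions import JunctionKey, ObservedJunction, write_star_sj

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic fixtures.

    Scales follow the count-level stand-in for the read simulation:
    ~1,000 expected read pairs per expressed transcript, fragment lengths
    ~N(250, 25), 3-6 exons of 100-400 nt per transcript. Roughly half the
    genes carry a same-start short/long 3'UTR isoform pair (length
    difference > 1 kb) so the misannotation scenario has material to work
    with at desk scale.
    """

    n_genes: int = 30
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exon_count_range: tuple[int, int] = (3, 6)
    exon_len_range: tuple[int, int] = (100, 400)
    intron_len_range: tuple[int, int] = (200, 800)
    frag_len_mean: float = 250.0
    frag_len_sd: float = 25.0
    multimap_fraction: float = 0.0
    noise: str = "none"
    seed: int = 0
    reads_per_transcript: float = 1000.0
    expressed_fraction: float = 0.8
    alt_utr_fraction: float = 0.5
    alt_utr_extra: tuple[int, int] = (1200, 2000)
    chrom: str = "chr1"
    emit_fragments: bool = True

    def __post_init__(self) -> None:
        for name in ("isoforms_per_gene", "exon_count_range",
                     "exon_len_range", "intron_len_range", "alt_utr_extra"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not 0.0 <= self.multimap_fraction <= 1.0:
            raise ValueError("multimap_fraction must lie in [0, 1]")
        if self.noise not in ("none", "round", "poisson"):
            raise ValueError("noise must be one of none, round, poisson")

    def bias_model(self) -> BiasModel:
        """The ground-truth bias model implied by the config."""
        return BiasModel.gaussian_lengths(self.frag_len_mean, self.frag_len_sd)


@dataclass
class ArtificialTranscript:
    """A 3'UTR-swap hybrid and its provenance."""

    hybrid: TranscriptModel
    donor_internal: str
    donor_utr: str
    utr_choice: str  # "short" or "long": which UTR variant the hybrid carries
    utr_fraction: float


@dataclass
class GroundTruth:
    """What the simulator knows and the scoring pipeline must not."""

    true_counts: dict[str, float] = field(default_factory=dict)
    modified_genes: set[str] = field(default_factory=set)
    artificial: dict[str, ArtificialTranscript] = field(default_factory=dict)


@dataclass
class ToyFixture:
    catalog: AnnotationCatalog
    genome: dict[str, str]

    def transcript_sequence(self, tx: TranscriptModel) -> str:
        return transcript_sequence(tx, self.genome)

    def transcript_sequences(self) -> dict[str, str]:
        return {
            tid: self.transcript_sequence(tx)
            for tid, tx in sorted(self.catalog.transcripts.items())
        }


def transcript_sequence(tx: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Spliced transcript sequence in 5'->3' transcript orientation."""
    from .bias import revcomp

    chrom_seq = genome[tx.chrom]
    seq = "".join(chrom_seq[e.start:e.end] for e in tx.exons)
    return revcomp(seq) if tx.strand == "-" else seq


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Toy catalog
# ---------------------------------------------------------------------------

def _assign_utrs(
    exons: tuple[GenomicInterval, ...], strand: str
) -> dict[str, tuple[GenomicInterval, ...]]:
    """First tx-orientation exon -> 5'UTR, last -> 3'UTR, middle -> CDS."""
    if len(exons) < 3:
        return {"cds": exons if len(exons) == 2 else (), "utr5": (), "utr3": ()}
    ordered = exons if strand != "-" else tuple(reversed(exons))
    return {
        "utr5": (ordered[0],),
        "cds": tuple(sorted(ordered[1:-1], key=lambda e: e.start)),
        "utr3": (ordered[-1],),
    }


def make_toy_catalog(config: SynthConfig) -> ToyFixture:
    """Deterministic toy genome + annotation catalog.

    Genes are laid out on one chromosome with padding; isoforms of a gene
    share the terminal exons and differ by skipped internal exons. Genes
    selected for the alternative-UTR scenario gain an isoform whose
    3'-terminal exon starts at the same position but extends >1 kb further
    and whose internal structure drops one exon.
    """
    rng = np.random.default_rng([config.seed, 1])
    pad = config.alt_utr_extra[1] + 200
    cursor = pad
    txs: list[TranscriptModel] = []

    for gi in range(config.n_genes):
        gene_id = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exon_count_range[0],
                                config.exon_count_range[1] + 1))
        ex_lens = rng.integers(config.exon_len_range[0],
                               config.exon_len_range[1] + 1, size=n_ex)
        in_lens = rng.integers(config.intron_len_range[0],
                               config.intron_len_range[1] + 1,
                               size=max(n_ex - 1, 0))
        starts = []
        pos = cursor
        for i in range(n_ex):
            starts.append(pos)
            pos += int(ex_lens[i])
            if i < n_ex - 1:
                pos += int(in_lens[i])
        exon_ivs = [
            GenomicInterval(config.chrom, s, s + int(l), strand)
            for s, l in zip(starts, ex_lens)
        ]
        gene_end = pos
        cursor = gene_end + pad + int(rng.integers(500, 1500))

        n_iso = int(rng.integers(config.isoforms_per_gene[0],
                                 config.isoforms_per_gene[1] + 1))
        is_alt = n_ex >= 4 and rng.random() < config.alt_utr_fraction

        structures: list[tuple[int, ...]] = [tuple(range(n_ex))]
        alt_extra = 0
        if is_alt:
            # long-UTR isoform: drop one internal exon, extend terminal exon
            drop = int(rng.integers(1, n_ex - 1))
            alt_extra = int(rng.integers(config.alt_utr_extra[0],
                                         config.alt_utr_extra[1] + 1))
            structures.append(tuple(i for i in range(n_ex) if i != drop))
        n_more = max(n_iso - len(structures), 0)
        for _ in range(n_more):
            if n_ex < 3:
                break
            internal = list(range(1, n_ex - 1))
            n_drop = int(rng.integers(1, len(internal) + 1))
            dropped = set(rng.choice(internal, size=n_drop, replace=False))
            struct = tuple(i for i in range(n_ex) if i not in dropped)
            if struct not in structures:
                structures.append(struct)

        for k, struct in enumerate(structures):
            iso_exons = [exon_ivs[i] for i in struct]
            if is_alt and k == 1 and alt_extra:
                # same-start 3'UTR, extended downstream in tx orientation
                if strand == "-":
                    first = iso_exons[0]
                    iso_exons[0] = GenomicInterval(
                        first.chrom, first.start - alt_extra, first.end, strand
                    )
                else:
                    last = iso_exons[-1]
                    iso_exons[-1] = GenomicInterval(
                        last.chrom, last.start, last.end + alt_extra, strand
                    )
            exons = tuple(iso_exons)
            parts = _assign_utrs(exons, strand)
            txs.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}T{k + 1}",
                    gene_id=gene_id,
                    exons=exons,
                    cds=parts.get("cds", ()),
                    utr5=parts.get("utr5", ()),
                    utr3=parts.get("utr3", ()),
                )
            )

    genome_len = cursor + pad
    seq = "".join(rng.choice(_BASES, size=genome_len))
    catalog = AnnotationCatalog.from_transcripts(txs)
    return ToyFixture(catalog=catalog, genome={config.chrom: seq})


# ---------------------------------------------------------------------------
# 3'UTR swap
# ---------------------------------------------------------------------------

def make_utr_swap(
    catalog: AnnotationCatalog,
    min_len_diff: int = 1000,
    seed: int = 0,
) -> GroundTruth:
    """Construct artificial 3'UTR-swap transcripts for eligible genes.

    A gene is eligible when two of its annotated 3'UTRs start at the same
    genomic position (5' end in transcript orientation) and their lengths
    differ by more than ``min_len_diff``. One short-UTR and one long-UTR
    transcript are drawn at random; the hybrid takes the 5'UTR+CDS exon
    structure of one (random) and the 3'UTR of the other. A hybrid identical
    to an annotated isoform leaves the gene unmodified.
    """
    rng = np.random.default_rng([seed, 2])
    truth = GroundTruth()
    n_skipped = 0
    for gene_id in sorted(catalog.genes):
        groups: dict[int, list[TranscriptModel]] = {}
        for tid in sorted(catalog.genes[gene_id]):
            tx = catalog.transcripts[tid]
            start = utr3_start(tx)
            if start is None:
                n_skipped += 1
                continue
            groups.setdefault(start, []).append(tx)
        chosen = None
        for start in sorted(groups):
            group = groups[start]
            lens = [utr3_length(t) for t in group]
            if max(lens) - min(lens) > min_len_diff:
                chosen = group
                break
        if chosen is None:
            continue
        lens = [utr3_length(t) for t in chosen]
        shorts = sorted(
            t.transcript_id for t, l in zip(chosen, lens) if l == min(lens)
        )
        longs = sorted(
            t.transcript_id for t, l in zip(chosen, lens) if l == max(lens)
        )
        short_tx = catalog.transcripts[shorts[int(rng.integers(len(shorts)))]]
        long_tx = catalog.transcripts[longs[int(rng.integers(len(longs)))]]
        if rng.random() < 0.5:
            internal, utr_donor, utr_choice = short_tx, long_tx, "long"
        else:
            internal, utr_donor, utr_choice = long_tx, short_tx, "short"
        hybrid = replace(
            replace_utr3(internal, utr_donor.utr3),
            transcript_id=f"{gene_id}_artificial",
        )
        exonset = tuple((e.start, e.end) for e in hybrid.exons)
        identical = any(
            tuple((e.start, e.end) for e in catalog.transcripts[t].exons) == exonset
            for t in catalog.genes[gene_id]
        )
        if identical:
            logger.info(
                "gene %s: artificial transcript identical to an annotated "
                "isoform; left unmodified", gene_id,
            )
            continue
        truth.modified_genes.add(gene_id)
        truth.artificial[gene_id] = ArtificialTranscript(
            hybrid=hybrid,
            donor_internal=internal.transcript_id,
            donor_utr=utr_donor.transcript_id,
            utr_choice=utr_choice,
            utr_fraction=utr3_length(utr_donor) / hybrid.length,
        )
    if n_skipped:
        logger.info("%d transcripts without an annotated 3'UTR skipped", n_skipped)
    if not truth.artificial:
        logger.warning("no gene eligible for the 3'UTR swap; empty ground truth")
    return truth


# ---------------------------------------------------------------------------
# Observation simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    observed: dict[JunctionKey, ObservedJunction]
    fragments: list[FragmentRecord]
    truth_abundance: dict[str, float]
    oracle_abundance: dict[str, float]


def simulate_observed(
    catalog: AnnotationCatalog,
    truth: GroundTruth,
    bias: BiasModel,
    config: SynthConfig,
    genome: Mapping[str, str],
) -> SimulatedData:
    """Expected junction counts, fragments and abundance tables.

    Counts derive from scaled coverage profiles of the SOURCE transcripts:
    annotated isoforms for unmodified genes, the hybrid for modified genes
    (its junction chain is a subset of the annotated junctions). The truth
    abundance table carries the real per-transcript counts; the
    oracle-quantifier table assigns each modified gene's reads to the
    annotated transcript most similar (Jaccard) to its hybrid, ties broken
    by lexicographic transcript id.
    """
    if bias is None:
        raise ValueError("a bias model is required to simulate observations")
    rng = np.random.default_rng([config.seed, 3])
    mf = config.multimap_fraction

    sources: list[tuple[TranscriptModel, float]] = []
    truth_ab: dict[str, float] = {}
    for gene_id in sorted(catalog.genes):
        if gene_id in truth.modified_genes:
            art = truth.artificial[gene_id]
            sources.append((art.hybrid, config.reads_per_transcript))
            truth.true_counts[art.hybrid.transcript_id] = config.reads_per_transcript
            for tid in sorted(catalog.genes[gene_id]):
                truth_ab[tid] = 0.0
        else:
            for tid in sorted(catalog.genes[gene_id]):
                if rng.random() < config.expressed_fraction:
                    count = float(
                        config.reads_per_transcript * rng.gamma(4.0, 0.25)
                    )
                else:
                    count = 0.0
                truth_ab[tid] = count
                truth.true_counts[tid] = count
                if count > 0:
                    sources.append((catalog.transcripts[tid], count))

    expected: dict[JunctionKey, float] = {}
    fragments: list[FragmentRecord] = []
    for tx, count in sources:
        seq = transcript_sequence(tx, genome)
        profile = predict_coverage_profile(tx, bias, seq)
        scaled = scale_profile(profile, count, bias.mean_frag_len)
        for key, tpos in tx.junctions():
            expected[key] = expected.get(key, 0.0) + float(scaled.values[tpos])
        if config.emit_fragments and count > 0:
            fragments.extend(
                sample_fragments(
                    tx.transcript_id, seq, bias, int(round(count)), rng,
                    multimap_fraction=mf,
                )
            )

    observed: dict[JunctionKey, ObservedJunction] = {}
    for key in sorted(expected):
        total = expected[key]
        unique, multi = (1.0 - mf) * total, mf * total
        if config.noise == "round":
            unique, multi = float(np.rint(unique)), float(np.rint(multi))
        elif config.noise == "poisson":
            unique = float(rng.poisson(unique))
            multi = float(rng.poisson(multi))
        if unique + multi <= 0:
            continue
        observed[key] = ObservedJunction(
            key=key, unique_count=unique, multi_count=multi,
            motif=0, annotated=1, max_overhang=50,
        )

    oracle_ab = dict(truth_ab)
    for gene_id in sorted(truth.modified_genes):
        art = truth.artificial[gene_id]
        best_id, best_sim = None, -1.0
        for tid in sorted(catalog.genes[gene_id]):
            sim = transcript_jaccard(art.hybrid, catalog.transcripts[tid])
            if sim > best_sim:
                best_id, best_sim = tid, sim
        oracle_ab[best_id] = config.reads_per_transcript
    return SimulatedData(
        observed=observed,
        fragments=fragments,
        truth_abundance=truth_ab,
        oracle_abundance=oracle_ab,
    )


# ---------------------------------------------------------------------------
# Fixture directory
# ---------------------------------------------------------------------------

def write_abundance_tsv(abundances: Mapping[str, float], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        sorted(abundances.items()), columns=["transcript_id", "est_count"]
    )
    df.to_csv(path, sep="\t", index=False)


def write_fixture(
    config: SynthConfig,
    outdir: str | Path,
    *,
    with_utr_swap: bool = True,
) -> dict[str, Path]:
    """Generate and write a complete fixture directory; returns file paths.

    Emits the annotation GTF, genome and transcript FASTA, SJ.out.tab,
    fragment TSV, truth and oracle abundance TSVs, the bias model JSON and a
    ground-truth JSON — all consumed through the package's public readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture = make_toy_catalog(config)
    truth = (
        make_utr_swap(fixture.catalog, seed=config.seed)
        if with_utr_swap
        else GroundTruth()
    )
    bias = config.bias_model()
    sim = simulate_observed(fixture.catalog, truth, bias, config, fixture.genome)

    paths = {
        "gtf": outdir / "annotation.gtf",
        "genome": outdir / "genome.fa",
        "transcripts": outdir / "transcripts.fa",
        "sj": outdir / "SJ.out.tab",
        "fragments": outdir / "fragments.tsv",
        "abundance_truth": outdir / "abundance_truth.tsv",
        "abundance_oracle": outdir / "abundance_oracle.tsv",
        "bias_model": outdir / "bias_model.json",
        "truth": outdir / "truth.json",
    }
    write_gtf(fixture.catalog, paths["gtf"])
    write_fasta(fixture.genome, paths["genome"])
    write_fasta(fixture.transcript_sequences(), paths["transcripts"])
    write_star_sj(sim.observed, paths["sj"])
    write_fragments_tsv(sim.fragments, paths["fragments"])
    write_abundance_tsv(sim.truth_abundance, paths["abundance_truth"])
    write_abundance_tsv(sim.oracle_abundance, paths["abundance_oracle"])
    bias.to_json(paths["bias_model"])
    truth_doc = {
        "modified_genes": sorted(truth.modified_genes),
        "true_counts": {k: truth.true_counts[k] for k in sorted(truth.true_counts)},
        "artificial": {
            g: {
                "transcript_id": a.hybrid.transcript_id,
                "donor_internal": a.donor_internal,
                "donor_utr": a.donor_utr,
                "utr_choice": a.utr_choice,
                "utr_fraction": a.utr_fraction,
            }
            for g, a in sorted(truth.artificial.items())
        },
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1))
    return paths
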