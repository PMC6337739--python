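"""Transcript annotation catalogs: parsing, junction extraction, transforms.

Coordinates are 0-based half-open internally; GTF I/O converts from/to the
1-based inclusive convention at the boundary. Junction identity is the
intron interval plus strand, so the same intron on opposite strands yields
two distinct junctions (stranded libraries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from . import intervals as iv

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: (chrom, intron_start, intron_end, strand), 0-based half-open intron.
JunctionKey = tuple[str, int, int, str]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"interval start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptModel:
    """Exon-structured transcript with optional CDS/UTR sub-intervals.

    Exons are non-overlapping, sorted ascending by genomic start, and all on
    one chromosome and strand. Transcript coordinates run 5'->3' in
    transcript orientation: position 0 is the lowest genomic exonic base on
    '+' transcripts and the highest on '-' transcripts.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        chrom, strand = self.exons[0].chrom, self.exons[0].strand
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != chrom or ex.strand != strand:
                raise AnnotationError(
                    f"transcript {self.transcript_id} spans multiple "
                    "chromosomes or strands"
                )
            if ex.start < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are "
                    "unsorted"
                )
            prev_end = ex.end
        exon_ivs = [(e.start, e.end) for e in self.exons]
        for name, sub in (("cds", self.cds), ("utr5", self.utr5), ("utr3", self.utr3)):
            sub_ivs = [(x.start, x.end) for x in sub]
            if sub_ivs and iv.subtract(sub_ivs, exon_ivs):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: {name} intervals extend "
                    "outside the exon union"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def length(self) -> int:
        return sum(e.width for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    def exons_tx_order(self) -> tuple[GenomicInterval, ...]:
        """Exons in transcript (5'->3') orientation."""
        return self.exons if self.strand != "-" else tuple(reversed(self.exons))

    def covered(self) -> list[tuple[int, int]]:
        """Merged genomic intervals covered by the exons."""
        return iv.merge([(e.start, e.end) for e in self.exons])

    def junctions(self) -> list[tuple[JunctionKey, int]]:
        """Junction keys with the transcript coordinate of the last base of
        the upstream exon (in transcript orientation).

        A transcript with n exons yields n-1 junctions.
        """
        out: list[tuple[JunctionKey, int]] = []
        cum = 0
        exs = self.exons_tx_order()
        for i in range(len(exs) - 1):
            cum += exs[i].width
            up, down = exs[i], exs[i + 1]
            if self.strand == "-":
                key = (self.chrom, down.end, up.start, self.strand)
            else:
                key = (self.chrom, up.end, down.start, self.strand)
            out.append((key, cum - 1))
        return out

    def transcript_to_genomic(self, tpos: int) -> int:
        """Genomic coordinate of transcript base ``tpos`` (0-based)."""
        if not 0 <= tpos < self.length:
            raise AnnotationError(
                f"transcript position {tpos} out of range for "
                f"{self.transcript_id} (length {self.length})"
            )
        off = tpos
        for ex in self.exons_tx_order():
            if off < ex.width:
                if self.strand == "-":
                    return ex.end - 1 - off
                return ex.start + off
            off -= ex.width
        raise AssertionError("unreachable")

    def genomic_to_transcript(self, gpos: int) -> int:
        """Transcript coordinate of an exonic genomic base (inverse map)."""
        cum = 0
        for ex in self.exons_tx_order():
            if ex.start <= gpos < ex.end:
                if self.strand == "-":
                    return cum + (ex.end - 1 - gpos)
                return cum + (gpos - ex.start)
            cum += ex.width
        raise AnnotationError(
            f"genomic position {gpos} is not exonic in {self.transcript_id}"
        )


@dataclass
class Junction:
    """Intron interval with its transcript and gene memberships."""

    key: JunctionKey
    transcripts: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)


@dataclass
class AnnotationCatalog:
    """A set of transcript models with gene and junction indices."""

    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    genes: dict[str, set[str]] = field(default_factory=dict)
    junctions: dict[JunctionKey, Junction] = field(default_factory=dict)

    @classmethod
    def from_transcripts(cls, txs: Iterable[TranscriptModel]) -> "AnnotationCatalog":
        cat = cls()
        for tx in txs:
            if tx.transcript_id in cat.transcripts:
                prev = cat.transcripts[tx.transcript_id]
                if prev.gene_id != tx.gene_id:
                    raise AnnotationError(
                        f"transcript {tx.transcript_id} assigned to multiple "
                        f"genes ({prev.gene_id}, {tx.gene_id})"
                    )
                raise AnnotationError(f"duplicate transcript {tx.transcript_id}")
            cat.transcripts[tx.transcript_id] = tx
            cat.genes.setdefault(tx.gene_id, set()).add(tx.transcript_id)
        cat.junctions = extract_junctions(cat)
        return cat

    def gene_junctions(self, gene_id: str) -> list[Junction]:
        """J_i: all junctions annotated to ``gene_id``, sorted by key."""
        if gene_id not in self.genes:
            raise AnnotationError(f"unknown gene {gene_id}")
        return sorted(
            (j for j in self.junctions.values() if gene_id in j.genes),
            key=lambda j: j.key,
        )

    def gene_span(self, gene_id: str) -> GenomicInterval:
        txs = [self.transcripts[t] for t in self.genes[gene_id]]
        chrom, strand = txs[0].chrom, txs[0].strand
        return GenomicInterval(
            chrom,
            min(t.span.start for t in txs),
            max(t.span.end for t in txs),
            strand,
        )


def extract_junctions(catalog: AnnotationCatalog) -> dict[JunctionKey, Junction]:
    """Build the junction index: identical intron keys merge, accumulating
    transcript and gene memberships (a junction shared by transcripts of two
    genes belongs to both)."""
    out: dict[JunctionKey, Junction] = {}
    for tx in catalog.transcripts.values():
        for key, _ in tx.junctions():
            j = out.setdefault(key, Junction(key))
            j.transcripts.add(tx.transcript_id)
            j.genes.add(tx.gene_id)
    return out


# ---------------------------------------------------------------------------
# GTF I/O (Ensembl dialect), via gffutils
# ---------------------------------------------------------------------------

_GTF_FEATURES = {"exon", "CDS", "three_prime_utr", "five_prime_utr"}


def _validate_gtf_lines(path: Path) -> int:
    """Cheap structural pre-scan giving line-numbered errors; returns the
    number of data lines."""
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}: line {lineno}: invalid coordinate range "
                    f"{start}-{end}"
                )
            if fields[2] in _GTF_FEATURES and "transcript_id" not in fields[8]:
                raise AnnotationError(
                    f"{path}: line {lineno}: {fields[2]} record lacks "
                    "transcript_id"
                )
            n += 1
    return n


def parse_gtf(path: str | Path) -> AnnotationCatalog:
    """Parse an Ensembl-dialect GTF into an :class:`AnnotationCatalog`.

    GTF coordinates (1-based inclusive) are converted to internal 0-based
    half-open ones. Exons are grouped per transcript and sorted; CDS and UTR
    features are attached when present; the junction index is built.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _validate_gtf_lines(path) == 0:
        return AnnotationCatalog.from_transcripts([])

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in _GTF_FEATURES:
            continue
        try:
            tx_id = feat.attributes["transcript_id"][0]
            gene_id = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: {feat.featuretype} record without "
                f"transcript_id/gene_id attribute"
            ) from exc
        rec = per_tx.setdefault(
            tx_id, {"gene_id": gene_id, "exon": [], "CDS": [],
                    "three_prime_utr": [], "five_prime_utr": []}
        )
        if rec["gene_id"] != gene_id:
            raise AnnotationError(
                f"transcript {tx_id} assigned to multiple genes "
                f"({rec['gene_id']}, {gene_id})"
            )
        rec[feat.featuretype].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )

    txs = []
    for tx_id, rec in per_tx.items():
        if not rec["exon"]:
            raise AnnotationError(f"transcript {tx_id} has no exon records")
        txs.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=rec["gene_id"],
                exons=tuple(sorted(rec["exon"], key=lambda e: e.start)),
                cds=tuple(sorted(rec["CDS"], key=lambda e: e.start)),
                utr5=tuple(sorted(rec["five_prime_utr"], key=lambda e: e.start)),
                utr3=tuple(sorted(rec["three_prime_utr"], key=lambda e: e.start)),
            )
        )
    return AnnotationCatalog.from_transcripts(txs)


def _gtf_line(chrom, source, feature, start0, end, strand, attrs) -> str:
    attr_str = " ".join(f'{k} "{v}";' for k, v in attrs)
    return "\t".join(
        [chrom, source, feature, str(start0 + 1), str(end), ".", strand, ".", attr_str]
    )


def write_gtf(catalog: AnnotationCatalog, path: str | Path) -> None:
    """Write the catalog in normalized Ensembl-dialect GTF.

    Output ordering is deterministic (genes by chrom/start/id, transcripts by
    start/id, features by coordinate), so parse -> write is a fixed point on
    normalized files.
    """
    lines: list[str] = []
    gene_order = sorted(
        catalog.genes,
        key=lambda g: (
            catalog.gene_span(g).chrom,
            catalog.gene_span(g).start,
            g,
        ),
    )
    for gene_id in gene_order:
        span = catalog.gene_span(gene_id)
        lines.append(
            _gtf_line(span.chrom, "jccscore", "gene", span.start, span.end,
                      span.strand, [("gene_id", gene_id)])
        )
        txs = sorted(
            (catalog.transcripts[t] for t in catalog.genes[gene_id]),
            key=lambda t: (t.span.start, t.transcript_id),
        )
        for tx in txs:
            attrs = [("gene_id", gene_id), ("transcript_id", tx.transcript_id)]
            lines.append(
                _gtf_line(tx.chrom, "jccscore", "transcript", tx.span.start,
                          tx.span.end, tx.strand, attrs)
            )
            for feature, ivs in (
                ("exon", tx.exons),
                ("CDS", tx.cds),
                ("five_prime_utr", tx.utr5),
                ("three_prime_utr", tx.utr3),
            ):
                for x in sorted(ivs, key=lambda e: e.start):
                    lines.append(
                        _gtf_line(x.chrom, "jccscore", feature, x.start, x.end,
                                  x.strand, attrs)
                    )
    Path(path).write_text("".join(ln + "\n" for ln in lines))


def write_junction_bed(catalog: AnnotationCatalog, path: str | Path) -> None:
    """BED6 export of junction intron intervals for genome-browser use."""
    lines = []
    for key in sorted(catalog.junctions):
        chrom, s, e, strand = key
        name = f"{chrom}:{s}-{e}:{strand}"
        lines.append(f"{chrom}\t{s}\t{e}\t{name}\t0\t{strand}")
    Path(path).write_text("".join(ln + "\n" for ln in lines))


# ---------------------------------------------------------------------------
# Catalog transforms
# ---------------------------------------------------------------------------

def flatten_gene_regions(
    catalog: AnnotationCatalog, gene_id: str
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Flattened exonic regions (union of all member-transcript exons) and
    intronic regions (gaps within the gene span not covered by any exon)."""
    if gene_id not in catalog.genes:
        raise AnnotationError(f"unknown gene {gene_id}")
    txs = [catalog.transcripts[t] for t in catalog.genes[gene_id]]
    chrom, strand = txs[0].chrom, txs[0].strand
    exonic = iv.merge([(e.start, e.end) for t in txs for e in t.exons])
    intronic = iv.gaps(exonic)
    mk = lambda ivs: [GenomicInterval(chrom, s, e, strand) for s, e in ivs]
    return mk(exonic), mk(intronic)


def transcript_jaccard(a: TranscriptModel, b: TranscriptModel) -> float:
    """Jaccard index of the genomic nucleotide positions covered by the two
    transcripts' exons (0 when on different chromosomes or strands)."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0.0
    ca, cb = a.covered(), b.covered()
    inter = iv.total_length(iv.intersect(ca, cb))
    union = iv.total_length(ca) + iv.total_length(cb) - inter
    return inter / union if union else 0.0


def utr3_start(tx: TranscriptModel) -> int | None:
    """Genomic coordinate of the 5' end of the annotated 3'UTR in transcript
    orientation (the position where the UTR starts)."""
    if not tx.utr3:
        return None
    if tx.strand == "-":
        return max(u.end for u in tx.utr3)
    return min(u.start for u in tx.utr3)


def utr3_length(tx: TranscriptModel) -> int:
    return iv.total_length([(u.start, u.end) for u in tx.utr3])


LONG_UTR_SUFFIX = "longUTR"


def extend_utr3(catalog: AnnotationCatalog) -> AnnotationCatalog:
    """Expand the catalog with long-3'UTR transcript copies.

    Within each gene, 3'UTRs sharing the same start position (5' end in
    transcript orientation) are grouped; every transcript whose UTR is
    shorter than the group maximum gains a copy whose 3'UTR is replaced by
    the longest one, with ``longUTR`` appended to its identifier. Copies
    identical (base-for-base over exons) to an existing transcript are not
    added; originals are retained. Idempotent.
    """
    new_txs = list(catalog.transcripts.values())
    for gene_id in sorted(catalog.genes):
        members = sorted(catalog.genes[gene_id])
        groups: dict[int, list[TranscriptModel]] = {}
        for tid in members:
            tx = catalog.transcripts[tid]
            start = utr3_start(tx)
            if start is None:
                logger.info(
                    "extend_utr3: transcript %s has no annotated 3'UTR; skipped",
                    tid,
                )
                continue
            groups.setdefault(start, []).append(tx)
        existing_exonsets = {
            tuple((e.start, e.end) for e in catalog.transcripts[t].exons)
            for t in members
        }
        for start, group in sorted(groups.items()):
            longest = max(group, key=lambda t: (utr3_length(t), t.transcript_id))
            max_len = utr3_length(longest)
            for tx in group:
                if utr3_length(tx) >= max_len:
                    continue
                copy = replace_utr3(tx, longest.utr3)
                exonset = tuple((e.start, e.end) for e in copy.exons)
                if exonset in existing_exonsets:
                    continue
                existing_exonsets.add(exonset)
                new_txs.append(
                    replace(copy, transcript_id=tx.transcript_id + LONG_UTR_SUFFIX)
                )
    return AnnotationCatalog.from_transcripts(new_txs)


def replace_utr3(
    tx: TranscriptModel, utr3: tuple[GenomicInterval, ...]
) -> TranscriptModel:
    """Transcript copy whose 3'UTR (and the exonic bases it covers) is
    replaced by ``utr3``; the non-UTR exon structure is kept."""
    own_utr = [(u.start, u.end) for u in tx.utr3]
    internal = iv.subtract([(e.start, e.end) for e in tx.exons], own_utr)
    merged = iv.merge(internal + [(u.start, u.end) for u in utr3])
    exons = tuple(
        GenomicInterval(tx.chrom, s, e, tx.strand) for s, e in merged
    )
    return replace(tx, exons=exons, utr3=tuple(utr3))
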