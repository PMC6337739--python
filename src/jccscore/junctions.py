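"""Observed and predicted junction read counts.

Observed counts come from the aligner's per-junction table (STAR's
SJ.out.tab, 9 columns); predicted counts are read off scaled transcript
coverage profiles at the base just before each junction, in transcript
orientation, and summed across transcripts in a strand-aware fashion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .annotation import AnnotationCatalog, GenomicInterval, JunctionKey
from .bias import CoverageProfile

logger = logging.getLogger(__name__)

_STRAND_FROM_CODE = {0: ".", 1: "+", 2: "-"}
_CODE_FROM_STRAND = {v: k for k, v in _STRAND_FROM_CODE.items()}


@dataclass
class ObservedJunction:
    """Unique/multi-mapping read counts for one junction.

    Counts are kept as reals so that synthetic noise-free expectations are
    representable; aligner output is integer-valued. omega (the unique
    fraction) is defined as 1 when no reads span the junction, so a
    predicted-but-unobserved junction still contributes |C_j - 0| to the
    score.
    """

    key: JunctionKey
    unique_count: float
    multi_count: float = 0.0
    # SJ.out.tab metadata, kept for bit-exact round trips
    motif: int = 0
    annotated: int = 1
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.unique_count < 0 or self.multi_count < 0:
            raise ValueError(f"negative read count for junction {self.key}")

    @property
    def total(self) -> float:
        return self.unique_count + self.multi_count

    @property
    def omega(self) -> float:
        return self.unique_count / self.total if self.total > 0 else 1.0


@dataclass
class PredictedJunction:
    """Predicted junction-spanning read count with per-transcript parts."""

    key: JunctionKey
    per_transcript: dict[str, float] = field(default_factory=dict)

    @property
    def predicted(self) -> float:
        return sum(self.per_transcript.values())


def _fmt_count(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def read_star_sj(path: str | Path) -> dict[JunctionKey, ObservedJunction]:
    """Parse a STAR SJ.out.tab file.

    Columns: chrom, intron first base (1-based), intron last base (1-based),
    strand code (0 undefined / 1 + / 2 -), motif, annotated flag, unique
    reads, multi reads, max overhang. Keys are converted to 0-based
    half-open intron intervals.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "first", "last", "strand_code", "motif",
                   "annotated", "unique", "multi", "overhang"],
            dtype={"chrom": str},
        )
    except pd.errors.EmptyDataError:
        return {}
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed SJ.out.tab: {exc}") from exc
    out: dict[JunctionKey, ObservedJunction] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            first, last = int(row.first), int(row.last)
            code = int(row.strand_code)
            unique = float(row.unique)
            multi = float(row.multi)
            motif, annotated = int(row.motif), int(row.annotated)
            overhang = int(row.overhang)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: non-numeric field") from exc
        if code not in _STRAND_FROM_CODE:
            raise ValueError(f"{path}: line {i}: invalid strand code {code}")
        key = (str(row.chrom), first - 1, last, _STRAND_FROM_CODE[code])
        out[key] = ObservedJunction(
            key=key, unique_count=unique, multi_count=multi,
            motif=motif, annotated=annotated, max_overhang=overhang,
        )
    return out


def write_star_sj(
    observed: Mapping[JunctionKey, ObservedJunction], path: str | Path
) -> None:
    """Write observations in STAR's 9-column dialect, sorted by key."""
    lines = []
    for key in sorted(observed):
        chrom, s, e, strand = key
        o = observed[key]
        lines.append(
            "\t".join([
                chrom, str(s + 1), str(e), str(_CODE_FROM_STRAND[strand]),
                str(o.motif), str(o.annotated),
                _fmt_count(o.unique_count), _fmt_count(o.multi_count),
                str(o.max_overhang),
            ])
        )
    Path(path).write_text("".join(ln + "\n" for ln in lines))


def collapse_strand(key: JunctionKey) -> JunctionKey:
    return (key[0], key[1], key[2], ".")


def match_observed(
    observed: Mapping[JunctionKey, ObservedJunction],
    catalog: AnnotationCatalog,
    *,
    unstranded: bool = False,
) -> tuple[dict[JunctionKey, ObservedJunction], list[ObservedJunction]]:
    """Assign observed junctions to annotated keys.

    In stranded mode the key (including strand) must match exactly; strand
    code 0 records match nothing and are logged. In unstranded mode strands
    are ignored for matching and counts of same-intron records are summed.
    Returns (matched-by-annotated-key, unannotated observations).
    """
    matched: dict[JunctionKey, ObservedJunction] = {}
    novel: list[ObservedJunction] = []
    if unstranded:
        index: dict[JunctionKey, list[JunctionKey]] = {}
        for key in catalog.junctions:
            index.setdefault(collapse_strand(key), []).append(key)
        for key, obs in observed.items():
            targets = index.get(collapse_strand(key))
            if not targets:
                novel.append(obs)
                continue
            for t in targets:
                if t in matched:
                    m = matched[t]
                    m.unique_count += obs.unique_count
                    m.multi_count += obs.multi_count
                    m.max_overhang = max(m.max_overhang, obs.max_overhang)
                else:
                    matched[t] = ObservedJunction(
                        key=t, unique_count=obs.unique_count,
                        multi_count=obs.multi_count, motif=obs.motif,
                        annotated=obs.annotated, max_overhang=obs.max_overhang,
                    )
        return matched, novel
    n_undef = 0
    for key, obs in observed.items():
        if key[3] == ".":
            n_undef += 1
            novel.append(obs)
            continue
        if key in catalog.junctions:
            matched[key] = obs
        else:
            novel.append(obs)
    if n_undef:
        logger.info(
            "%d observed junctions with undefined strand dropped in "
            "stranded mode", n_undef,
        )
    return matched, novel


def predict_junction_coverage(
    profiles: Mapping[str, CoverageProfile],
    catalog: AnnotationCatalog,
) -> dict[JunctionKey, PredictedJunction]:
    """Predicted junction-spanning reads per annotated junction.

    For each transcript, the contribution to each of its junctions is the
    scaled coverage at the transcript-orientation coordinate of the last
    base of the upstream exon; contributions are summed over transcripts per
    (strand-aware) junction key.
    """
    out: dict[JunctionKey, PredictedJunction] = {}
    for tx_id in sorted(catalog.transcripts):
        tx = catalog.transcripts[tx_id]
        prof = profiles.get(tx_id)
        if prof is None:
            raise KeyError(f"missing coverage profile for transcript {tx_id}")
        if len(prof.values) != tx.length:
            raise ValueError(
                f"profile length {len(prof.values)} != transcript length "
                f"{tx.length} for {tx_id}"
            )
        for key, tpos in tx.junctions():
            pj = out.setdefault(key, PredictedJunction(key))
            pj.per_transcript[tx_id] = (
                pj.per_transcript.get(tx_id, 0.0) + float(prof.values[tpos])
            )
    return out


def count_region_reads(
    fragments: Iterable[GenomicInterval],
    exonic: Sequence[GenomicInterval],
    intronic: Sequence[GenomicInterval],
) -> tuple[int, int, float | None]:
    """Count fragments overlapping flattened exonic and intronic regions.

    A fragment increments each class at most once; one spanning an
    exon-intron boundary counts in both. The ratio intron/exon is None when
    no fragment overlaps an exon.
    """
    ex = iv.merge([(r.start, r.end) for r in exonic]) if exonic else []
    intr = iv.merge([(r.start, r.end) for r in intronic]) if intronic else []
    exon_count = intron_count = 0
    for fr in fragments:
        if ex and iv.overlaps_any(fr.start, fr.end, ex):
            exon_count += 1
        if intr and iv.overlaps_any(fr.start, fr.end, intr):
            intron_count += 1
    ratio = intron_count / exon_count if exon_count > 0 else None
    return exon_count, intron_count, ratio
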