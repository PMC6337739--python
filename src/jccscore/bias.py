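"""Fragment-bias model fitting and per-base coverage prediction.

The model carries four multiplicative terms estimated on single-isoform
genes: the fragment length distribution, fragment GC bias, positional bias
of the fragment midpoint along the transcript, and sequence bias of the
k-mers at the fragment ends (a stand-in for random-hexamer priming bias).
Terms are independent, binned, and mean-normalized to 1; the probability of
a fragment placement (start s, length l) on a transcript is proportional to
the product of the terms, and the predicted coverage of a base is the sum
over placements covering it.

Transcripts shorter than the minimum modelled fragment length, and
transcripts the caller flags as read-free, fall back to a uniform profile
rather than being dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationCatalog, TranscriptModel

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: serialization format version for BiasModel JSON documents
_MODEL_FORMAT = 1


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FragmentRecord:
    """A sequenced fragment in transcript coordinates [tstart, tend)."""

    transcript_id: str
    tstart: int
    tend: int
    multimap: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.tstart < self.tend:
            raise ValueError(
                f"invalid fragment [{self.tstart}, {self.tend}) on "
                f"{self.transcript_id}"
            )

    @property
    def length(self) -> int:
        return self.tend - self.tstart


@dataclass
class BiasModel:
    """Binned multiplicative fragment-bias model.

    frag_len_pmf is indexed by length - l_min over [l_min, l_max] and sums
    to 1. Weight vectors are positive and mean-normalized to 1.
    start_seq_weight maps end k-mers to relative weights (unseen k-mers
    weigh 1).
    """

    frag_len_pmf: np.ndarray
    l_min: int
    l_max: int
    gc_weight: np.ndarray
    pos_weight: np.ndarray
    start_seq_weight: dict[str, float] = field(default_factory=dict)
    k: int = 6
    mean_frag_len: float = 0.0

    def __post_init__(self) -> None:
        self.frag_len_pmf = np.asarray(self.frag_len_pmf, dtype=float)
        self.gc_weight = np.asarray(self.gc_weight, dtype=float)
        self.pos_weight = np.asarray(self.pos_weight, dtype=float)
        if len(self.frag_len_pmf) != self.l_max - self.l_min + 1:
            raise ValueError("frag_len_pmf length inconsistent with [l_min, l_max]")
        if np.any(self.frag_len_pmf < 0) or not np.isclose(
            self.frag_len_pmf.sum(), 1.0, atol=1e-9
        ):
            raise ValueError("frag_len_pmf must be a probability vector")
        if np.any(self.gc_weight <= 0) or np.any(self.pos_weight <= 0):
            raise ValueError("bias weights must be positive")
        if not self.mean_frag_len:
            self.mean_frag_len = float(self.lengths @ self.frag_len_pmf)

    @property
    def lengths(self) -> np.ndarray:
        return np.arange(self.l_min, self.l_max + 1)

    @property
    def n_gc_bins(self) -> int:
        return len(self.gc_weight)

    @property
    def n_pos_bins(self) -> int:
        return len(self.pos_weight)

    def kmer_weight(self, kmer: str) -> float:
        return self.start_seq_weight.get(kmer, 1.0)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format": _MODEL_FORMAT,
            "l_min": self.l_min,
            "l_max": self.l_max,
            "frag_len_pmf": self.frag_len_pmf.tolist(),
            "gc_weight": self.gc_weight.tolist(),
            "pos_weight": self.pos_weight.tolist(),
            "start_seq_weight": self.start_seq_weight,
            "k": self.k,
            "mean_frag_len": self.mean_frag_len,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "BiasModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format") != _MODEL_FORMAT:
            raise ValueError(f"unsupported bias model format {doc.get('format')}")
        return cls(
            frag_len_pmf=np.array(doc["frag_len_pmf"]),
            l_min=doc["l_min"],
            l_max=doc["l_max"],
            gc_weight=np.array(doc["gc_weight"]),
            pos_weight=np.array(doc["pos_weight"]),
            start_seq_weight=dict(doc["start_seq_weight"]),
            k=doc["k"],
            mean_frag_len=doc["mean_frag_len"],
        )

    # -- constructors -------------------------------------------------------

    @classmethod
    def flat(
        cls,
        l_min: int,
        l_max: int,
        *,
        pmf: np.ndarray | None = None,
        n_gc_bins: int = 25,
        n_pos_bins: int = 20,
        k: int = 6,
    ) -> "BiasModel":
        """Bias-free model: all weights 1, uniform length pmf by default."""
        n = l_max - l_min + 1
        if pmf is None:
            pmf = np.full(n, 1.0 / n)
        return cls(
            frag_len_pmf=np.asarray(pmf, float),
            l_min=l_min,
            l_max=l_max,
            gc_weight=np.ones(n_gc_bins),
            pos_weight=np.ones(n_pos_bins),
            start_seq_weight={},
            k=k,
        )

    @classmethod
    def gaussian_lengths(
        cls,
        mean: float,
        sd: float,
        *,
        n_sd: float = 3.0,
        gc_weight: np.ndarray | None = None,
        pos_weight: np.ndarray | None = None,
        start_seq_weight: dict[str, float] | None = None,
        k: int = 6,
    ) -> "BiasModel":
        """Model with a discretized truncated-normal fragment length pmf."""
        l_min = max(int(mean - n_sd * sd), 1)
        l_max = int(np.ceil(mean + n_sd * sd))
        lengths = np.arange(l_min, l_max + 1)
        pmf = np.exp(-0.5 * ((lengths - mean) / sd) ** 2)
        pmf /= pmf.sum()
        m = cls.flat(l_min, l_max, pmf=pmf, k=k)
        if gc_weight is not None:
            m.gc_weight = _mean_normalize(np.asarray(gc_weight, float))
        if pos_weight is not None:
            m.pos_weight = _mean_normalize(np.asarray(pos_weight, float))
        if start_seq_weight:
            m.start_seq_weight = dict(start_seq_weight)
        m.mean_frag_len = float(m.lengths @ m.frag_len_pmf)
        return m


@dataclass
class CoverageProfile:
    """Per-base predicted fragment coverage along a transcript."""

    transcript_id: str
    values: np.ndarray
    normalized: bool
    fallback_uniform: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("coverage values must be nonnegative")
        if self.normalized and not np.isclose(self.values.sum(), 1.0, atol=1e-9):
            raise ValueError("normalized profile must sum to 1")


def _mean_normalize(w: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Scale so that the (optionally weighted) mean of w is 1.

    Fitting normalizes with the expected bin mass as weights, so noisy
    near-empty bins do not shift the calibration of the mass-bearing ones.
    """
    if weights is None:
        m = w.mean() if len(w) else 1.0
    else:
        tot = weights.sum()
        m = float(w @ weights / tot) if tot > 0 else 1.0
    return w / m if m > 0 else w


def _gc_cumsum(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    return np.concatenate([[0], np.cumsum(is_gc)])


def _bin_index(frac: np.ndarray, n_bins: int) -> np.ndarray:
    return np.clip((np.asarray(frac) * n_bins).astype(int), 0, n_bins - 1)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def eligible_transcripts(
    fragments_by_tx: Mapping[str, Sequence[FragmentRecord]],
    catalog: AnnotationCatalog,
    *,
    min_tx_len: int = 600,
    max_tx_len: int = 7000,
    min_reads: int = 500,
    max_reads: int = 10000,
) -> list[str]:
    """Transcripts of single-isoform genes with length in
    [min_tx_len, max_tx_len] and assigned read count in [min_reads,
    max_reads] — the bias-fitting training set."""
    out = []
    for tx_id in sorted(fragments_by_tx):
        tx = catalog.transcripts.get(tx_id)
        if tx is None:
            continue
        if len(catalog.genes[tx.gene_id]) != 1:
            continue
        if not min_tx_len <= tx.length <= max_tx_len:
            continue
        if not min_reads <= len(fragments_by_tx[tx_id]) <= max_reads:
            continue
        out.append(tx_id)
    return out


def fit_bias_model(
    fragments: Iterable[FragmentRecord],
    catalog: AnnotationCatalog,
    seqs: Mapping[str, str],
    *,
    n_gc_bins: int = 25,
    n_pos_bins: int = 20,
    k: int = 6,
    len_quantiles: tuple[float, float] = (0.005, 0.995),
    min_tx_len: int = 600,
    max_tx_len: int = 7000,
    min_reads: int = 500,
    max_reads: int = 10000,
    pseudocount: float = 0.5,
) -> BiasModel:
    """Fit all bias terms from fragment evidence on eligible transcripts.

    Each term is the ratio of observed to expected-under-uniform-placement
    frequencies per bin, mean-normalized, with a small pseudocount so every
    weight stays positive. The fragment-length pmf is the empirical
    distribution truncated to the given quantile range.
    """
    by_tx: dict[str, list[FragmentRecord]] = {}
    for fr in fragments:
        by_tx.setdefault(fr.transcript_id, []).append(fr)

    elig = eligible_transcripts(
        by_tx, catalog,
        min_tx_len=min_tx_len, max_tx_len=max_tx_len,
        min_reads=min_reads, max_reads=max_reads,
    )
    if not elig:
        raise ValueError(
            "no eligible single-isoform gene for bias fitting; relax the "
            "length/read-count thresholds or provide more fragments"
        )
    for tx_id in elig:
        if tx_id not in seqs:
            raise KeyError(f"missing sequence for eligible transcript {tx_id}")

    all_lens = np.array(
        [fr.length for t in elig for fr in by_tx[t]], dtype=int
    )
    lo, hi = np.quantile(all_lens, len_quantiles)
    l_min, l_max = int(np.floor(lo)), int(np.ceil(hi))
    lengths = np.arange(l_min, l_max + 1)
    pmf = np.bincount(
        np.clip(all_lens, l_min, l_max) - l_min, minlength=len(lengths)
    ).astype(float)
    # clip() above folds the trimmed tails into the boundary bins; remove them
    pmf[0] = np.sum(all_lens == l_min)
    pmf[-1] = np.sum(all_lens == l_max)
    if pmf.sum() == 0:
        raise ValueError("no fragments within the length support")
    pmf /= pmf.sum()

    obs_gc = np.zeros(n_gc_bins)
    obs_pos = np.zeros(n_pos_bins)
    exp_gc = np.zeros(n_gc_bins)
    exp_pos = np.zeros(n_pos_bins)
    obs_kmer: dict[str, float] = {}
    bg_kmer: dict[str, float] = {}

    for tx_id in elig:
        seq = seqs[tx_id].upper()
        L = len(seq)
        gcc = _gc_cumsum(seq)
        frs = [fr for fr in by_tx[tx_id] if l_min <= fr.length <= l_max]
        if not frs:
            continue
        # observed term frequencies
        ts = np.array([fr.tstart for fr in frs])
        te = np.array([fr.tend for fr in frs])
        gcfrac = (gcc[te] - gcc[ts]) / (te - ts)
        np.add.at(obs_gc, _bin_index(gcfrac, n_gc_bins), 1.0)
        np.add.at(obs_pos, _bin_index((ts + te) / 2 / L, n_pos_bins), 1.0)
        for fr in frs:
            if fr.tstart + k <= L:
                km5 = seq[fr.tstart:fr.tstart + k]
                obs_kmer[km5] = obs_kmer.get(km5, 0.0) + 1.0
            if fr.tend - k >= 0:
                km3 = revcomp(seq[fr.tend - k:fr.tend])
                obs_kmer[km3] = obs_kmer.get(km3, 0.0) + 1.0
        # expected frequencies under uniform placement, weighted by the pmf
        n_t = float(len(frs))
        for li, l in enumerate(lengths):
            if pmf[li] == 0 or l > L:
                continue
            n_valid = L - l + 1
            w = n_t * pmf[li] / n_valid
            gfrac = (gcc[l:] - gcc[:-l]) / l
            exp_gc += w * np.bincount(
                _bin_index(gfrac, n_gc_bins), minlength=n_gc_bins
            )
            mid = (np.arange(n_valid) + l / 2) / L
            exp_pos += w * np.bincount(
                _bin_index(mid, n_pos_bins), minlength=n_pos_bins
            )
        # background k-mer frequency of the training sequences (stand-in for
        # the exact placement-weighted enumeration; see docs/methods.md)
        for s in range(L - k + 1):
            km = seq[s:s + k]
            bg_kmer[km] = bg_kmer.get(km, 0.0) + 1.0
            kmr = revcomp(km)
            bg_kmer[kmr] = bg_kmer.get(kmr, 0.0) + 1.0

    def ratio_weights(obs: np.ndarray, exp: np.ndarray) -> np.ndarray:
        # observed and expected are in count units and share the same total
        exp_scaled = exp / exp.sum() * obs.sum()
        w = (obs + pseudocount) / (exp_scaled + pseudocount)
        w[exp == 0] = 1.0
        return _mean_normalize(w, weights=exp)

    gc_weight = ratio_weights(obs_gc, exp_gc)
    pos_weight = ratio_weights(obs_pos, exp_pos)

    obs_tot = sum(obs_kmer.values())
    bg_tot = sum(bg_kmer.values())
    kmer_w = {
        km: (obs_kmer.get(km, 0.0) + pseudocount)
        / (cnt / bg_tot * obs_tot + pseudocount)
        for km, cnt in bg_kmer.items()
    }
    if kmer_w:
        mean_w = sum(
            w * bg_kmer[km] for km, w in kmer_w.items()
        ) / bg_tot
        kmer_w = {km: w / mean_w for km, w in kmer_w.items()}

    model = BiasModel(
        frag_len_pmf=pmf,
        l_min=l_min,
        l_max=l_max,
        gc_weight=gc_weight,
        pos_weight=pos_weight,
        start_seq_weight=kmer_w,
        k=k,
    )
    logger.info(
        "fitted bias model on %d transcripts (%d fragments), length support "
        "[%d, %d], mean fragment length %.1f",
        len(elig), len(all_lens), l_min, l_max, model.mean_frag_len,
    )
    return model


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def placement_weights(
    model: BiasModel, seq: str, l: int
) -> np.ndarray:
    """Relative weights of all placements of length ``l`` on ``seq``
    (vector over start positions)."""
    L = len(seq)
    n_valid = L - l + 1
    if n_valid <= 0:
        return np.zeros(0)
    li = l - model.l_min
    if not 0 <= li < len(model.frag_len_pmf):
        return np.zeros(n_valid)
    gcc = _gc_cumsum(seq)
    gfrac = (gcc[l:] - gcc[:-l]) / l
    w = model.frag_len_pmf[li] * model.gc_weight[
        _bin_index(gfrac, model.n_gc_bins)
    ]
    mid = (np.arange(n_valid) + l / 2) / L
    w = w * model.pos_weight[_bin_index(mid, model.n_pos_bins)]
    if model.start_seq_weight:
        k = model.k
        kw5 = np.array(
            [model.kmer_weight(seq[s:s + k]) for s in range(n_valid)]
        )
        kw3 = np.array(
            [model.kmer_weight(revcomp(seq[s + l - k:s + l])) for s in range(n_valid)]
        )
        w = w * kw5 * kw3
    return w


def _uniform_profile(tx_id: str, length: int) -> CoverageProfile:
    return CoverageProfile(
        transcript_id=tx_id,
        values=np.full(length, 1.0 / length),
        normalized=True,
        fallback_uniform=True,
    )


def predict_coverage_profile(
    tx: TranscriptModel,
    model: BiasModel,
    seq: str,
    *,
    no_reads: bool = False,
) -> CoverageProfile:
    """Normalized per-base coverage profile of a transcript under the model.

    Falls back to a uniform profile when the transcript is shorter than the
    minimum modelled fragment length (prediction "failed"), when the caller
    flags it as read-free, or when the sequence is shorter than the k-mer.
    """
    L = tx.length
    if seq is not None and len(seq) != L:
        raise ValueError(
            f"sequence length {len(seq)} != transcript length {L} for "
            f"{tx.transcript_id}"
        )
    if no_reads or L < model.l_min:
        return _uniform_profile(tx.transcript_id, L)
    if model.start_seq_weight and L < model.k:
        logger.info(
            "transcript %s shorter than k-mer; uniform fallback", tx.transcript_id
        )
        return _uniform_profile(tx.transcript_id, L)

    seq = seq.upper()
    cov = np.zeros(L)
    pos = np.arange(L)
    for l in model.lengths[model.frag_len_pmf > 0]:
        if l > L:
            continue
        w = placement_weights(model, seq, int(l))
        n_valid = L - l + 1
        cs = np.concatenate([[0.0], np.cumsum(w)])
        lo = np.maximum(0, pos - l + 1)
        hi = np.minimum(pos, n_valid - 1) + 1
        cov += cs[hi] - cs[np.minimum(lo, n_valid)]
    total = cov.sum()
    if total <= 0:
        return _uniform_profile(tx.transcript_id, L)
    return CoverageProfile(
        transcript_id=tx.transcript_id, values=cov / total, normalized=True
    )


def scale_profile(
    profile: CoverageProfile, est_count: float, mean_frag_len: float
) -> CoverageProfile:
    """Scale a normalized profile to predicted read coverage: divide by its
    sum and multiply by est_count x mean fragment length."""
    if est_count < 0:
        raise ValueError("estimated count must be nonnegative")
    if not profile.normalized:
        raise ValueError("profile must be normalized before scaling")
    total = profile.values.sum()
    values = (
        profile.values / total * mean_frag_len * est_count
        if total > 0
        else np.zeros_like(profile.values)
    )
    return CoverageProfile(
        transcript_id=profile.transcript_id,
        values=values,
        normalized=False,
        fallback_uniform=profile.fallback_uniform,
    )


def profile_correlation(a: CoverageProfile, b: CoverageProfile) -> float:
    """Pearson correlation of two profiles of one transcript; NaN when
    either vector is constant."""
    if len(a.values) != len(b.values):
        raise ValueError("profiles have different lengths")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        return float("nan")
    return float(np.corrcoef(a.values, b.values)[0, 1])


# ---------------------------------------------------------------------------
# Fragment evidence I/O and sampling
# ---------------------------------------------------------------------------

_FRAG_COLUMNS = ["transcript_id", "tstart", "tend", "multimap"]


def read_fragments_tsv(path: str | Path) -> list[FragmentRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_FRAG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing fragment columns {sorted(missing)}")
    return [
        FragmentRecord(r.transcript_id, int(r.tstart), int(r.tend), bool(r.multimap))
        for r in df.itertuples()
    ]


def write_fragments_tsv(fragments: Iterable[FragmentRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(f.transcript_id, f.tstart, f.tend, int(f.multimap)) for f in fragments],
        columns=_FRAG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def sample_fragments(
    tx_id: str,
    seq: str,
    model: BiasModel,
    n: int,
    rng: np.random.Generator,
    *,
    multimap_fraction: float = 0.0,
) -> list[FragmentRecord]:
    """Draw ``n`` fragments from the model's placement distribution on one
    transcript (inverse of the fitting direction; used by the synthetic
    generator)."""
    L = len(seq)
    starts: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    ls: list[int] = []
    for l in model.lengths[model.frag_len_pmf > 0]:
        if l > L:
            continue
        w = placement_weights(model, seq.upper(), int(l))
        starts.append(np.arange(L - l + 1))
        weights.append(w)
        ls.extend([int(l)] * (L - l + 1))
    if not weights:
        return []
    w_all = np.concatenate(weights)
    if w_all.sum() <= 0:
        return []
    s_all = np.concatenate(starts)
    l_all = np.array(ls)
    idx = rng.choice(len(w_all), size=n, p=w_all / w_all.sum())
    mm = rng.random(n) < multimap_fraction
    return [
        FragmentRecord(tx_id, int(s_all[i]), int(s_all[i] + l_all[i]), bool(m))
        for i, m in zip(idx, mm)
    ]


def read_transcript_fasta(path: str | Path) -> dict[str, str]:
    """Transcript sequences keyed by record id (first whitespace token)."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}
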