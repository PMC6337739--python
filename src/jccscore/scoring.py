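"""The junction coverage compatibility (JCC) score family.

For gene i with annotated junction set J_i, observed unique junction read
counts R_j, predicted junction coverages C_j and unique fractions omega_j,

    JCC_i = sum_j g(w_j) | s * C_j - R_j |  /  sum_j g(w_j) R_j,
    s = ( sum_k g(w_k) R_k / sum_k g(w_k) C_k ) ** beta,

where g is a nonnegative weight function of the unique fraction (default: a
step at 0.75, so junctions dominated by multi-mapping reads do not
contribute) and beta in {0, 1} switches the within-gene rescaling of the
predicted coverages. With beta = 1 the score lies in [0, 2]: 0 means the
scaled predictions match the observations at every weighted junction, 2
means observed and predicted mass sit on disjoint junction sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationCatalog, JunctionKey
from .junctions import ObservedJunction, PredictedJunction

_TIE_TOL = 1e-12

STATUS_SCORED = "scored"
STATUS_NOT_EXPRESSED = "not_expressed"
STATUS_NO_JUNCTIONS = "no_junctions"
STATUS_INSUFFICIENT = "insufficient_unique_junction_reads"


@dataclass(frozen=True)
class WeightFunction:
    """Nondecreasing map from the unique fraction omega to a weight.

    kinds: ``step`` (1 iff omega >= threshold), ``ramp`` (linear rise to 1
    at the threshold), ``logistic`` (smooth step with the given steepness).
    """

    kind: str = "step"
    threshold: float = 0.75
    steepness: float = 20.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp", "logistic"):
            raise ValueError(f"unknown weight function kind {self.kind!r}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def __call__(self, omega):
        om = np.asarray(omega, dtype=float)
        if np.any(om < 0) or np.any(om > 1):
            raise ValueError("omega must lie in [0, 1]")
        if self.kind == "step":
            w = (om >= self.threshold).astype(float)
        elif self.kind == "ramp":
            w = (
                np.clip(om / self.threshold, 0.0, 1.0)
                if self.threshold > 0
                else np.ones_like(om)
            )
        else:
            w = 1.0 / (1.0 + np.exp(-self.steepness * (om - self.threshold)))
        return float(w) if np.isscalar(omega) else w


@dataclass(frozen=True)
class ScoreConfig:
    """Scoring parameters and gene-level reporting filters."""

    weight: WeightFunction = field(default_factory=WeightFunction)
    beta: int = 1
    min_unique_junction_reads: int = 25
    min_unique_fraction: float = 0.75
    max_intron_exon_ratio: float = 0.1
    high_score_threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.beta not in (0, 1):
            raise ValueError("beta must be 0 (no scaling) or 1 (scaling)")
        if self.min_unique_junction_reads < 0:
            raise ValueError("min_unique_junction_reads must be >= 0")
        if not 0.0 <= self.min_unique_fraction <= 1.0:
            raise ValueError("min_unique_fraction must lie in [0, 1]")


def jcc_score(
    R: Sequence[float],
    C: Sequence[float],
    omega: Sequence[float],
    config: ScoreConfig | None = None,
) -> float:
    """JCC score of one gene from its junction vectors.

    Raises ValueError when no weighted junction carries observed reads (the
    caller must have classified the gene as unscorable first). When beta = 1
    and the weighted predicted mass is zero, the scale factor is defined as
    1, giving a score of exactly 1 (the formula's 0/0 case).
    """
    config = config or ScoreConfig()
    R = np.asarray(R, dtype=float)
    C = np.asarray(C, dtype=float)
    om = np.asarray(omega, dtype=float)
    if not (len(R) == len(C) == len(om)):
        raise ValueError("R, C, omega must have equal lengths")
    w = config.weight(om)
    wr = float(np.sum(w * R))
    if wr <= 0:
        raise ValueError("sum of weighted observed junction reads is zero")
    wc = float(np.sum(w * C))
    if config.beta == 1 and wc > 0:
        # stable form: w*s*C = (w*C/wc)*wr with every ratio in [0, 1], so the
        # scale factor never overflows when wc is tiny
        z = (w * C) / wc
        return float(np.sum(np.abs(z * wr - w * R)) / wr)
    s = 1.0 if wc == 0 else (wr / wc) ** config.beta
    return float(np.sum(w * np.abs(s * C - R)) / wr)


def classify_gene(
    gene_id: str,
    catalog: AnnotationCatalog,
    abundances: Mapping[str, float],
    observed: Mapping[JunctionKey, ObservedJunction],
    config: ScoreConfig | None = None,
) -> str:
    """Validity category of a gene: not expressed (total estimated
    abundance 0), expressed without junctions, with junctions but no
    weighted uniquely mapping junction reads, or scorable."""
    config = config or ScoreConfig()
    if gene_id not in catalog.genes:
        raise KeyError(f"unknown gene {gene_id}")
    total = sum(abundances.get(t, 0.0) for t in catalog.genes[gene_id])
    if total == 0:
        return STATUS_NOT_EXPRESSED
    juncs = catalog.gene_junctions(gene_id)
    if not juncs:
        return STATUS_NO_JUNCTIONS
    wr = 0.0
    for j in juncs:
        obs = observed.get(j.key)
        if obs is not None:
            wr += config.weight(obs.omega) * obs.unique_count
    if wr <= 0:
        return STATUS_INSUFFICIENT
    return STATUS_SCORED


def _gene_vectors(
    juncs,
    observed: Mapping[JunctionKey, ObservedJunction],
    predicted: Mapping[JunctionKey, PredictedJunction],
):
    R, C, om, multi = [], [], [], []
    for j in juncs:
        obs = observed.get(j.key)
        R.append(obs.unique_count if obs else 0.0)
        multi.append(obs.multi_count if obs else 0.0)
        om.append(obs.omega if obs else 1.0)
        pred = predicted.get(j.key)
        C.append(pred.predicted if pred else 0.0)
    return (np.array(R), np.array(C), np.array(om), np.array(multi))


GENE_TABLE_COLUMNS = [
    "gene_id", "jcc", "status", "unique_junction_reads", "unique_fraction",
    "intron_exon_ratio", "total_predicted_abundance", "passes_filters",
]


def score_all_genes(
    catalog: AnnotationCatalog,
    abundances: Mapping[str, float],
    observed: Mapping[JunctionKey, ObservedJunction],
    predicted: Mapping[JunctionKey, PredictedJunction],
    intron_exon: Mapping[str, float] | None = None,
    config: ScoreConfig | None = None,
) -> pd.DataFrame:
    """Per-gene score table.

    One row per gene with the JCC (for scorable genes), the validity status,
    the filter covariates (total unique junction reads, read-weighted unique
    fraction, intron/exon read-count ratio) and whether the gene passes the
    reporting filters. A missing intron/exon ratio does not fail the filter.
    """
    config = config or ScoreConfig()
    intron_exon = intron_exon or {}
    rows = []
    for gene_id in sorted(catalog.genes):
        status = classify_gene(gene_id, catalog, abundances, observed, config)
        total_abund = sum(
            abundances.get(t, 0.0) for t in catalog.genes[gene_id]
        )
        juncs = catalog.gene_junctions(gene_id)
        R, C, om, multi = _gene_vectors(juncs, observed, predicted)
        uj = float(R.sum())
        denom = float(R.sum() + multi.sum())
        uf = uj / denom if denom > 0 else math.nan
        ratio = intron_exon.get(gene_id, math.nan)
        if ratio is None:
            ratio = math.nan
        jcc = (
            jcc_score(R, C, om, config) if status == STATUS_SCORED else math.nan
        )
        passes = (
            status == STATUS_SCORED
            and uj >= config.min_unique_junction_reads
            and uf >= config.min_unique_fraction
            and (math.isnan(ratio) or ratio < config.max_intron_exon_ratio)
        )
        rows.append(
            (gene_id, jcc, status, uj, uf, ratio, total_abund, passes)
        )
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def permute_counts_within_genes(
    abundances: Mapping[str, float],
    catalog: AnnotationCatalog,
    seed: int,
) -> dict[str, float]:
    """Reassign the estimated counts among each gene's transcripts by a
    seeded uniform random permutation (the within-gene permutation control);
    the per-gene count multiset is preserved."""
    rng = np.random.default_rng(seed)
    out = dict(abundances)
    for gene_id in sorted(catalog.genes):
        txs = sorted(catalog.genes[gene_id])
        if len(txs) < 2:
            continue
        counts = [abundances.get(t, 0.0) for t in txs]
        perm = rng.permutation(len(txs))
        for t, p in zip(txs, perm):
            out[t] = counts[p]
    return out


def inferential_cv(
    bootstrap_counts: pd.DataFrame,
    catalog: AnnotationCatalog,
) -> tuple[pd.Series, pd.Series]:
    """Coefficient of variation of bootstrapped counts per transcript and
    per gene (gene level: member-transcript rows summed first).

    CV = sample standard deviation / mean; NaN when the mean is 0.
    Requires at least two bootstrap replicates.
    """
    if bootstrap_counts.shape[1] < 2:
        raise ValueError("at least 2 bootstrap replicates required")

    def cv(df: pd.DataFrame) -> pd.Series:
        mean = df.mean(axis=1)
        sd = df.std(axis=1, ddof=1)
        out = sd / mean
        out[mean == 0] = math.nan
        return out

    tx_cv = cv(bootstrap_counts)
    gene_of = {
        t: catalog.transcripts[t].gene_id
        for t in bootstrap_counts.index
        if t in catalog.transcripts
    }
    known = bootstrap_counts.loc[list(gene_of)]
    gene_counts = known.groupby([gene_of[t] for t in known.index]).sum()
    return tx_cv, cv(gene_counts)


@dataclass(frozen=True)
class ScoreComparison:
    """Agreement between two per-gene score tables on shared scored genes."""

    n_shared: int
    pearson: float
    spearman: float
    mean_difference: float
    n_higher: int
    n_lower: int
    n_equal: int


def compare_scores(a: pd.DataFrame, b: pd.DataFrame) -> ScoreComparison:
    """Compare two gene score tables (e.g., two annotation catalogs or two
    quantifiers) over genes scored in both."""
    sa = a[a["status"] == STATUS_SCORED].set_index("gene_id")["jcc"]
    sb = b[b["status"] == STATUS_SCORED].set_index("gene_id")["jcc"]
    shared = sorted(set(sa.index) & set(sb.index))
    if not shared:
        raise ValueError("no shared scored genes between the two tables")
    x, y = sa[shared].to_numpy(), sb[shared].to_numpy()
    if len(shared) >= 2 and np.ptp(x) > 0 and np.ptp(y) > 0:
        pear = float(stats.pearsonr(x, y).statistic)
        spear = float(stats.spearmanr(x, y).statistic)
    else:
        pear = spear = math.nan
    diff = x - y
    return ScoreComparison(
        n_shared=len(shared),
        pearson=pear,
        spearman=spear,
        mean_difference=float(diff.mean()),
        n_higher=int(np.sum(diff > _TIE_TOL)),
        n_lower=int(np.sum(diff < -_TIE_TOL)),
        n_equal=int(np.sum(np.abs(diff) <= _TIE_TOL)),
    )
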