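import logging

import numpy as np
import pytest

from jccscore.annotation import (
    AnnotationCatalog,
    GenomicInterval,
    TranscriptModel,
)
from jccscore.synthetic import (
    GroundTruth,
    SynthConfig,
    make_toy_catalog,
    make_utr_swap,
    simulate_observed,
)

logging.getLogger("jccscore").setLevel(logging.WARNING)


def make_tx(tx_id, gene_id, exons, strand="+", chrom="chr1", **kw):
    """Compact transcript constructor from (start, end) pairs."""
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    for name in ("cds", "utr5", "utr3"):
        if name in kw:
            kw[name] = tuple(
                GenomicInterval(chrom, s, e, strand) for s, e in kw[name]
            )
    return TranscriptModel(tx_id, gene_id, ivs, **kw)


@pytest.fixture
def two_exon_tx():
    return make_tx("T1", "G1", [(100, 200), (300, 400)])


@pytest.fixture
def toy_catalog():
    """Two genes, three transcripts, one shared-intron junction pair."""
    txs = [
        make_tx("T1", "G1", [(100, 200), (300, 400), (500, 600)]),
        make_tx("T2", "G1", [(100, 200), (500, 600)]),
        make_tx("T3", "G2", [(1000, 1100), (1300, 1400)], strand="-"),
    ]
    return AnnotationCatalog.from_transcripts(txs)


@pytest.fixture(scope="session")
def null_fixture():
    """50-gene multi-isoform fixture with noise-free expected counts drawn
    from the generator's own bias model (the parameter-recovery null)."""
    cfg = SynthConfig(
        n_genes=50, seed=1, isoforms_per_gene=(2, 4), emit_fragments=False
    )
    fix = make_toy_catalog(cfg)
    bias = cfg.bias_model()
    sim = simulate_observed(fix.catalog, GroundTruth(), bias, cfg, fix.genome)
    seqs = fix.transcript_sequences()
    return cfg, fix, bias, sim, seqs


@pytest.fixture(scope="session")
def swap_fixture():
    """40-gene fixture with 3'UTR-swap hybrids and the Jaccard-oracle
    quantifier abundances."""
    cfg = SynthConfig(n_genes=40, seed=11, emit_fragments=False)
    fix = make_toy_catalog(cfg)
    truth = make_utr_swap(fix.catalog, seed=cfg.seed)
    bias = cfg.bias_model()
    sim = simulate_observed(fix.catalog, truth, bias, cfg, fix.genome)
    seqs = fix.transcript_sequences()
    return cfg, fix, truth, bias, sim, seqs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
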