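# Methods

## The score

For gene *i*, `JCC_i = Σ_j g(ω_j)|s·C_j − R_j| / Σ_j g(ω_j) R_j` over the
gene's annotated junctions, with `s = (Σ g(ω)R / Σ g(ω)C)^β`. `R_j` is the
number of uniquely mapping reads the aligner reports across junction *j*,
`C_j` the number predicted from abundance estimates and coverage profiles,
and `ω_j` the fraction of junction-spanning reads that map uniquely.

Junction identity is the intron interval plus strand (0-based half-open
internally; GTF and SJ.out.tab conventions are converted at the I/O
boundary). A junction shared by transcripts of several genes belongs to the
junction set of each. A junction with no observed reads keeps `ω = 1`, so a
predicted-but-unobserved junction still contributes `|s·C_j − 0|` — this is
exactly the signature of a gene whose estimated isoform mix implies
junctions the data never shows.

Weight functions: `step` (1 iff `ω ≥ 0.75`, the default), `ramp` (linear
rise to 1 at the threshold) and `logistic` (smooth step, steepness 20 by
default). All map [0, 1] → [0, ∞) and are nondecreasing. `β` is restricted
to {0, 1} in the configuration; the exponent form is kept internally.

Numerical choices:

* With `β = 1` the weighted terms are computed as
  `w·s·C = (w·C / Σ w·C) · Σ w·R`, each ratio in [0, 1], so the scale
  factor cannot overflow when the weighted predicted mass is tiny.
* `β = 1` with zero weighted predicted mass and positive observed mass is
  a 0/0 case of the definition; the scale factor is defined as 1, giving a
  score of exactly 1. The condition is deterministic and documented here
  rather than producing NaN.
* A gene is scorable iff `Σ g(ω_j) R_j > 0`. The ≥ 25-unique-reads,
  ≥ 75%-unique-fraction and < 0.1 intron/exon-ratio thresholds are
  *reporting* filters (the `passes_filters` column), not validity
  conditions; a missing intron/exon ratio (no fragment evidence) does not
  fail the filter.
* Score comparisons count two scores as equal when they differ by less
  than 1e-12.

## Coverage prediction and the bias model

The predicted coverage of transcript base *p* is the sum over fragment
placements (start *s*, length *l*) covering *p* of

`pmf(l) · w_GC(bin) · w_pos(bin) · w_kmer(5' end) · w_kmer(3' end)`,

normalized to sum 1 per transcript, then scaled by estimated count × mean
fragment length. The predicted junction-spanning reads from a transcript
are the scaled coverage at the last base of the exon preceding the junction
in transcript orientation (on the minus strand this is the genomic start of
the downstream-coordinate exon), summed strand-aware across transcripts.

The bias model is deliberately simple and pluggable — independent
multiplicative binned terms rather than a joint GLM:

* **Fragment length pmf** — empirical distribution truncated to the
  0.5th–99.5th percentiles (stabilizes the tails); its mean is the "mean
  fragment length" used for scaling.
* **Fragment GC** — 25 bins of fragment GC fraction.
* **Position** — 20 bins of the fragment midpoint's relative position; a
  single curve for all transcript lengths.
* **End k-mers** — k = 6 by default; the 3' end uses the reverse
  complement of the terminal k bases (the 5' end of the mate).

Each weight is the ratio of observed to expected-under-uniform-placement
bin counts with a 0.5-count pseudocount, normalized so the
expected-mass-weighted mean is 1 (weighting by expected mass keeps noisy
near-empty bins from shifting the calibration of the bins that matter).
Expected GC/position counts are exact placement enumerations per fragment
length, vectorized with cumulative sums; the expected k-mer frequency is
approximated by the background k-mer frequency of the training sequences,
which is indistinguishable at the weight-ratio level and much cheaper than
a placement-weighted enumeration over all lengths.

Fitting uses single-isoform genes with transcript length 600–7,000 nt and
500–10,000 assigned fragments, so read assignment within the training set
is unambiguous. Transcripts shorter than the minimum modelled fragment
length, transcripts the caller flags as read-free (zero assigned
fragments when fragment evidence is provided), and transcripts shorter
than the k-mer fall back to a uniform profile rather than being dropped.
When no bias model or sequences are available at all, every profile is
uniform (logged as a warning); with `β = 1` the score is then invariant to
the assumed mean fragment length, which only enters as a common factor
within each gene.

## Synthetic data

The generator emulates the quantities the score consumes — junction-level
expected counts — rather than raw reads. Defaults (chosen once as the study
conditions of the test suite):

* 30 genes (50 in the null-recovery fixture), 1–3 isoforms per gene, 3–6
  exons of 100–400 nt, introns 200–800 nt, uniform base composition, both
  strands.
* Fragment lengths ~ N(250 nt, 25 nt) truncated at ±3 sd; flat bias
  weights, so the truth model is exactly representable by the fitted form.
* ~1,000 expected read pairs per expressed transcript; each transcript of
  an unmodified gene is expressed with probability 0.8 with a Gamma(4)
  count (CV 0.5), giving the within-gene heterogeneity the permutation
  control needs.
* Half the genes (with ≥ 4 exons) carry a same-start short/long 3'UTR
  isoform pair with length difference 1.2–2 kb; the long-UTR isoform also
  skips one internal exon, because a pair differing *only* in the UTR
  yields a swap hybrid identical to an annotated isoform (such genes are
  detected and left unmodified, as the dedup rule requires).

The 3'UTR-swap scenario picks, per eligible gene, one short-UTR and one
long-UTR transcript at random, combines the 5'UTR+CDS exon structure of one
with the 3'UTR of the other, and simulates that gene's reads only from the
hybrid, which is *not* in the catalog given to scoring. The recorded
`utr_choice` and UTR fraction allow stratified analyses. The bundled
"oracle quantifier" assigns each modified gene's reads to the annotated
transcript with the highest Jaccard similarity (of exonic genomic
positions) to the hybrid, ties broken lexicographically — a stand-in for
the common behaviour of real quantifiers on misannotated genes.

Noise modes: `none` emits exact expected counts (possibly fractional —
the SJ.out.tab reader accepts decimal counts for this reason; real STAR
files are integral and parse unchanged), `round` rounds deterministically,
`poisson` draws seeded Poisson counts. The `none` mode exists so the null
case is exact: with the true abundances and the generating bias model, the
pipeline reproduces every observed count and all scores are 0 to floating
point. A configurable multi-mapping fraction moves that share of each
junction's reads to the multi-mapper column (`ω = 1 − fraction`). All
outputs are pure functions of (config, seed); every randomness source takes
an explicit integer seed.

What the generator does **not** emulate: sequencing errors and quality,
non-uniform genomic base composition, paralogy/shared sequence between
genes (multi-mapping is injected at the junction-count level, not derived
from alignment), intron-retaining reads, and real quantifier behaviour
beyond the Jaccard oracle. Passing tests therefore demonstrate correctness
of the score machinery and its documented properties, not performance on
real libraries.

## Design choices in open territory

* 3'UTR start-position grouping for the catalog expansion and the swap is
  **within-gene**; genome-wide grouping would tie unrelated genes together.
* The unique fraction used for the gene-level 75% filter is read-weighted
  (`Σ R / Σ (R + multi)` over the gene's junctions), not a per-junction
  average.
* Strand handling: junction strands must match exactly; STAR's
  undefined-strand records (code 0) match nothing in stranded mode (and
  are logged) and match either strand in `--unstranded` mode.
* Observed junctions absent from the annotation are excluded from scoring
  (the score is defined over annotated junctions) but exported in a
  diagnostics table.
* Problem sizes in the test suite (50-gene fixtures, 10,000 random gene
  configurations, ~4×10⁴–6×10⁴ fragments for bias-recovery checks) were
  chosen to make the statistical assertions stable at desk scale.

## Limitations

* The bias model's independent-terms assumption ignores interactions
  (e.g., GC × position) that a joint GLM would capture; the positional
  term is shared across transcript-length classes.
* Fragment placement on the genome for the intron/exon ratio uses the
  fragment's transcript-coordinate span mapped to genomic ends; spliced
  fragments are not split into blocks.
* The score has no sampling distribution attached: it flags incompatibility
  but does not separate shot noise from misannotation at low coverage
  (hence the ≥ 25-unique-reads reporting filter).
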