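# Methods

This note documents the models and procedures implemented in `smdiv`, the
defaults chosen where the underlying study protocol leaves room, and what
the synthetic-data tests do and do not demonstrate.

## Primer handling and in-silico PCR

Degenerate primers are treated as IUPAC position sets. Matching is
**primer-anchored and ungapped**: a mismatch is any target position whose
base lies outside the primer's set, and per-primer identity is
1 − mismatches/primer length. This replaces an external aligner while
preserving the ≥90% identity filter used for reference-set construction;
indel-tolerant primer matching is deliberately out of scope. Minus-strand
hits are found on the reverse complement and reported in forward, 0-based,
half-open coordinates. Amplicons include both primer sequences (the
targeted products of ~200 bp ACP, ~700 bp AD and ~1,400 bp KS regions are
sized with primers); primer clipping is a separate read-preparation step.
The default mismatch tolerance when matching primers to reads (as opposed
to references) is `max_mismatch=2`, exposed on `PrimerPair`.

The bundled pairs are A3/A7R (AD, degeneracy 128/96), K1/M6R (KS and
methyl-malonyl-CoA, 12/4) and Pks firmi_F/R (ACP, 65,536/32,768);
degeneracies are validated against exhaustive enumeration in the tests.

## Read preparation

Stage order is fixed: quality filter → demultiplex → dereplicate → chimera
flag → trim; total read mass (sum of duplicate counts) is non-increasing
at every stage and every stage logs input/output counts.

- **Quality windows.** Windows of `window` bases (default 50) slide one
  base at a time; the read is truncated at the start of the first window
  whose mean quality falls below `q_cutoff` (default Q20). Reads shorter
  than one window after truncation are dropped. "Ambiguity removal" is
  implemented as dropping reads containing any non-ACGT base; the
  alternative reading (masking single calls) is noted but not used, and
  the choice is logged.
- **Demultiplexing** requires an exact 10-nt barcode at the 5' end;
  barcode and (when present at the expected offset) forward primer are
  clipped. Unmatched reads go to an `unassigned` bin.
- **Dereplication** is exact-sequence, pooled across samples with
  per-sample size bookkeeping (so downstream OTU tables retain sample
  resolution), followed by removal of groups below `min_size=2`
  (singleton removal). Singleton removal precedes chimera checking; the
  study protocol does not state the order, so it is fixed and documented
  here.
- **Chimera test.** A deliberate simplification of de-novo two-parent
  detection keeping the abundance-skew idea (parents must be ≥1.9× the
  query's abundance) and crossover evidence. For a parent pair (A, B),
  sites are classified as A-votes (query matches A, not B) or B-votes;
  the query is flagged when some breakpoint gives ≥1 A-vote and at most
  `vote_error_tolerance` (default 1%) contradicting votes in the prefix,
  the mirror condition in the suffix, and a two-parent model identity at
  least `min_crossover_gain` (default 0.005, i.e. one extra matching base
  per 200 bp) above the best single parent. Sequences are compared
  ungapped over their common prefix, adequate after length trimming. This
  is not claimed to reproduce any external tool's output; its operating
  characteristics are established by simulation (below).
- **Trimming** cuts all retained reads to the shortest retained length,
  after dropping reads below an optional floor.

## Clustering and identity

Pairwise identity uses a global alignment (match +1, mismatch −1, gap open
−2, gap extend −1, via Bio.Align.PairwiseAligner) with identity = matches /
alignment columns, **terminal-gap columns excluded** (amplicons are
length-trimmed but reference fragments may be ragged); internal gaps count
as non-matching columns. Because co-optimal alignments can differ between
argument orders, the argument pair is canonicalised before aligning so the
measure is exactly symmetric. Greedy centroid clustering visits sequences
in (size desc, length desc, id asc) order; each sequence joins the first
centroid within the threshold, else seeds a new one. The scheme is
order-dependent, so this ordering is part of the contract and output is
deterministic. An optional 8-mer prescreen accelerates centroid search and
can be switched off to preserve the exact contract.

Shared-cluster accounting pools query and reference sequences, clusters at
each threshold, and partitions clusters into query-only / reference-only /
shared (≥1 member of each origin); the three counts always sum to the
total.

## Diversity and overlap

Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) — defined
when F2 = 0 and the default of common toolchains; the classic F1²/(2F2)
form is available behind a flag. Rarefaction subsamples without
replacement (multivariate hypergeometric) with 10 iterations per depth by
default. The overlap of N communities is
(ᾱ/γ − 1/N)/(1 − 1/N), clipped to [0, 1], computed on Chao1 richness with
the observed-OTU version reported alongside. A pooled estimate below the
largest per-site estimate is treated as estimator noise (warning), not an
error. Reported percentages are rounded half-up, with raw ratios always
retained: direct rounding of the published coverage ratios reproduces the
40% mean and the 41% P3 cell but gives 33.4% (pooled) and 38.5% (P1) where
the published table prints 34% and 39%; since that rounding rule is
unknown, the package reports raw ratios and does not chase those two
cells.

## Sharing

Within each (site, stage) group a cluster counts as present only with
nonzero counts in ≥2 of 3 biological replicates; a cluster survives
globally if it passes in at least one group. Venn region counts partition
the filtered clusters; percentages use the filtered union as denominator
(the original figure convention is unstated; the choice is recorded in the
report). Site comparisons pool stages after replicate filtering.
"Shared between stages" means replicate-consistent presence in both stages
of the same site.

## Phylogeny

Distances are 1 − pairwise identity, replacing an external
multiple-alignment step so the tree contract stays self-contained; a
pre-computed distance matrix is accepted for users who run their own MSA.
Neighbor joining is the standard Q-matrix agglomeration with
deterministic tie-breaking by the lexicographically smallest pair of clade
labels (a clade is labelled by its smallest leaf). Negative branch-length
estimates are clamped to zero and logged. On additive matrices the
implementation reconstructs the generating tree exactly (tested against
path-length matrices of random binary trees and cross-checked against
scikit-bio's NJ).

## Ordination and inference

NMDS minimises Kruskal stress-1 (scikit-learn's non-metric MDS on
precomputed Bray-Curtis dissimilarities) over 8 random starts, 300
iterations, eps 1e−9; the Shepard correlation (Pearson, upper triangles of
input dissimilarities vs embedded distances) diagnoses fit. NMDS preserves
rank order only, so even perfectly representable configurations guarantee
near-zero stress but not a perfectly linear Shepard plot.

Differential abundance fits a per-OTU negative-binomial regression (log
link, NB2 variance μ + αμ²) by iteratively reweighted least squares,
batched across OTUs in numpy. Dispersion is estimated per OTU by profile
maximum likelihood under the full model and **held fixed** for
reduced-model and bootstrap refits — the LRT is then conditional on the
full-model dispersion, a standard device that stabilises small-sample
fits and makes the ~10⁵ bootstrap refits tractable. The multivariate
statistic is the sum of per-OTU LRTs over converged OTUs. Significance
comes from a residual bootstrap: randomized PIT residuals are computed
under the reduced (null) model, permuted **jointly across rows** (one
permutation per resample, preserving between-OTU correlation), inverted
through the null quantile function, and the statistic is recomputed;
p = (1 + #{stat* ≥ stat})/(B + 1), default B = 999. This follows the
sum-of-univariate-LRT idea of multivariate abundance GLMs without claiming
bit-for-bit equivalence with any external package; calibration is by
simulation instead (type-I error at nominal 0.05 lands in [0.01, 0.10]
over 200 null repetitions with 199 resamples).

For the correlation step, "differentially abundant" is thresholded at raw
p < 0.05 by default (configurable); Benjamini-Hochberg-adjusted values are
computed and reported alongside but not used for the default filter, since
the original analysis states no correction. Marker (16S) OTUs are
restricted by taxon-pairing rules (Firmicutes vs ACP; Actinobacteria,
Firmicutes and Proteobacteria vs KS, methyl-malonyl-CoA and AD) and to
genera above 1% mean relative abundance in the marker table; Spearman's
rho uses tie-corrected ranks.

## Functional assignment

Queries are translated in six frames and locally aligned (affine-gap
Smith-Waterman, BLOSUM62, gap open −11 / extend −1) against characterized
domains. Bit scores use the ungapped Karlin-Altschul approximation for
BLOSUM62 (λ = 0.3176, K = 0.134), E = m·n·2^(−bit) with n the total
reference residues. The contract is the cutoff logic — best hit per query
(bitscore desc, identity desc, domain id asc) passes iff identity ≥ 70%,
alignment length ≥ 200 aa (AD) or 100 aa (KS, methyl-malonyl-CoA, ACP),
and E ≤ 1e−25 — not equivalence with an external search tool. The bundled
reference set is **synthetic**: random proteins labelled with compound
names from the secondary-metabolite literature, generated
deterministically in code (`make_synthetic_domain_fixture`); users supply
a real database in the same form.

## Synthetic communities

The generator emulates the targeted study design: 3 sites × 2 vegetation
stages × 3 replicates, lognormal family abundances, a configurable
fraction of families whose abundance shifts (default 4-fold) at
senescence, exact primer binding sites flanking each family, per-base
errors at a 5% aggregate default with indels only inside homopolymer runs
≥3 (a caricature of pyrosequencing chemistry sufficient for testing
dereplication and clustering robustness), and optional two-parent
chimeras with uniform breakpoints. Family sequences radiate from a single
ancestral core on a star phylogeny at a mutation rate placing inter-family
identity below the clustering threshold minus a margin (default 0.95 −
0.08); thresholds whose band would fall below the ~0.65 identity floor of
unrelated sequences are rejected.

Site membership satisfies two constraints at once: exactly
round(overlap × n) families are shared by **all** sites, and the pooled
family count is tuned to 3n/(1 + 2·overlap) by additionally sharing
families between site **pairs**, so that the α/γ overlap statistic of the
true per-site counts equals the overlap parameter. With all-site sharing
alone the statistic would equal o/(3 − 2o), not o.

What the generator does **not** emulate: realistic phylogenetic structure
within families, codon-aware evolution, quality-score/error correlation,
PCR amplification bias, or flowgram-level artefacts. Passing tests
demonstrate correctness of the pipeline's algorithms under controlled
conditions, not performance on real 454 data. One practical consequence of
the 5% per-base default is documented honesty rather than realism: at
200 bp essentially every read is unique, so singleton removal (which on
real data relies on error-free duplicate reads) removes nearly all mass.
The bundled pipeline demo therefore simulates at a 1% per-base rate —
typical of real pyrosequencing — purely so downstream stages have material
to work on; all statistical guarantees are tested at the conditions stated
with them (error-free reads for exact-recovery claims, 5%-style errors
where robustness is the point).

Per-sample read depth defaults to 500 (the protocol states no target);
tests run at 100–400 reads/sample and 5–50 families/site — desk-scale
sizes chosen so the whole suite exercises every stage in well under a
minute each.

## Determinism

Every stochastic stage takes a seed; identical configuration + seed gives
byte-identical outputs (FASTQ, OTU tables, coordinates). The pipeline
manifest records per-stage input/output counts so filtering can be
audited.

## Known limitations

- Greedy clustering is O(clusters × sequences) alignments without the
  k-mer prescreen; it targets dereplicated amplicon sets (10²–10⁴
  uniques), not raw shotgun scale.
- The chimera test assumes length-comparable sequences and ungapped
  comparison; indel-shifted chimeras can escape it.
- E-values use ungapped Karlin-Altschul constants with gapped alignments;
  they order hits sensibly but are not calibrated database E-values.
- The NB bootstrap holds dispersion fixed at the full-model estimate;
  with very few samples per cell the per-OTU dispersion itself is noisy,
  which the bootstrap does not propagate.
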