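# smdiv

**In-silico survey of NRPS/PKS biosynthetic-domain diversity in rhizosphere
amplicon data.**

Soil and rhizosphere bacteria — above all Actinobacteria and Firmicutes —
encode secondary metabolites (antibiotics, siderophores, toxins) in
non-ribosomal peptide synthetase (NRPS) and polyketide synthase (PKS) gene
clusters. Amplicon sequencing of conserved biosynthetic domains (the NRPS
adenylation domain AD, the PKS ketosynthase KS and methyl-malonyl-CoA
transferase, and the Firmicutes PKS acyl carrier protein ACP) with
degenerate primers gives a culture-independent view of that chemical
potential. `smdiv` implements the complete desk side of such a survey, for
microbial ecologists and natural-product researchers:

- **degenerate-primer arithmetic** (IUPAC expansion, mismatch-tolerant
  matching, in-silico PCR, reference-set construction),
- **454-style read preparation** (rolling Q20/50 bp quality windows,
  barcode demultiplexing, dereplication with singleton removal, a
  two-parent de-novo chimera test with a 1.9 abundance skew, common-length
  trimming),
- **greedy centroid OTU clustering** at multiple identity thresholds
  (75–97%), with OTU tables and representative picking,
- **richness and community overlap**: bias-corrected Chao1, rarefaction,
  and the effective-species overlap of N communities,
- **replicate-consistency filtering and Venn-style sharing** across sites
  and vegetation stages,
- **neighbor-joining phylogenies** of representatives with annotated
  Newick output,
- **ordination and inference**: Bray-Curtis NMDS with Shepard diagnostics,
  per-OTU negative-binomial GLMs with likelihood-ratio tests and a
  residual-resampling bootstrap, Spearman correlation of differentially
  abundant marker vs SM OTUs,
- **rule-based functional assignment** of representatives against
  characterized domains (≥70% amino-acid identity, class-dependent minimum
  alignment length, E ≤ 1e−25),
- a **synthetic-community generator** with a ground-truth table, so every
  stage is testable without any external download.

## The overlap model

Per-community (alpha) richness is estimated with bias-corrected Chao1,

    S_chao1 = S_obs + F1(F1 − 1) / (2(F2 + 1)),

from singleton (F1) and doubleton (F2) counts; gamma is the Chao1 richness
of the pooled communities. Because α/γ alone is misleading when communities
barely overlap, richness is treated as an effective number of species and
rescaled:

    overlap = (ᾱ/γ − 1/N) / (1 − 1/N),

which equals 1 for identical communities and 0 for completely distinct
ones (γ = N·ᾱ).

## Worked example

Richness estimates for three rhizosphere sampling sites (per-site Chao1
29,216 / 39,579 / 25,608; pooled 61,301):

```python
>>> import numpy as np
>>> from smdiv.diversity import overlap_statistic
>>> alphas, gamma = [29216, 39579, 25608], 61301
>>> print(f"mean alpha (Chao1): {round(np.mean(alphas))}")
mean alpha (Chao1): 31468
>>> ov = overlap_statistic(alphas, gamma)
>>> print(f"overlap: {ov:.3f} ({round(100*ov, 1)}%)")
overlap: 0.270 (27.0%)
```

Each site hosts on average ~31,468 distinct gene variants, yet the three
sites share only 27% of that diversity — most of the biosynthetic
repertoire is site-specific.

Primer arithmetic from the shell:

```sh
$ smdiv primers count GCNGGNCAYWSNYTNGGNGARTAYA   # ACP forward primer
65536
```

A full synthetic run (simulate → prep → cluster → diversity → sharing →
phylo → stats → annotate), writing OTU tables, richness/sharing reports, a
Newick tree, test tables and a JSON manifest of per-stage read counts:

```sh
smdiv run --seed 5 --outdir runs/demo
```

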