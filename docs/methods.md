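# Methods note

This note documents the models, conventions and numerical choices behind
`viroclean`, in the spirit of a package reference manual. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model and assumptions

The method treats the *negativeome* — the set of vOTUs detected in
negative controls — as a proxy for external contamination, and assumes:

1. Contaminants enter samples and NCs from the same (study-specific)
   sources, so a contaminant strain in a sample is *identical* to the
   strain in an NC of the same study.
2. Resident (biological) strains of an NC-shared species have diverged
   measurably from the contaminant strain, so strain comparison can
   separate them.
3. Detection is presence-based: a vOTU belongs to the negativeome as soon
   as one NC has nonzero post-QC RPKM for it.

Under these assumptions, zeroing only strain-identical cells removes
contamination while preserving resident diversity; the species-level
variant is retained as the conservative comparator.

## Thresholds (defaults)

| parameter | default | unit | meaning |
|---|---|---|---|
| `ani_min` / `af_min` | 95 / 85 | % | species-rank dereplication (AF on the shorter sequence), inclusive |
| `breadth_min` | 0.75 | fraction | counts with breadth **strictly below** are zeroed |
| `min_length` | 1000 | bp | vOTU rows shorter than this are dropped |
| viral/host genes | strict `<` | — | dropped only when viral genes are *fewer* than host genes; ties kept |
| `min_cov` | 1 | reads | a position is covered (and all bases with depth ≥ 1 are alleles) at total depth ≥ min_cov |
| `popani_min` | 99.999 | % | strain identity, inclusive |
| `min_fraction` | 0.75 | fraction | mutually covered genome required in analysis mode; waived in decontamination mode |
| read-mapping estimator | > 0.50 / > 0.75 | breadth | strictly greater ("more than") |

Boundary semantics follow the printed rules exactly: the strain decision
is made on integer difference counts via rational arithmetic
(`d/|C| ≤ (100 − popani_min)/100` with `popani_min` parsed as a decimal
literal), never on pre-rounded percentages, so one disjoint-allele
difference over 100,000 compared positions is exactly the 99.999%
boundary and is shared.

## Dialect choices

- **Pileup interchange.** Per-position TSV
  (`sample_id, votu_id, pos, A, C, G, T`), 1-based inclusive coordinates,
  uncovered positions absent, all-zero rows forbidden. This is a toolkit
  convention chosen for desk-scale testability; BAM-era pipelines pass
  alignments to a profiler instead.
- **Alignment records.** The de-facto 12-column tabular format; minus-
  strand hits are encoded with descending target coordinates on disk and
  normalized to ascending + strand flag in memory.
- **HSP aggregation for ANI/AF.** ANI is the alignment-length-weighted
  mean identity over HSPs (no overlap trimming); AF merges overlapping
  intervals on the shorter sequence before taking the union. Simple and
  order-independent; documented as a dialect, not an inference of any
  upstream tool's behavior.
- **Greedy clustering order.** Length descending, id ascending tie-break;
  a contig joins the first qualifying representative in seeding order.
  Representatives are therefore the longest members and the result is
  invariant to input row order.
- **Consensus ties.** At equal depth the lexicographically smallest base
  (A < C < G < T) wins — an explicit, reproducible convention.
- **Linkage.** Strain trees use complete linkage by default (configurable,
  recorded in the output); node heights are half the merge distance so
  leaf-to-leaf path lengths reproduce 1 − popANI. Pairs excluded by the
  75% rule are *not* imputed; an incomplete leaf set is an error listing
  the missing pairs.
- **RPKM denominator.** "Per million reads mapped" uses the mapping
  totals computed *before* breadth zeroing (the denominator describes the
  mapping, not the filtered table); the totals are caller-supplied, so
  the post-filter convention is available by passing filtered sums.
- **% abundance.** Relative RPKM share per sample (RPKM divided by the
  sample's RPKM sum). Shannon uses natural log.
- **Permutation Wilcoxon.** The statistic is the rank sum of the first
  group on pooled mid-ranks; two-sided extremeness is measured around the
  expected rank sum; p uses the +1 correction (never 0) and is
  deterministic per seed.

## Internal aligner

`align_pair` runs optimal local alignment (Smith–Waterman, affine gaps,
match +1 / mismatch −1 / open −3 / extend −1) on both strands for inputs
up to 2 kb, and a k-mer-seeded (k = 11) ungapped X-drop extension over
merged diagonals above that. The seeded route trades gap handling for
speed; at the divergence levels relevant to the 95% species threshold
(substitution-dominated), its ANI stays within half a point of the
exhaustive route (asserted in tests). For heavily rearranged or
indel-rich genomes an external all-vs-all search can be supplied as a
12-column table instead.

## Synthetic data: what it emulates and what it does not

Defaults (chosen once as a scaled-down but structurally faithful design,
and used by the test suite and acceptance script):

- 3 studies × (8 infants + 4 mothers + 2 NCs); 50 vOTUs of 8–12 kb.
- Richness log-normal per group: infant median 8 (σ = 0.7), maternal
  median 16 (σ = 0.4) — infants poorer than mothers, mirroring early-life
  gut viromes at 1/30 scale.
- Each study's NC pool (8 vOTUs) is drawn from a 12-vOTU cross-study
  contaminant pool; each NC detects pool members with probability 0.85.
  The cross-study overlap is deliberately larger than in real multi-study
  data, where contamination is mostly study-specific: at this scale some
  overlap is required for the external-catalog estimator to be exercised
  at all.
- 60% of samples are contaminated; contaminated samples carry
  1 + Poisson(1) NC vOTUs with the *identical* NC strain at log-normal
  abundance shares (median ≈ 1.5%, long-tailed, capped at 99%).
- Resident strains diverge from the ancestral/NC strain by 50–200
  substitutions; at 10 kb genomes this puts resident popANI ≤ 99.5%,
  well below the 99.999% identity threshold.
- Coverage is complete and pileups error-free by default, making popANI
  arithmetic exact; `gap_fraction` places a contiguous uncovered block
  per genome copy and `error_rate` widens allele sets (never silencing
  the true base).

Not emulated: read-level errors and mapping ambiguity, MDA amplification
bias, assembly artifacts and chimeras, abundance correlation structure
between contaminants, and real taxonomic composition. Passing the
recovery tests therefore demonstrates the *logic* of strain-level
decontamination under its stated assumptions — not robustness to
violations of assumption 1 (a contaminant that mutates or a resident
strain identical to the NC strain by chance is out of model).

## Problem sizes

Simulated designs are intentionally small (tens of samples, ~50 genomes
of ~10 kb) so that oracle re-implementations — brute-force per-position
popANI scans, exhaustive greedy clustering, exhaustive permutation
enumeration — remain feasible and the whole suite runs in minutes on one
CPU. The acceptance script aggregates 5 replicate datasets per run.

## Known limitations

- The internal aligner is not a substitute for a sensitive all-vs-all
  search on large, repeat-rich corpora; feed external alignments for
  production dereplication.
- Strain comparison needs a pileup for both members of a pair; pairs
  without one degrade to "not promoted" with a warning, so sensitivity is
  bounded by profiling coverage.
- External estimation is a correlate of contamination, not a removal
  method; the estimate is attached as a per-sample covariate for
  downstream correction models, which are out of scope.
- Frequency-based (prevalence-model) decontamination is intentionally not
  implemented; positive-control spikes can be handled by adding their
  reference sequences to the catalog.
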