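# viroclean

Negative-control-based contamination assessment and **strain-level
decontamination** for VLP-enriched virome studies.

## The problem

Gut virome samples prepared by viral-like-particle (VLP) enrichment are
low-biomass libraries: reagent, kit and environmental ("kitome")
sequences can make up a large share of what is sequenced, especially in
early-life samples with low viral richness. Negative controls (NCs) —
no-template buffer/reagent libraries processed alongside the samples —
capture this *negativeome*, and the set of virus species (vOTUs) detected
in NCs is a proxy for external contamination.

Removing every NC-detected vOTU from the samples (species-level
decontamination) is too aggressive: a sample and an NC can carry the same
viral *species* but different *strains*, in which case the sample's strain
is likely a genuine biological signal. `viroclean` implements the
strain-aware alternative: a sample's vOTU is zeroed only when its strain
is *identical* to an NC strain.

## The method

- **vOTUs.** Contigs are dereplicated at the MIUViG species rank: 95%
  average nucleotide identity (ANI) over 85% alignment fraction of the
  shorter sequence, greedy longest-first clustering.
- **Abundance.** Read counts with breadth of coverage < 75% of the contig
  are zeroed; counts become RPKM
  (`count / (length/10³) / (mapped_reads/10⁶)`); vOTU rows shorter than
  1000 bp, with fewer viral than host genes, or flagged as plasmids are
  dropped.
- **Strains.** Per sample and vOTU, an allele profile is built from the
  pileup at minimum coverage 1. For two samples, over the mutually
  covered positions *C*:

  - popANI = 100·(1 − *d*/|*C*|), where *d* counts positions whose
    observed allele sets are **disjoint**;
  - conANI counts positions whose consensus bases differ (so
    popANI ≥ conANI).

  Strains are *shared* when popANI ≥ 99.999% (inclusive, decided with
  exact rational arithmetic). Analyses additionally require ≥ 75% of the
  genome to be mutually covered; decontamination waives that requirement
  so shallow NC coverage cannot rescue a contaminant.
- **Decontamination.** Strain level zeroes exactly the sample×vOTU cells
  backed by a strain-identity call against an own-study NC; species level
  zeroes every own-study NC-shared vOTU. Reports include per-sample
  richness drops and shared richness/abundance percentages.
- **External estimation.** For studies without internal NCs,
  contamination is estimated leave-own-study-out against a negativeome
  catalog: the % of a sample's vOTUs found in other studies' NC entries
  (and, as a weaker alternative, the % of reads mapped to catalog contigs
  covered to > 50%/75% breadth).
- **Statistics.** Permutation Wilcoxon rank-sum (N = 10,000 two-sided),
  Spearman concordance, Benjamini–Hochberg adjustment, 1 − Bray–Curtis
  similarity, and ultrametric strain trees from 1 − popANI distances.

A deterministic synthetic-data module generates multi-study designs with
planted NC-identical contaminant strains and divergent resident strains,
so every stage is testable without any sequencing data.

## Worked example

```python
from viroclean import synthetic, decontam

ds = synthetic.simulate_dataset(synthetic.SimConfig(seed=7))
comps = synthetic.strain_comparisons(ds, scope="own_study")
outcome = decontam.decontaminate(ds.matrix, comps)
per = outcome.report.per_sample
```

On the default design (3 studies × 12 samples + 2 NCs, 50 vOTUs) this
prints:

```
samples sharing vOTUs with own NCs: 33/36
samples sharing an identical strain: 24/36
median richness drop, strain level:  12.5%
median richness drop, species level: 25.0%
sensitivity vs planted truth: 1.00, false-removal rate: 0.00
external-catalog estimate vs truth, Spearman rho: 0.63
```

Most samples share *species* with NCs, fewer share identical *strains*;
strain-level cleaning removes exactly the planted contaminants (perfect
sensitivity, no false removals) and halves the richness loss relative to
species-level cleaning — the reason to decontaminate at strain rank.

The same pipeline is scriptable from a shell:

```bash
viroclean run-all --seed 7 --outdir run/
viroclean simulate --seed 1 --outdir fx/ --with-pileup
viroclean cluster --fasta contigs.fa --out clusters.tsv
```

`run-all` writes the RPKM table, both cleaned matrices, the negativeome
catalog, strain comparisons, external estimates, a JSON report and a
manifest (config hash + seed) sufficient to re-execute the run.

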