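# opsinconv

Analysis of gene conversion and purifying selection on tandemly duplicated
L/M opsin genes.

## The problem

Catarrhine primates carry long- (L) and middle- (M) wavelength-sensitive
cone opsin genes in a tandem array on the X chromosome; together with the
autosomal S opsin they enable routine trichromacy. The two paralogs are
~96% identical and exchange sequence by inter-paralog gene conversion,
which homogenizes them — yet their spectral difference, carried by three
amino acids (residues 180, 277 and 285), persists across species. The
standard explanation is a tug of war: conversion homogenizes the genes at
the individual level, and purifying selection removes conversion products
that erase the spectral difference, so homogenization accumulates in
introns while the central exons stay divergent.

`opsinconv` packages the analyses used to detect that signature in
population samples of the exon 3 – exon 5 region (~3.6 kb spanning the
tuning residues), for five-species data sets of gibbon-like design or for
any alignment following the same conventions:

* **Genotype calling** from the three tuning residues, with peak
  absorption (λmax) inferred by the additive model
  λmax = 560 − 7·[Ala180] − 8·[Phe277] − 15·[Ala285] nm.
* **Diversity and divergence**: within-group nucleotide diversity π and
  between-group divergence *d* as mean pairwise p-distances on
  complete-deletion columns; synonymous/non-synonymous components by the
  Nei–Gojobori pathway method; bootstrap SEs (1000 replicates) and
  one-tailed Z tests.
* **Among-group phylogenies**: neighbor-joining on Jukes–Cantor-corrected
  divergences, −(3/4)·ln(1 − 4p/3), with column-bootstrap bipartition
  supports — the exon tree keeps the ancient duplication while the intron
  tree clusters paralogs within lineages.
* **Gene-conversion detection** (Sawyer-style): maximal runs of identical
  polymorphic sites between sequence pairs, tested against a permutation
  null of the alignment-wide maximum run — a built-in multiple-comparison
  correction over all pairs and fragments.
* **Divergence-vs-polymorphism contrasts**: per-species 2×2 tables of
  fixed inter-paralog differences vs polymorphisms at synonymous sites vs
  introns with two-sided Fisher exact tests, plus McDonald–Kreitman, HKA
  and D′ linkage disequilibrium utilities.
* **A forward simulator** of the duplicated pair on a species tree —
  Jukes–Cantor mutation, inter-paralog conversion with geometric tract
  lengths, and purifying selection as rejection of events that change a
  constrained amino acid — providing ground truth for every stage.

## Worked example

Simulate a five-species data set under the default scenario (heavy intron
conversion, full purging of amino-acid-changing events) and run two stages:

```sh
opsinconv simulate --seed 2 --outdir out
opsinconv genotype -a out/simulated_alignment.fasta -o out/genotypes.tsv
opsinconv contrast -a out/simulated_alignment.fasta -o out/contrast.tsv
```

`genotypes.tsv` begins:

```text
id         species  res180  res277  res285  gene_call  spectral_hybrid  lambda_max_nm
1_Hag_M_L  Hag      Ser     Tyr     Thr     L          False            560.0
1_Hag_M_M  Hag      Ala     Phe     Ala     M          False            530.0
```

Every simulated sequence is called L (Tyr277 + Thr285, λmax 560 nm) or M
(Phe277 + Ala285, λmax 530 nm); no spectral hybrids appear because the
simulator's purifying selection rejects events that alter the tuning
residues. `contrast.tsv` holds the per-species divergence-vs-polymorphism
table:

```text
species  div_syn  div_intron  poly_syn  poly_intron  fisher_p
Hag      7        13          2         20           0.0622
Hpi      7        9           0         16           0.0068
Ssy      8        18          0         16           0.0159
```

Reading the first row: among gap-free sites, 7 synonymous and 13 intron
sites are fixed differences between the L and M groups, while 2 synonymous
and 20 intron sites are polymorphic — the divergence-to-polymorphism ratio
is far lower in introns (13:20) than at synonymous sites (7:2), the
footprint of intron-restricted homogenization, with the two-sided Fisher
P per species. `opsinconv all -c config.yml` runs every stage (genotypes,
divergence/diversity with Z-tests, contrast tables, exon and intron trees,
conversion tracts) from one YAML config.

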