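# Methods

## Scope and data model

`opsinconv` analyses aligned population samples of a tandemly duplicated
gene pair — concretely the L/M cone opsin exon 3 – exon 5 region — for the
joint footprint of inter-paralog gene conversion and purifying selection.
All stages operate on an `Alignment` of equal-length records whose IDs
follow the `<individual>_<species>_<sex>_<locus>` convention, plus a
`RegionMap` giving exon/intron intervals, per-exon codon phase (GFF-style:
bases to skip before the first complete codon) and residue-number anchors.
The default map lays out exon3 (169 nt), intron3 (1550), exon4 (166),
intron4 (1550), exon5 (240) and numbers exon 3's first codon as residue
148, which places residue 180 in exon 3 and residues 277/285 in exon 5.
Coordinates are 0-based half-open internally, 1-based inclusive in
reports.

Conventions shared by every statistic:

* **Complete deletion**: a column is used only if no analysed sequence has
  `-` or `N` there. `N` is treated like a gap — conservative, and it makes
  the retained-column set independent of which symbol encodes missing
  data. Columns are recomputed per comparison set (per species pair, per
  tree, etc.), not alignment-wide; the functions take explicit column
  lists, so either policy is available.
* **Heterozygotes**: IUPAC two-fold codes are split into two
  pseudo-haplotypes deterministically (alphabetically first base to copy
  `_a`). Per-site statistics (π, *d*, site classification) are invariant
  to this assignment; haplotype-requiring analyses (conversion detection,
  D′, MK on phased data) are restricted to single-copy males, where no
  phasing is needed.

## Diversity, divergence and site classes

π is the unweighted mean pairwise p-distance within a group; *d* the mean
over all between-group pairs, with no net (within-group) subtraction.
Both are uncorrected proportions; the Jukes–Cantor transform
−(3/4)ln(1−4p/3) is applied only when building trees. Synonymous and
non-synonymous components use the Nei–Gojobori pathway method: per-codon
synonymous site counts as the fraction of single-base changes that are
synonymous (changes to stops counted as non-synonymous, which keeps
syn + nonsyn = 3 exactly), and multi-position codon differences averaged
unweighted over all substitution orderings, excluding orderings that pass
through a stop (falling back to all orderings if every one is blocked).

Bootstrap SEs resample sites for nucleotide statistics and whole codons
for synonymous/non-synonymous statistics (keeping codon integrity); 1000
replicates by default. Two estimates are compared by a one-tailed Z test,
Z = (v₁−v₂)/√(se₁²+se₂²), with P from the upper normal tail; the
degenerate case of two identical zero-SE estimates reports P = 1 with a
log flag. Autosomal reference diversities are scaled by 3/4 before
comparison with the X-linked opsin region (θ = 4Nₑμ autosomal vs 3Nₑμ
X-linked).

Site classification for the contingency-table contrasts marks a retained
site *fixed* when both groups are internally monomorphic with different
bases, *polymorphic* when either group segregates, else *invariant* —
so a site that both differs between groups and segregates within one
counts as polymorphic, never fixed. A coding site is synonymous iff every
pair of observed bases at it encodes the same amino acid in the
consensus context of the other two codon positions; codons with more than
one variable position are flagged ambiguous but classified by the same
rule. Fisher's exact test is two-sided by the minimum-likelihood rule
(sum of all equal-margin tables no more probable than the observed one),
which is also scipy's convention.

## Trees

Among-group trees take one group per (species × gene type); single
outgroup sequences form singleton groups. Distances are JC-corrected
between-group divergences on jointly gap-free columns; the tree is classic
Saitou–Nei neighbor joining with a deterministic tie-break (lowest-index
pair) and negative branch lengths clamped to zero at output only (raw
values retained on the tree object). Supports are bipartition frequencies
across column-bootstrap replicates of the whole matrix-plus-NJ procedure;
a saturated replicate (p ≥ 0.75) contributes no support. The diagnostic
contrast is summarised by one bipartition: the split of all L groups from
all M groups, present in the exon tree (single ancient duplication) and
absent from the intron tree when conversion has clustered paralogs within
lineages.

## Conversion detection

The alignment is condensed to polymorphic, gap- and ambiguity-free
columns. For each sequence pair, candidate tracts ("inner fragments") are
maximal runs of consecutive polymorphic sites at which the pair agrees,
scored by run length; an optional BLAST-like mode (match +1, mismatch −g)
allows mismatches inside fragments but is off by default. Significance
uses a permutation null: shuffle the polymorphic-column order, record the
maximum fragment score over *all* pairs, and assign each observed fragment
P = (1 + #{perm max ≥ score})/(n_perm + 1). Taking the alignment-wide
maximum is the multiple-comparison correction; the +1 estimator avoids
zero P-values. Columns are exchangeable under the no-conversion null
(sites are i.i.d. given the genealogy), so the test is exactly calibrated;
it is conservative for pairs far less diverged than the pair driving the
null maximum. Fragment bounds run from the first to the last matching
polymorphic site — the data cannot localise a tract boundary between
polymorphic sites — and are annotated with exon/intron overlap fractions.
The inner permutation loop is numba-compiled; 10,000 permutations default.

## The simulator

The generator emulates the study system, not a generic coalescent. A
random ancestral sequence (exon codons stop-free) is duplicated at the
root; the L copy receives Ser180/Tyr277/Thr285 and the M copy
Ala/Phe/Ala, and the M copy additionally receives one non-synonymous
single-base change at each of the twelve non-tuning residues where the
two paralogs differ (153, 171, 174, 178 / 230, 233, 236 / 274, 275, 279,
298, 309) — the catarrhine paralogs differ at ~15 amino acids of which
three are spectral. These differences matter mechanistically: a
conversion tract overlapping an exon then almost always changes a masked
amino acid and is purged, which is what maintains exonic (including
synonymous) divergence while introns homogenize.

On each genome branch (the species tree plus a duplication stem), each
paralog receives Poisson(b·L) candidate Jukes–Cantor mutations, and the
genome Poisson(λ_c·L·b) candidate conversions with uniform start,
geometric tract length and random direction. Purifying selection is event
rejection: a candidate changing the amino acid of a masked codon is
discarded with probability `p_purge` (1 by default, mask = all exon
codons; `"tuning"` or explicit residue lists are available), and any
event creating a premature stop is always discarded. Within species,
haplotypes are drawn on a star genealogy — each of `n_samples` copies per
locus receives Poisson(θ/2·L) private mutations, so E[π] = θ exactly,
which is all the downstream statistics require; no within-species
coalescent, recombination, demography or GC-biased conversion is
modelled, and the L/M length difference from the real intron-3 Alu
element is ignored (equal-length paralogs).

Default study conditions (chosen once, from the regime the data show):
species tree `(((Hag,Hla,Hpi),Ssy),Nle)` with tip depth 0.005
substitutions/site and Nomascus basal; duplication stem 0.030 per paralog
(≈6–7% unconverted inter-paralog divergence); θ = 0.003 (intron and
reference diversity 0.1–0.4%); λ_c = 0.8 initiations/site per unit branch
length with mean tract 800 nt — heavy homogenization, leaving ~1% intron
divergence; `n_samples` = 2 males per species per locus. Every candidate
event (accepted or purged) is logged to a JSON ground-truth record.

## Numerical and design choices

* Phasing, NJ tie-breaks, per-stage seeds (SHA-256 of master seed + stage
  name, < 2³¹) make every pipeline rerun byte-identical.
* Fisher tables with a zero margin return P = 1 with a flag; JC saturation
  (p ≥ 0.75) raises, naming the offending group pair.
* HKA follows the two-locus 1987 formulation: method-of-moments θ per
  locus and shared T from S (polymorphism) and D (divergence) counts with
  aₙ = Σ 1/i sample-size correction, X² over the four cells with the
  standard variances, 1 df; an optional 3/4 weight on an X-linked locus's
  polymorphism θ.
* The additive λmax model spans seven distinct peaks (560, 553, 552, 545,
  538, 537, 530 nm): 560−15 and 560−7−8 coincide at 545.

## What the tests show — and don't

Simulation-based tests run at reduced sizes: permutation calibration on
200 conversion-free data sets (10 haplotypes each, 2000 permutations),
signature reproduction on 50 replicates (600 permutations), parameter
recovery on 100. Under the default conditions all four diagnostic
signatures (synonymous > intron divergence; exon tree keeps / intron tree
loses the duplication split; detected tracts ≥80% intronic; lower
divergence:polymorphism ratio in introns) appear in ≥95% of replicates.
Because the generator uses a star genealogy and equal-length paralogs,
these results validate the estimators and tests, not robustness to
genealogical noise, indels or sampling artefacts in real data; and the
conversion detector shares the known limitation of run-based statistics —
it cannot see conversions in regions with fewer differences than their
flanks, so detected-tract maps understate old, fully homogenized
exchange.
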