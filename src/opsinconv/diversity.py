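"""Nucleotide diversity, divergence, Nei-Gojobori counting and bootstrap errors.

Diversity (pi) is the mean pairwise proportion of differing sites within a
group; divergence (d) is the mean pairwise proportion between two groups.
Both are uncorrected p-distances computed on complete-deletion columns;
multiple-hit correction is applied only for tree building (see
:mod:`opsinconv.phylogeny`).  Synonymous/non-synonymous components use the
Nei-Gojobori pathway method with unweighted averaging over substitution
orderings, excluding pathways through stop codons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from opsinconv.genotype import translate_codon

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass(frozen=True)
class DistanceEstimate:
    """A pi or d estimate with its bootstrap SE and site accounting."""

    value: float
    se: float | None
    n_sites: float
    site_class: str  # all | synonymous | nonsynonymous | intron | exon
    kind: str  # "pi" | "d"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"distance {self.value} outside [0, 1]")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")


@dataclass
class CodonPairCount:
    """Accumulated Nei-Gojobori site and difference counts for a sequence pair."""

    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_diffs: float = 0.0
    nonsyn_diffs: float = 0.0

    def __iadd__(self, other: "CodonPairCount") -> "CodonPairCount":
        self.syn_sites += other.syn_sites
        self.nonsyn_sites += other.nonsyn_sites
        self.syn_diffs += other.syn_diffs
        self.nonsyn_diffs += other.nonsyn_diffs
        return self


def pairwise_p_distance(a: str, b: str, columns: Sequence[int]) -> float:
    """Proportion of retained columns at which the two sequences differ."""
    if len(columns) == 0:
        raise ValueError("pairwise_p_distance: no retained columns")
    diffs = sum(1 for j in columns if a[j] != b[j])
    return diffs / len(columns)


def nucleotide_diversity(
    seqs: Sequence[str], columns: Sequence[int], site_class: str = "all"
) -> DistanceEstimate:
    """Mean pairwise p-distance over all unordered pairs within a group."""
    if len(seqs) < 2:
        raise ValueError("nucleotide_diversity needs at least 2 sequences")
    dists = [
        pairwise_p_distance(a, b, columns) for a, b in itertools.combinations(seqs, 2)
    ]
    return DistanceEstimate(float(np.mean(dists)), None, len(columns), site_class, "pi")


def nucleotide_divergence(
    group_a: Sequence[str],
    group_b: Sequence[str],
    columns: Sequence[int],
    site_class: str = "all",
) -> DistanceEstimate:
    """Mean pairwise p-distance over all between-group pairs (no net correction)."""
    if not group_a or not group_b:
        raise ValueError("nucleotide_divergence: empty group")
    dists = [pairwise_p_distance(a, b, columns) for a in group_a for b in group_b]
    return DistanceEstimate(float(np.mean(dists)), None, len(columns), site_class, "d")


# ---------------------------------------------------------------------------
# Nei-Gojobori synonymous / non-synonymous counting


def _syn_fraction(codon: str) -> float:
    """Synonymous sites in a codon: per position, (synonymous changes)/3.

    Changes creating stop codons count as non-synonymous, which keeps
    syn + nonsyn sites exactly 3 per codon.
    """
    aa = translate_codon(codon)
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if translate_codon(mutant) != "Stop" and translate_codon(mutant) == aa:
                s += 1 / 3
    return s


def _pathway_steps(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (syn, nonsyn) difference counts over mutational pathways.

    All orderings of the differing positions are enumerated; pathways that
    pass through a stop codon are excluded.  If every pathway is blocked the
    unweighted average over all pathways is used.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    pathways: list[tuple[float, float]] = []
    open_pathways: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = translate_codon(cur), translate_codon(nxt)
            if aa_nxt == "Stop" or aa_cur == "Stop":
                blocked = True
            if aa_cur == aa_nxt:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        pathways.append((syn, nonsyn))
        if not blocked:
            open_pathways.append((syn, nonsyn))
    use = open_pathways if open_pathways else pathways
    syn_avg = sum(p[0] for p in use) / len(use)
    nonsyn_avg = sum(p[1] for p in use) / len(use)
    return syn_avg, nonsyn_avg


def nei_gojobori_pair(
    codons_a: Sequence[str], codons_b: Sequence[str]
) -> CodonPairCount:
    """Accumulate Nei-Gojobori counts over aligned, gap-free codon pairs."""
    if len(codons_a) != len(codons_b):
        raise ValueError("codon lists differ in length")
    total = CodonPairCount()
    for idx, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        if translate_codon(ca) == "Stop" or translate_codon(cb) == "Stop":
            raise ValueError(f"internal stop codon at codon index {idx}")
        sa, sb = _syn_fraction(ca), _syn_fraction(cb)
        syn, nonsyn = _pathway_steps(ca, cb)
        total += CodonPairCount(
            syn_sites=(sa + sb) / 2,
            nonsyn_sites=3 - (sa + sb) / 2,
            syn_diffs=syn,
            nonsyn_diffs=nonsyn,
        )
    return total


def _ng_mean(pairs: list[tuple[Sequence[str], Sequence[str]]]) -> tuple[float, float, float, float]:
    """Mean per-site syn and nonsyn distances over sequence pairs."""
    ps_list, pn_list, s_sites, n_sites = [], [], [], []
    for ca, cb in pairs:
        c = nei_gojobori_pair(ca, cb)
        ps_list.append(c.syn_diffs / c.syn_sites if c.syn_sites else 0.0)
        pn_list.append(c.nonsyn_diffs / c.nonsyn_sites if c.nonsyn_sites else 0.0)
        s_sites.append(c.syn_sites)
        n_sites.append(c.nonsyn_sites)
    return (
        float(np.mean(ps_list)),
        float(np.mean(pn_list)),
        float(np.mean(s_sites)),
        float(np.mean(n_sites)),
    )


def ng_diversity(codon_group: Sequence[Sequence[str]]) -> tuple[DistanceEstimate, DistanceEstimate]:
    """Within-group synonymous and non-synonymous diversity (Nei-Gojobori)."""
    if len(codon_group) < 2:
        raise ValueError("ng_diversity needs at least 2 sequences")
    pairs = list(itertools.combinations(codon_group, 2))
    ps, pn, s_sites, n_sites = _ng_mean(pairs)
    return (
        DistanceEstimate(ps, None, s_sites, "synonymous", "pi"),
        DistanceEstimate(pn, None, n_sites, "nonsynonymous", "pi"),
    )


def ng_divergence(
    codon_group_a: Sequence[Sequence[str]], codon_group_b: Sequence[Sequence[str]]
) -> tuple[DistanceEstimate, DistanceEstimate]:
    """Between-group synonymous and non-synonymous divergence (Nei-Gojobori)."""
    if not codon_group_a or not codon_group_b:
        raise ValueError("ng_divergence: empty group")
    pairs = [(a, b) for a in codon_group_a for b in codon_group_b]
    ps, pn, s_sites, n_sites = _ng_mean(pairs)
    return (
        DistanceEstimate(ps, None, s_sites, "synonymous", "d"),
        DistanceEstimate(pn, None, n_sites, "nonsynonymous", "d"),
    )


# ---------------------------------------------------------------------------
# Resampling and tests


def bootstrap_se(
    statistic: Callable[[np.ndarray], float],
    n_units: int,
    reps: int = 1000,
    seed: int | None = None,
) -> float:
    """Bootstrap SE of a statistic over resampling units (sites or codons).

    ``statistic`` receives an integer array of resampled unit indices (with
    replacement) and returns the recomputed value.  The 1000-replicate
    default matches common distance-software practice.
    """
    if reps < 2:
        raise ValueError("bootstrap_se needs at least 2 replicates")
    rng = np.random.default_rng(seed)
    values = np.empty(reps)
    for r in range(reps):
        idx = rng.integers(0, n_units, size=n_units)
        values[r] = statistic(idx)
    return float(np.std(values, ddof=1))


def z_test_one_tailed(e1: DistanceEstimate, e2: DistanceEstimate) -> float:
    """One-tailed Z test of H1: e1.value > e2.value; returns the P-value."""
    if e1.se is None or e2.se is None:
        raise ValueError("z_test_one_tailed requires bootstrap SEs on both estimates")
    denom = np.hypot(e1.se, e2.se)
    if denom == 0.0:
        if e1.value == e2.value:
            logger.warning("Z undefined (identical values, zero SEs); reporting P=1")
            return 1.0
        return 0.0 if e1.value > e2.value else 1.0
    z = (e1.value - e2.value) / denom
    return float(stats.norm.sf(z))


def scale_autosomal_to_x(pi: float) -> float:
    """Scale an autosomal diversity to the X-linked expectation (x 3/4)."""
    if pi < 0:
        raise ValueError("pi must be non-negative")
    return 0.75 * pi
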