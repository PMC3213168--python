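"""Divergence-vs-polymorphism contrasts: site classification, Fisher's exact
test, the McDonald-Kreitman test, the HKA test, and D' linkage disequilibrium.

The central bookkeeping classifies each retained alignment site as a fixed
inter-group difference (both groups internally monomorphic, different bases),
polymorphic (segregating within at least one group), or invariant, and as
synonymous, non-synonymous or intronic.  Cross-classifying fixed differences
and polymorphisms by site class gives the 2x2 tables behind the
"divergence-to-polymorphism ratio" contrasts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from opsinconv.alignment_io import Alignment, RegionMap
from opsinconv.genotype import translate_codon

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteClassification:
    """Per-site status and class for the retained columns of an alignment."""

    sites: tuple[int, ...]  # 0-based alignment positions
    status: tuple[str, ...]  # fixed | polymorphic | invariant
    site_class: tuple[str, ...]  # synonymous | nonsynonymous | intron | other
    ambiguous_codon: tuple[bool, ...]  # codon has >1 segregating position

    def count(self, status: str, site_class: str) -> int:
        return sum(
            1
            for st, cl in zip(self.status, self.site_class)
            if st == status and cl == site_class
        )

    def table(self, class1: str, class2: str) -> np.ndarray:
        """2x2 table: rows (fixed divergence, polymorphism) x (class1, class2)."""
        return np.array(
            [
                [self.count("fixed", class1), self.count("fixed", class2)],
                [self.count("polymorphic", class1), self.count("polymorphic", class2)],
            ]
        )


def _consensus(bases: Sequence[str]) -> str:
    counts = Counter(bases)
    top = max(counts.values())
    return sorted(b for b, c in counts.items() if c == top)[0]


def _is_synonymous_change(codon_template: str, pos: int, b1: str, b2: str) -> bool:
    c1 = codon_template[:pos] + b1 + codon_template[pos + 1 :]
    c2 = codon_template[:pos] + b2 + codon_template[pos + 1 :]
    return translate_codon(c1) == translate_codon(c2)


def classify_alignment_sites(
    aln: Alignment,
    group1_ids: Sequence[str],
    group2_ids: Sequence[str],
    region_map: RegionMap,
    columns: Sequence[int],
) -> SiteClassification:
    """Classify each retained site by fixation status and site class.

    A site is *fixed* when each group is internally monomorphic and the two
    groups carry different bases; any within-group segregation makes it
    *polymorphic*.  A coding site is synonymous when every observed change
    at it is synonymous in the consensus codon context of the two groups;
    codons with more than one segregating/divergent position are flagged
    ambiguous but classified by the same rule.
    """
    if not group1_ids or not group2_ids:
        raise ValueError("classify_alignment_sites: empty group")
    g1 = [aln.get(i).bases for i in group1_ids]
    g2 = [aln.get(i).bases for i in group2_ids]
    everyone = g1 + g2
    colset = set(columns)

    statuses, classes, ambig = [], [], []
    for j in columns:
        b1 = {s[j] for s in g1}
        b2 = {s[j] for s in g2}
        if len(b1) == 1 and len(b2) == 1:
            status = "fixed" if b1 != b2 else "invariant"
        else:
            status = "polymorphic"
        reg = region_map.region_of_site(j)
        is_amb = False
        if reg is None:
            cls = "other"
        elif reg.kind == "intron":
            cls = "intron"
        else:
            frame = region_map.coding_frame(j)
            if frame is None:
                cls = "other"  # partial codon at an exon edge
            else:
                start, pos = frame
                codon_sites = [start, start + 1, start + 2]
                if any(s not in colset for s in codon_sites):
                    cls = "other"  # codon broken by deleted columns
                else:
                    template = "".join(
                        _consensus([s[k] for s in everyone]) for k in codon_sites
                    )
                    observed = sorted(b1 | b2)
                    syn = all(
                        _is_synonymous_change(template, pos, x, y)
                        for i, x in enumerate(observed)
                        for y in observed[i + 1 :]
                    )
                    cls = "synonymous" if syn else "nonsynonymous"
                    n_var = sum(
                        1 for k in codon_sites if len({s[k] for s in everyone}) > 1
                    )
                    is_amb = n_var > 1
        statuses.append(status)
        classes.append(cls)
        ambig.append(is_amb)
    return SiteClassification(tuple(columns), tuple(statuses), tuple(classes), tuple(ambig))


def fisher_exact_two_sided(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact P (minimum-likelihood rule) for a 2x2 table.

    Sums the point probabilities, at fixed margins, of all tables no more
    probable than the observed one.  A zero margin admits only one table and
    yields P=1 (flagged in the log).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        logger.warning("Fisher table has a zero margin; no association testable, P=1")
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


def mcdonald_kreitman(
    aln: Alignment,
    species_a_ids: Sequence[str],
    species_b_ids: Sequence[str],
    region_map: RegionMap,
    columns: Sequence[int],
) -> tuple[np.ndarray, float]:
    """McDonald-Kreitman contrast between two species for one locus.

    Returns the 2x2 table (fixed/polymorphic x nonsynonymous/synonymous)
    over coding sites and its two-sided Fisher P.  Groups should be
    orthologous haplotypes (single-copy male sequences).
    """
    cls = classify_alignment_sites(aln, species_a_ids, species_b_ids, region_map, columns)
    table = cls.table("nonsynonymous", "synonymous")
    return table, fisher_exact_two_sided(table)


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def hka_test(
    locus1: tuple[int, int, int, float],
    locus2: tuple[int, int, int, float],
    x_linked_locus: int | None = None,
) -> tuple[float, float]:
    """Two-locus HKA test; each locus is (S_poly, D_div, n_samples, L_sites).

    Method-of-moments fits per-locus theta and a shared divergence time T
    (coalescent units, equal population sizes) to the four observed counts:

        E[S_i] = theta_i * a_{n_i},          Var[S_i] = E[S_i] + theta_i^2 * b_{n_i}
        E[D_i] = theta_i * (T + 1),          Var[D_i] = E[D_i] + theta_i^2

    with a_n = sum 1/i, b_n = sum 1/i^2 (i < n).  X^2 sums (obs-exp)^2/Var
    over the four cells and is referred to chi-square with 1 df.  Pass
    ``x_linked_locus`` (1 or 2) to weight that locus's theta by 3/4 when
    contrasting X-linked with autosomal data.
    """
    S = [locus1[0], locus2[0]]
    D = [locus1[1], locus2[1]]
    n = [locus1[2], locus2[2]]
    L = [locus1[3], locus2[3]]
    if min(n) < 2 or min(L) <= 0:
        raise ValueError("each locus needs n >= 2 and positive length")
    if sum(S) + sum(D) == 0:
        raise ValueError("degenerate input: no polymorphism or divergence at either locus")
    a = [_harmonic(k) for k in n]
    b = [_harmonic(k, 2) for k in n]
    # per-locus theta weight: 3/4 for an X-linked locus vs autosomal references
    w = [1.0, 1.0]
    if x_linked_locus is not None:
        w[x_linked_locus - 1] = 0.75

    tot = [S[i] + D[i] for i in range(2)]

    def d_balance(u: float) -> float:
        # u = T + 1; S_i + D_i = theta_i (w_i a_i + u), D_i = theta_i u
        return sum(u * tot[i] / (w[i] * a[i] + u) for i in range(2)) - sum(D)

    from scipy.optimize import brentq

    lo, hi = 1e-9, 1e9
    if d_balance(lo) > 0 or d_balance(hi) < 0:
        raise ValueError("HKA moment equations have no solution for these counts")
    u = brentq(d_balance, lo, hi)
    theta = [tot[i] / (w[i] * a[i] + u) for i in range(2)]
    x2 = 0.0
    for i in range(2):
        th = w[i] * theta[i]  # effective polymorphism theta (3/4 on X)
        eS = th * a[i]
        vS = eS + th**2 * b[i]
        eD = theta[i] * u
        vD = eD + theta[i] ** 2
        x2 += (S[i] - eS) ** 2 / vS + (D[i] - eD) ** 2 / vD
    p = float(stats.chi2.sf(x2, df=1))
    return float(x2), p


def d_prime(haplotypes: Sequence[str], site_i: int, site_j: int) -> float:
    """Normalised linkage disequilibrium D' between two biallelic sites."""
    pairs = [(h[site_i], h[site_j]) for h in haplotypes]
    alleles_i = sorted({p[0] for p in pairs})
    alleles_j = sorted({p[1] for p in pairs})
    if len(alleles_i) != 2 or len(alleles_j) != 2:
        raise ValueError("both sites must be biallelic among the haplotypes")
    n = len(pairs)
    A, B = alleles_i[0], alleles_j[0]
    pA = sum(1 for p in pairs if p[0] == A) / n
    pB = sum(1 for p in pairs if p[1] == B) / n
    pAB = sum(1 for p in pairs if p == (A, B)) / n
    d = pAB - pA * pB
    if d >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax == 0:
        return 0.0
    return abs(d) / dmax
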