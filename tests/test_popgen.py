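"""Site classification, Fisher's exact test, MK, HKA and D'."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from conftest import make_alignment
from opsinconv.popgen import (
    classify_alignment_sites,
    d_prime,
    fisher_exact_two_sided,
    hka_test,
    mcdonald_kreitman,
)

# ---------------------------------------------------------------------------
# brute-force Fisher oracle


def oracle_fisher_two_sided(table) -> float:
    """Enumerate all 2x2 tables with the observed margins; sum point
    probabilities no greater than the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_prob(x):
        # hypergeometric point mass for cell (0,0)=x
        return (
            gammaln(r1 + 1)
            - gammaln(x + 1)
            - gammaln(r1 - x + 1)
            + gammaln(r2 + 1)
            - gammaln(c1 - x + 1)
            - gammaln(r2 - c1 + x + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
        )

    xs = range(max(0, c1 - r2), min(r1, c1) + 1)
    probs = {x: math.exp(log_prob(x)) for x in xs}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            # two-sided minimum-likelihood values as printed for the gibbon
            # synonymous-vs-intron contrasts
            ([[8, 13], [1, 41]], 3.7e-4),
            ([[9, 27], [0, 21]], 1.9e-2),
            ([[9, 4], [1, 26]], 2.3e-5),
        ],
    )
    def test_reference_contingency_tables(self, table, expected):
        assert fisher_exact_two_sided(table) == pytest.approx(expected, rel=0.05)

    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided([[1, 1], [1, 1]]) == 1.0

    def test_zero_margin_flagged_as_one(self):
        assert fisher_exact_two_sided([[0, 0], [3, 7]]) == 1.0

    def test_matches_brute_force_enumeration(self):
        """Oracle equivalence over random tables with margins up to 60."""
        rng = np.random.default_rng(17)
        tables = [[[8, 13], [1, 41]], [[9, 7], [1, 71]], [[2, 2], [2, 2]]]
        for _ in range(200):
            tables.append(rng.integers(0, 31, size=(2, 2)).tolist())
        for t in tables:
            t = np.asarray(t)
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert fisher_exact_two_sided(t) == pytest.approx(
                oracle_fisher_two_sided(t), rel=1e-6
            ), t.tolist()


class TestSiteClassification:
    def _alignment(self, tiny_region_map):
        # exon [0,6): codons 0-2 and 3-5; intron [6,12)
        rows = {
            "1_Hag_M_L": "TTTAAAGGGGGG",
            "2_Hag_M_L": "TTTAAAGGGGGG",
            "1_Hag_M_M": "TTCAAAGGGAGG",
            "2_Hag_M_M": "TTCAAAGGGAGG",
        }
        return make_alignment(rows)

    def test_fixed_synonymous_and_fixed_intron_sites(self, tiny_region_map):
        aln = self._alignment(tiny_region_map)
        cls = classify_alignment_sites(
            aln, ["1_Hag_M_L", "2_Hag_M_L"], ["1_Hag_M_M", "2_Hag_M_M"],
            tiny_region_map, list(range(12)),
        )
        # site 2: TTT vs TTC, both Phe -> fixed synonymous
        assert cls.status[2] == "fixed" and cls.site_class[2] == "synonymous"
        # site 9: intron fixed difference
        assert cls.status[9] == "fixed" and cls.site_class[9] == "intron"

    def test_segregation_beats_fixation(self, tiny_region_map):
        rows = {
            "1_x_M_L": "TTTAAAGGGGGG",
            "2_x_M_L": "TTTAAAGGGGGG",
            "1_x_M_M": "TTTAAAGGGAGG",
            "2_x_M_M": "TTTAAAGGGGGG",  # intron site 9 segregates within M
        }
        aln = make_alignment(rows)
        cls = classify_alignment_sites(
            aln, ["1_x_M_L", "2_x_M_L"], ["1_x_M_M", "2_x_M_M"],
            tiny_region_map, list(range(12)),
        )
        assert cls.status[9] == "polymorphic"

    def test_nonsynonymous_classification(self, tiny_region_map):
        rows = {
            "1_x_M_L": "TTTAAAGGGGGG",
            "1_x_M_M": "GTTAAAGGGGGG",  # Phe -> Val at codon 1 position 1
        }
        aln = make_alignment(rows)
        cls = classify_alignment_sites(
            aln, ["1_x_M_L"], ["1_x_M_M"], tiny_region_map, list(range(12))
        )
        assert cls.status[0] == "fixed" and cls.site_class[0] == "nonsynonymous"

    def test_statuses_partition_all_retained_sites(self, simulated_default):
        cfg, aln, _ = simulated_default
        from opsinconv.alignment_io import complete_deletion_columns

        l_ids = [r.raw_id for r in aln if r.locus_tag == "L" and r.species_code == "Hag"]
        m_ids = [r.raw_id for r in aln if r.locus_tag == "M" and r.species_code == "Hag"]
        cols = complete_deletion_columns(aln, l_ids + m_ids)
        cls = classify_alignment_sites(aln, l_ids, m_ids, cfg.region_map(), cols)
        assert len(cls.status) == len(cols)
        counts = {s: cls.status.count(s) for s in ("fixed", "polymorphic", "invariant")}
        assert sum(counts.values()) == len(cols)


class TestMK:
    def test_balanced_table_not_significant(self, tiny_region_map):
        rows = {
            "1_A_M_L": "TTTAAAGGGGGG",
            "1_B_M_L": "TTTAAAGGGGGG",
        }
        aln = make_alignment(rows)
        table, p = mcdonald_kreitman(
            aln, ["1_A_M_L"], ["1_B_M_L"], tiny_region_map, list(range(12))
        )
        assert table.sum() == 0 and p == 1.0


class TestHKA:
    def test_proportional_counts_fit_perfectly(self):
        x2, p = hka_test((10, 30, 5, 1000.0), (20, 60, 5, 2000.0))
        assert x2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            hka_test((0, 0, 5, 100.0), (0, 0, 5, 100.0))

    @staticmethod
    def _coalescent_counts(rng, theta, T, n, L):
        """Independent null generator: S from coalescent tree length,
        D from a Poisson with the ancestral-coalescent contribution."""
        t_total = 0.0
        for k in range(n, 1, -1):
            t_total += k * rng.exponential(2.0 / (k * (k - 1)))
        S = rng.poisson(theta * L * t_total / 2)
        D = rng.poisson(theta * L * (T + rng.exponential(1.0)))
        return S, D

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(100)
        theta, T, n = 0.01, 5.0, 8
        rejections = 0
        reps = 400
        for _ in range(reps):
            s1, d1 = self._coalescent_counts(rng, theta, T, n, 800)
            s2, d2 = self._coalescent_counts(rng, theta, T, n, 1200)
            if s1 + d1 == 0 or s2 + d2 == 0:
                continue
            _, p = hka_test((s1, d1, n, 800.0), (s2, d2, n, 1200.0))
            rejections += p < 0.05
        rate = rejections / reps
        assert rate < 0.09, rate

    def test_power_against_excess_divergence(self):
        rng = np.random.default_rng(101)
        theta, T, n = 0.01, 5.0, 8
        sig = 0
        reps = 100
        for _ in range(reps):
            s1, d1 = self._coalescent_counts(rng, theta, T, n, 800)
            s2, d2 = self._coalescent_counts(rng, theta, T, n, 1200)
            d2 *= 10  # locus 2 diverges far in excess of its polymorphism
            _, p = hka_test((s1, d1, n, 800.0), (s2, d2, n, 1200.0))
            sig += p < 0.05
        assert sig / reps > 0.5


class TestDPrime:
    def test_perfect_association(self):
        haps = ["AG", "AG", "CT", "CT"]
        assert d_prime(haps, 0, 1) == pytest.approx(1.0)

    def test_independent_alleles(self):
        haps = ["AG", "AT", "CG", "CT"]
        assert d_prime(haps, 0, 1) == pytest.approx(0.0)

    def test_matches_direct_enumeration(self):
        # haplotypes AB x4, aB x1, ab x5
        haps = ["AG"] * 4 + ["CG"] * 1 + ["CT"] * 5
        pA, pB = 4 / 10, 5 / 10
        pAB = 4 / 10
        D = pAB - pA * pB
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
        assert d_prime(haps, 0, 1) == pytest.approx(abs(D) / dmax)

    def test_monomorphic_site_rejected(self):
        with pytest.raises(ValueError):
            d_prime(["AG", "AG", "AT"], 0, 1)
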