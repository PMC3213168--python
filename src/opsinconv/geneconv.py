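"""Sawyer-style detection of gene-conversion tracts between sequence pairs.

The alignment is condensed to its polymorphic, gap-free columns.  For each
sequence pair, candidate converted tracts ("inner fragments") are maximal
runs of consecutive polymorphic sites at which the pair agrees, scored by
run length.  Significance comes from a permutation null: polymorphic-site
column order is shuffled, the maximum fragment score over *all* pairs is
recorded per permutation, and a fragment's global P-value is the tail
probability of that maximum — a built-in correction for the many pairs and
fragments examined.  An optional BLAST-like mode allows mismatches inside
fragments at a penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from opsinconv.alignment_io import Alignment, RegionMap

_CLEAN = frozenset("ACGT")


@dataclass(frozen=True)
class PolymorphicProfile:
    """Condensed alignment: retained polymorphic columns with back-mapping."""

    ids: tuple[str, ...]
    site_indices: tuple[int, ...]  # 0-based original-alignment positions
    matrix: np.ndarray  # uint8 codes, shape (n_records, n_poly_sites)

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)

    def row(self, raw_id: str) -> np.ndarray:
        try:
            return self.matrix[self.ids.index(raw_id)]
        except ValueError:
            raise KeyError(raw_id) from None


@dataclass(frozen=True)
class ConversionFragment:
    """A candidate converted tract between two sequences.

    Coordinates are 1-based inclusive original-alignment positions, spanning
    from the first to the last matching polymorphic site (the data cannot
    localise tract boundaries between polymorphic sites).
    """

    seq1: str
    seq2: str
    start: int
    end: int
    n_poly_sites: int
    score: float
    global_sim_p: float | None = None
    regions_hit: tuple[tuple[str, float], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("fragment start > end")
        if self.n_poly_sites < 1:
            raise ValueError("fragment must contain a polymorphic site")


def build_profile(aln: Alignment, ids: Sequence[str] | None = None) -> PolymorphicProfile:
    """Condense to polymorphic columns free of gaps and ambiguity codes."""
    use = list(ids) if ids is not None else aln.ids()
    if len(use) < 2:
        raise ValueError("build_profile needs at least 2 records")
    seqs = [aln.get(i).bases for i in use]
    code = {b: k for k, b in enumerate("ACGT")}
    keep, cols = [], []
    for j in range(aln.length):
        column = [s[j] for s in seqs]
        if any(b not in _CLEAN for b in column):
            continue
        if len(set(column)) < 2:
            continue
        keep.append(j)
        cols.append([code[b] for b in column])
    matrix = (
        np.array(cols, dtype=np.uint8).T if cols else np.zeros((len(use), 0), dtype=np.uint8)
    )
    return PolymorphicProfile(tuple(use), tuple(keep), matrix)


def _segment_spans(agree: np.ndarray, penalty: float) -> list[tuple[int, int, float]]:
    """(first, last, score) spans of fragments in profile coordinates.

    With ``penalty`` disabled (0), fragments are maximal runs of agreement
    scored by length.  With a positive penalty, maximal-scoring segments
    (match +1, mismatch -penalty) are found by a Kadane-style scan, trimmed
    to start and end on matches.
    """
    n = len(agree)
    out: list[tuple[int, int, float]] = []
    if penalty <= 0:
        j = 0
        while j < n:
            if agree[j]:
                start = j
                while j < n and agree[j]:
                    j += 1
                out.append((start, j - 1, float(j - start)))
            else:
                j += 1
        return out
    score, start = 0.0, 0
    best, best_span = 0.0, None
    j = 0
    while j < n:
        val = 1.0 if agree[j] else -penalty
        if score + val <= 0:
            if best_span is not None and best > 0:
                out.append((best_span[0], best_span[1], best))
            score, start, best, best_span = 0.0, j + 1, 0.0, None
        else:
            if score == 0.0:
                start = j
            score += val
            if score > best and agree[j]:
                best, best_span = score, (start, j)
        j += 1
    if best_span is not None and best > 0:
        out.append((best_span[0], best_span[1], best))
    return out


def pairwise_fragments(
    profile: PolymorphicProfile, id1: str, id2: str, mismatch_penalty: float = 0.0
) -> list[ConversionFragment]:
    """Candidate fragments for one pair, before significance testing."""
    a, b = profile.row(id1), profile.row(id2)
    agree = a == b
    frags = []
    for first, last, score in _segment_spans(agree, mismatch_penalty):
        frags.append(
            ConversionFragment(
                seq1=id1,
                seq2=id2,
                start=profile.site_indices[first] + 1,
                end=profile.site_indices[last] + 1,
                n_poly_sites=int(np.count_nonzero(agree[first : last + 1])),
                score=score,
            )
        )
    return frags


def _agreement_matrix(profile: PolymorphicProfile) -> np.ndarray:
    """Boolean (n_pairs, n_sites) agreement matrix over all unordered pairs."""
    m = profile.matrix
    n = m.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    return m[iu] == m[ju]


def _max_scores(agree: np.ndarray, penalty: float) -> float:
    """Maximum fragment score over all rows of an agreement matrix."""
    n_rows, n_sites = agree.shape
    if n_sites == 0:
        return 0.0
    if penalty <= 0:
        run = np.zeros(n_rows)
        best = 0.0
        for j in range(n_sites):
            run = (run + 1.0) * agree[:, j]
            m = run.max()
            if m > best:
                best = m
        return float(best)
    score = np.zeros(n_rows)
    best = 0.0
    for j in range(n_sites):
        val = np.where(agree[:, j], 1.0, -penalty)
        score = np.maximum(score + val, 0.0)
        m = score.max()
        if m > best:
            best = m
    return float(best)


@njit(cache=False)
def _null_max_runs(agree: np.ndarray, perms: np.ndarray) -> np.ndarray:  # pragma: no cover
    n_perm, n_sites = perms.shape
    n_rows = agree.shape[0]
    out = np.zeros(n_perm)
    for k in range(n_perm):
        best = 0
        for r in range(n_rows):
            run = 0
            for j in range(n_sites):
                if agree[r, perms[k, j]]:
                    run += 1
                    if run > best:
                        best = run
                else:
                    run = 0
        out[k] = best
    return out


@njit(cache=False)
def _null_max_segments(
    agree: np.ndarray, perms: np.ndarray, penalty: float
) -> np.ndarray:  # pragma: no cover
    n_perm, n_sites = perms.shape
    n_rows = agree.shape[0]
    out = np.zeros(n_perm)
    for k in range(n_perm):
        best = 0.0
        for r in range(n_rows):
            score = 0.0
            for j in range(n_sites):
                if agree[r, perms[k, j]]:
                    score += 1.0
                    if score > best:
                        best = score
                else:
                    score = max(score - penalty, 0.0)
        out[k] = best
    return out


def permutation_null_max(
    profile: PolymorphicProfile,
    n_perm: int = 10000,
    seed: int | None = None,
    mismatch_penalty: float = 0.0,
) -> np.ndarray:
    """Null distribution of the alignment-wide maximum fragment score.

    Each permutation shuffles the order of the polymorphic columns (the null
    of differences scattered at random along the sequence) and records the
    maximum score over all sequence pairs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    agree = _agreement_matrix(profile)
    rng = np.random.default_rng(seed)
    n_sites = profile.n_sites
    if n_sites == 0:
        return np.zeros(n_perm)
    perms = rng.permuted(
        np.tile(np.arange(n_sites, dtype=np.int64), (n_perm, 1)), axis=1
    )
    if mismatch_penalty <= 0:
        return _null_max_runs(agree, perms)
    return _null_max_segments(agree, perms, mismatch_penalty)


def global_permutation_test(
    profile: PolymorphicProfile,
    n_perm: int = 10000,
    seed: int | None = None,
    mismatch_penalty: float = 0.0,
) -> list[ConversionFragment]:
    """All pairwise fragments with global permutation P-values attached.

    A fragment's global P is ``(1 + #{permutation max >= score}) /
    (n_perm + 1)``; the max statistic makes it simultaneously valid over all
    pairs and fragments.
    """
    fragments = []
    ids = profile.ids
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            fragments.extend(pairwise_fragments(profile, ids[i], ids[j], mismatch_penalty))
    if not fragments:
        return []
    null_max = permutation_null_max(profile, n_perm, seed, mismatch_penalty)
    null_sorted = np.sort(null_max)
    out = []
    for frag in fragments:
        exceed = len(null_sorted) - np.searchsorted(null_sorted, frag.score, side="left")
        p = (1 + int(exceed)) / (n_perm + 1)
        out.append(replace(frag, global_sim_p=p))
    return out


def annotate_regions(
    frag: ConversionFragment, region_map: RegionMap
) -> ConversionFragment:
    """Attach (region name, overlap fraction of tract length) annotations."""
    start0, end0 = frag.start - 1, frag.end - 1  # back to 0-based inclusive
    length = end0 - start0 + 1
    hits = []
    for reg in region_map.regions:
        ov = min(end0 + 1, reg.end) - max(start0, reg.start)
        if ov > 0:
            hits.append((reg.name, ov / length))
    return replace(frag, regions_hit=tuple(hits))


def detect_conversions(
    aln: Alignment,
    region_map: RegionMap,
    ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | None = None,
    mismatch_penalty: float = 0.0,
) -> list[ConversionFragment]:
    """Significant conversion tracts with exon/intron composition.

    For faithful emulation of the haplotype-requiring original analysis,
    restrict ``ids`` to single-copy male sequences.
    """
    profile = build_profile(aln, ids)
    if profile.n_sites == 0:
        return []
    tested = global_permutation_test(profile, n_perm, seed, mismatch_penalty)
    return [
        annotate_regions(f, region_map) for f in tested if f.global_sim_p < alpha
    ]


def intronic_fraction(frags: Sequence[ConversionFragment], region_map: RegionMap) -> float:
    """Fraction of total significant tract length lying in intron regions."""
    total = intron = 0.0
    intron_names = set(region_map.names("intron"))
    for f in frags:
        length = f.end - f.start + 1
        total += length
        intron += length * sum(frac for name, frac in f.regions_hit if name in intron_names)
    if total == 0:
        raise ValueError("no fragments given")
    return intron / total
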