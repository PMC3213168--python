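"""Forward simulator of a tandemly duplicated gene pair under mutation,
paralog gene conversion, and purifying selection at constrained codons.

The model: a random ancestral sequence is duplicated at the root into an L
and an M copy with forced divergent states at the three spectral-tuning
codons (L: Ser180/Tyr277/Thr285; M: Ala/Phe/Ala) and at the remaining
fixed amino-acid differences between the paralogs.  The duplicated pair then
descends one genome lineage per species-tree branch.  On a branch of length
``b`` (expected substitutions/site), each paralog receives Poisson(b*L)
candidate point mutations (Jukes-Cantor: uniform target base), and the
genome receives Poisson(conv_rate*L*b) candidate conversion events with a
uniform start, geometric tract length and random direction.  Purifying
selection is modelled as rejection: any candidate event that would change
the amino acid of a masked codon is discarded with probability ``p_purge``
(events creating stop codons are always discarded).  At each tip,
``n_samples`` haplotypes per locus are drawn on a star genealogy: each
receives Poisson(theta/2 * L) private mutations, so expected within-species
pairwise diversity equals ``theta``.

Defaults emulate the gibbon L/M opsin study region: exons 3-5 with introns
3-4 (~3.7 kb), neutral diversity 0.3%, ~6% synonymous inter-paralog
divergence from a deep duplication, heavy inter-paralog conversion, and
complete purging of conversions that would alter a tuning residue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import dendropy
import numpy as np

from opsinconv.alignment_io import Alignment, RegionMap, SequenceRecord, default_opsin_region_map
from opsinconv.genotype import translate_codon

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

DEFAULT_SPECIES_TREE = (
    "(((Hag:0.002,Hla:0.002,Hpi:0.002):0.002,Ssy:0.004):0.001,Nle:0.005);"
)

# forced tuning-codon states after the duplication
L_TUNING = {180: "TCT", 277: "TAC", 285: "ACT"}  # Ser, Tyr, Thr
M_TUNING = {180: "GCT", 277: "TTC", 285: "GCT"}  # Ala, Phe, Ala

# Non-tuning amino-acid differences between the L and M paralogs within the
# exon 3 - exon 5 region, at their conventional opsin residue numbers.  The
# two catarrhine paralogs differ at ~15 amino acids of which three are the
# spectral-tuning sites; the remainder make conversion tracts that overlap
# an exon deleterious under the masked-codon purging rule, which is what
# maintains the paralogs' exonic (including synonymous) divergence.
DEFAULT_FIXED_AA_DIFFERENCES = (
    153, 171, 174, 178,        # exon 3
    230, 233, 236,             # exon 4
    274, 275, 279, 298, 309,   # exon 5
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated data set.

    ``conv_rate`` is conversion initiations per site per unit branch length;
    ``tract_mean`` the mean of the geometric tract-length distribution;
    ``dup_stem_length`` the branch (subs/site) each paralog evolves between
    the duplication and the species-tree root, which sets the inter-paralog
    divergence (~2x its value); ``selection_mask`` is ``"tuning"`` (the
    three spectral-tuning codons), ``"exons"`` (every complete exon codon),
    or an iterable of anchored residue numbers.
    """

    species_tree: str = DEFAULT_SPECIES_TREE
    exon3: int = 169
    intron3: int = 1550
    exon4: int = 166
    intron4: int = 1550
    exon5: int = 240
    theta: float = 0.003
    dup_stem_length: float = 0.030
    conv_rate: float = 0.8
    tract_mean: float = 800.0
    selection_mask: str | tuple[int, ...] = "exons"
    p_purge: float = 1.0
    fixed_aa_differences: tuple[int, ...] = DEFAULT_FIXED_AA_DIFFERENCES
    n_samples: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("theta", "dup_stem_length", "conv_rate", "tract_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.p_purge <= 1.0:
            raise ValueError("p_purge must be in [0, 1]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def region_map(self) -> RegionMap:
        return default_opsin_region_map(
            self.exon3, self.intron3, self.exon4, self.intron4, self.exon5
        )


def paper_scenario_config(seed: int | None = None, **overrides) -> SimulationConfig:
    """The emulation scenario: heavy intron conversion with full exon purging."""
    return SimulationConfig(seed=seed, **overrides)


@dataclass
class SimulationTruth:
    """Ground truth: the generating tree and every candidate event."""

    species_tree: str
    region_layout: dict
    seed: int | None
    events: list[dict] = field(default_factory=list)

    def accepted_conversions(self) -> list[dict]:
        return [e for e in self.events if e["type"] == "conversion" and e["accepted"]]


def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(truth), fh, indent=1)


def read_truth(path) -> SimulationTruth:
    with open(path) as fh:
        data = json.load(fh)
    return SimulationTruth(**data)


class _Evolver:
    """Mutation/conversion machinery over uint8-coded sequences."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.region_map = cfg.region_map()
        self.length = self.region_map.regions[-1].end
        self.codon_starts = np.array(self.region_map.codon_starts(), dtype=int)
        self.masked_starts = self._resolve_mask()
        self.truth_events: list[dict] = []

    def _resolve_mask(self) -> set[int]:
        mask = self.cfg.selection_mask
        if mask == "exons":
            return set(self.region_map.codon_starts())
        if mask == "tuning":
            return {self.region_map.anchor_codon_start(r) for r in (180, 277, 285)}
        return {self.region_map.anchor_codon_start(int(r)) for r in mask}

    # -- sequence helpers -------------------------------------------------
    def random_ancestor(self) -> np.ndarray:
        seq = self.rng.integers(0, 4, size=self.length).astype(np.uint8)
        # keep every complete exon codon stop-free
        for s in self.codon_starts:
            while translate_codon(self._codon(seq, s)) == "Stop":
                seq[s : s + 3] = self.rng.integers(0, 4, size=3)
        return seq

    @staticmethod
    def _codon(seq: np.ndarray, start: int) -> str:
        return "".join(_BASES[b] for b in seq[start : start + 3])

    def _codons_ok(self, seq: np.ndarray, starts: Sequence[int]) -> bool:
        return all(translate_codon(self._codon(seq, s)) != "Stop" for s in starts)

    def _aa_changed_at_masked(
        self, old: np.ndarray, new: np.ndarray, lo: int, hi: int
    ) -> bool:
        for s in self.masked_starts:
            if s + 3 <= lo or s >= hi:
                continue
            if translate_codon(self._codon(old, s)) != translate_codon(self._codon(new, s)):
                return True
        return False

    def _overlapping_codons(self, lo: int, hi: int) -> list[int]:
        return [int(s) for s in self.codon_starts if s + 3 > lo and s < hi]

    # -- evolutionary operators -------------------------------------------
    def mutate(self, seq: np.ndarray, branch_len: float, branch: str, log: bool = True) -> None:
        """Apply Poisson(branch_len * L) candidate point mutations in place."""
        n = self.rng.poisson(branch_len * self.length)
        for _ in range(n):
            site = int(self.rng.integers(0, self.length))
            old_base = seq[site]
            new_base = (old_base + 1 + self.rng.integers(0, 3)) % 4
            proposal = seq.copy()
            proposal[site] = new_base
            accepted = True
            if not self._codons_ok(proposal, self._overlapping_codons(site, site + 1)):
                accepted = False  # premature stop: always lethal
            elif self._aa_changed_at_masked(seq, proposal, site, site + 1):
                accepted = self.rng.random() >= self.cfg.p_purge
            if accepted:
                seq[site] = new_base
            if log:
                self.truth_events.append(
                    {
                        "branch": branch,
                        "type": "mutation",
                        "start": site,
                        "end": site + 1,
                        "donor": None,
                        "accepted": accepted,
                    }
                )

    def convert(self, genome: dict[str, np.ndarray], branch_len: float, branch: str) -> None:
        """Apply Poisson(conv_rate * L * branch_len) candidate conversions."""
        n = self.rng.poisson(self.cfg.conv_rate * self.length * branch_len)
        for _ in range(n):
            donor, recipient = ("L", "M") if self.rng.random() < 0.5 else ("M", "L")
            start = int(self.rng.integers(0, self.length))
            tract = int(self.rng.geometric(1.0 / self.cfg.tract_mean))
            end = min(self.length, start + tract)
            proposal = genome[recipient].copy()
            proposal[start:end] = genome[donor][start:end]
            accepted = True
            if not self._codons_ok(proposal, self._overlapping_codons(start, end)):
                accepted = False  # chimeric stop codon
            elif self._aa_changed_at_masked(genome[recipient], proposal, start, end):
                accepted = self.rng.random() >= self.cfg.p_purge
            if accepted:
                genome[recipient] = proposal
            self.truth_events.append(
                {
                    "branch": branch,
                    "type": "conversion",
                    "start": start,
                    "end": end,
                    "donor": f"{donor}->{recipient}",
                    "accepted": accepted,
                }
            )


def simulate_dataset(cfg: SimulationConfig) -> tuple[Alignment, SimulationTruth]:
    """Simulate one alignment of L/M haplotypes plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    ev = _Evolver(cfg, rng)
    region_map = ev.region_map

    tree = dendropy.Tree.get(data=cfg.species_tree, schema="newick")
    if tree.seed_node is None or len(tree.leaf_nodes()) < 2:
        raise ValueError("invalid species tree")
    if all(leaf.edge.length is None for leaf in tree.leaf_nodes()):
        raise ValueError("species tree lacks branch lengths")

    ancestor = ev.random_ancestor()
    genome = {"L": ancestor.copy(), "M": ancestor.copy()}
    for residue, codon in L_TUNING.items():
        s = region_map.anchor_codon_start(residue)
        genome["L"][s : s + 3] = [_CODE[b] for b in codon]
    for residue, codon in M_TUNING.items():
        s = region_map.anchor_codon_start(residue)
        genome["M"][s : s + 3] = [_CODE[b] for b in codon]
    # remaining fixed amino-acid differences: one non-synonymous, non-stop
    # single-base change in the M copy at each listed residue
    for residue in cfg.fixed_aa_differences:
        s = region_map.anchor_codon_start(int(residue))
        codon = "".join(_BASES[b] for b in genome["M"][s : s + 3])
        aa = translate_codon(codon)
        options = []
        for pos in range(3):
            for alt in _BASES:
                if alt == codon[pos]:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if translate_codon(mutant) not in ("Stop", aa):
                    options.append(mutant)
        pick = options[int(rng.integers(0, len(options)))]
        genome["M"][s : s + 3] = [_CODE[b] for b in pick]

    # duplication stem: both paralogs evolve, conversions already possible
    ev.mutate(genome["L"], cfg.dup_stem_length, "stem/L")
    ev.mutate(genome["M"], cfg.dup_stem_length, "stem/M")
    ev.convert(genome, cfg.dup_stem_length, "stem")

    tip_genomes: dict[str, dict[str, np.ndarray]] = {}

    node_counter = iter(range(1, 10_000))

    def descend(node, genome_state):
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            g = {"L": genome_state["L"].copy(), "M": genome_state["M"].copy()}
            name = child.taxon.label if child.taxon else f"node{next(node_counter)}"
            ev.mutate(g["L"], b, f"{name}/L")
            ev.mutate(g["M"], b, f"{name}/M")
            ev.convert(g, b, name)
            if child.is_leaf():
                tip_genomes[name.replace(" ", "_")] = g
            else:
                descend(child, g)

    descend(tree.seed_node, genome)

    records = []
    for species in sorted(tip_genomes):
        g = tip_genomes[species]
        for i in range(1, cfg.n_samples + 1):
            for locus in ("L", "M"):
                hap = g[locus].copy()
                ev.mutate(hap, cfg.theta / 2.0, f"{species}/{locus}/sample{i}")
                records.append(
                    SequenceRecord(
                        raw_id=f"{i}_{species}_M_{locus}",
                        bases="".join(_BASES[b] for b in hap),
                        individual=str(i),
                        species_code=species,
                        sex="M",
                        locus_tag=locus,
                    )
                )
    truth = SimulationTruth(
        species_tree=cfg.species_tree,
        region_layout={r.name: [r.start, r.end, r.kind] for r in region_map.regions},
        seed=cfg.seed,
        events=ev.truth_events,
    )
    return Alignment(tuple(records)), truth


def group_ids(aln: Alignment) -> dict[str, list[str]]:
    """Default grouping: one group per (species, locus tag)."""
    groups: dict[str, list[str]] = {}
    for rec in aln:
        key = f"{rec.species_code}_{rec.locus_tag}"
        groups.setdefault(key, []).append(rec.raw_id)
    return groups
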