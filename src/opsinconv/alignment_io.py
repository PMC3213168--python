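"""Alignment input/output, ID parsing, region maps and gap conventions.

Record IDs follow the underscore scheme used for the gibbon opsin data sets
(``<individual>_<species>_<sex>_<locus>``, e.g. ``1_Hag_M_L``); non-conforming
IDs are accepted leniently with all fields unknown.  Coordinates are 0-based
half-open internally and 1-based inclusive in reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# Two-fold IUPAC ambiguity codes, each expanding to its alphabetically sorted base pair.
IUPAC2 = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
VALID_SYMBOLS = frozenset("ACGT-N") | frozenset(IUPAC2)

KNOWN_SPECIES = frozenset({"Hag", "Hla", "Hpi", "Nle", "Ssy"})
KNOWN_LOCI = frozenset({"L", "M", "E", "S"})


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with metadata parsed from its ID."""

    raw_id: str
    bases: str
    individual: str = "unknown"
    species_code: str = "unknown"
    sex: str = "unknown"
    locus_tag: str = "other"

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"record {self.raw_id!r}: empty sequence")
        bad = set(self.bases) - VALID_SYMBOLS
        if bad:
            pos = next(i for i, b in enumerate(self.bases) if b in bad)
            raise ValueError(
                f"record {self.raw_id!r}: illegal symbol {self.bases[pos]!r} at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Alignment:
    """An ordered collection of equal-length sequence records."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [r.raw_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record IDs: {dup}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, raw_id: str) -> SequenceRecord:
        for r in self.records:
            if r.raw_id == raw_id:
                return r
        raise KeyError(raw_id)

    def ids(self) -> list[str]:
        return [r.raw_id for r in self.records]

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        return Alignment(tuple(self.get(i) for i in wanted))

    def column(self, i: int) -> str:
        return "".join(r.bases[i] for r in self.records)


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # 0-based
    end: int  # half-open
    kind: str  # "exon" | "intron"
    codon_phase_at_start: int = 0  # GFF-style: bases to skip before the first complete codon

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ValueError(f"region {self.name}: kind must be exon or intron")
        if not 0 <= self.start < self.end:
            raise ValueError(f"region {self.name}: bad interval [{self.start}, {self.end})")
        if self.codon_phase_at_start not in (0, 1, 2):
            raise ValueError(f"region {self.name}: phase must be 0..2")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionMap:
    """Exon/intron partition of the aligned region with codon-phase bookkeeping.

    ``residue_anchors`` maps a protein residue number to ``(region name,
    offset)`` where *offset* is the 0-based position of the codon's first base
    within that (exon) region.
    """

    regions: tuple[Region, ...]
    residue_anchors: dict[int, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = -1
        for reg in self.regions:
            if reg.start < prev_end:
                raise ValueError("regions overlap or are unsorted")
            prev_end = reg.end
        for res, (name, off) in self.residue_anchors.items():
            reg = self.region(name)
            if reg.kind != "exon":
                raise ValueError(f"anchor for residue {res} not in an exon")
            if not (0 <= off and off + 3 <= len(reg)):
                raise ValueError(f"anchor for residue {res} outside region {name}")

    def region(self, name: str) -> Region:
        for reg in self.regions:
            if reg.name == name:
                return reg
        raise KeyError(f"unknown region {name!r}")

    def names(self, kind: str | None = None) -> list[str]:
        return [r.name for r in self.regions if kind is None or r.kind == kind]

    def region_of_site(self, site: int) -> Region | None:
        for reg in self.regions:
            if reg.start <= site < reg.end:
                return reg
        return None

    def coding_frame(self, site: int) -> tuple[int, int] | None:
        """Return (codon_start_site, position_in_codon) for an exonic site.

        Codons are framed within each exon from its declared phase; codons
        split across exon boundaries are not bridged and their partial bases
        return None (they are excluded from codon-based statistics).
        """
        reg = self.region_of_site(site)
        if reg is None or reg.kind != "exon":
            return None
        first = reg.start + reg.codon_phase_at_start
        if site < first:
            return None
        pos = (site - first) % 3
        start = site - pos
        if start + 3 > reg.end:
            return None
        return start, pos

    def codon_starts(self, names: Sequence[str] | None = None) -> list[int]:
        """0-based alignment positions of every complete in-frame codon."""
        out = []
        for reg in self.regions:
            if reg.kind != "exon" or (names is not None and reg.name not in names):
                continue
            first = reg.start + reg.codon_phase_at_start
            s = first
            while s + 3 <= reg.end:
                out.append(s)
                s += 3
        return out

    def anchor_codon_start(self, residue_number: int) -> int:
        """Alignment position of the first base of an anchored residue's codon."""
        if residue_number not in self.residue_anchors:
            raise KeyError(f"no anchor for residue {residue_number}")
        name, off = self.residue_anchors[residue_number]
        return self.region(name).start + off


def default_opsin_region_map(
    exon3: int = 169, intron3: int = 1550, exon4: int = 166, intron4: int = 1550, exon5: int = 240
) -> RegionMap:
    """Region map for the exon 3 - exon 5 opsin segment.

    Exon 3 opens in frame with residue 148; every complete codon is anchored
    by its protein residue number, so the spectral-tuning residues 180
    (exon 3) and 277/285 (exon 5) resolve to their codon starts.  Default
    lengths give a ~3.7-kb region with ~3.1 kb of intron.
    """
    starts = {}
    pos = 0
    layout = [
        ("exon3", exon3, "exon", 0),
        ("intron3", intron3, "intron", 0),
        ("exon4", exon4, "exon", (3 - exon3 % 3) % 3),
        ("intron4", intron4, "intron", 0),
        ("exon5", exon5, "exon", (3 - (exon3 + exon4) % 3) % 3),
    ]
    regions = []
    for name, length, kind, phase in layout:
        regions.append(Region(name, pos, pos + length, kind, phase))
        starts[name] = pos
        pos += length
    # residue numbering: exon3 first codon = residue 148
    n_e3 = exon3 // 3  # complete codons in exon 3 (phase 0)
    first_e4 = 148 + n_e3 + (1 if exon3 % 3 else 0)
    e4_phase = (3 - exon3 % 3) % 3
    n_e4 = (exon4 - e4_phase) // 3
    first_e5 = first_e4 + n_e4 + (1 if (exon4 - e4_phase) % 3 else 0)
    e5_phase = (3 - (exon3 + exon4) % 3) % 3
    n_e5 = (exon5 - e5_phase) // 3
    anchors: dict[int, tuple[str, int]] = {}
    for i in range(n_e3):
        anchors[148 + i] = ("exon3", 3 * i)
    for i in range(n_e4):
        anchors[first_e4 + i] = ("exon4", e4_phase + 3 * i)
    for i in range(n_e5):
        anchors[first_e5 + i] = ("exon5", e5_phase + 3 * i)
    return RegionMap(tuple(regions), anchors)


def parse_sequence_id(raw_id: str) -> tuple[str, str, str, str]:
    """Parse ``individual_species_sex_locus`` IDs; lenient on anything else.

    Reference-locus IDs like ``115_Nle_E_1`` put the locus letter (eta-globin
    ``E`` or S opsin ``S``) in the third field with a trailing allele number,
    so a third field other than M/F is interpreted as the locus tag.
    """
    parts = raw_id.split("_")
    if len(parts) == 5 and parts[4] in ("a", "b"):  # phased copy suffix
        parts = parts[:4]
    if len(parts) == 4 and all(parts):
        individual, species, third, fourth = parts
        if third in ("M", "F") and fourth[:1] in KNOWN_LOCI:
            return individual, species, third, fourth[:1]
        if third in KNOWN_LOCI - {"L", "M"}:
            # reference loci (eta-globin 'E', S opsin 'S') carry the locus
            # letter in the third field and an allele number in the fourth
            return individual, species, "unknown", third
    logger.warning("sequence ID %r does not follow the underscore scheme", raw_id)
    return "unknown", "unknown", "unknown", "other"


def _make_record(raw_id: str, bases: str) -> SequenceRecord:
    ind, sp, sex, locus = parse_sequence_id(raw_id)
    return SequenceRecord(
        raw_id=raw_id, bases=bases.upper(), individual=ind, species_code=sp, sex=sex, locus_tag=locus
    )


def read_fasta_alignment(path) -> Alignment:
    """Read a sequential FASTA alignment; case-normalised, file order kept."""
    records = [
        _make_record(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return Alignment(tuple(records))


def write_fasta_alignment(aln: Alignment, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.bases), id=r.raw_id, description="") for r in aln],
        str(path),
        "fasta",
    )


def complete_deletion_columns(aln: Alignment, subset: Iterable[str] | None = None) -> list[int]:
    """Indices of columns free of gaps ('-') and 'N' in the given records.

    'N' is treated like a gap: complete deletion drops any column with
    missing data in the analysed subset.
    """
    ids = aln.ids() if subset is None else list(subset)
    if not ids:
        raise ValueError("complete_deletion_columns: empty subset")
    seqs = [aln.get(i).bases for i in ids]
    return [
        j
        for j in range(aln.length)
        if all(s[j] != "-" and s[j] != "N" for s in seqs)
    ]


def split_heterozygous_record(rec: SequenceRecord) -> tuple[SequenceRecord, SequenceRecord]:
    """Split a record with IUPAC heterozygous sites into two phased copies.

    At each two-fold ambiguity the alphabetically first base goes to copy
    ``_a`` and the second to copy ``_b`` (deterministic phasing; per-site
    statistics are unaffected by the arbitrary assignment).
    """
    a, b = [], []
    for base in rec.bases:
        if base in IUPAC2:
            x, y = IUPAC2[base]
            a.append(x)
            b.append(y)
        else:
            a.append(base)
            b.append(base)
    rec_a = replace(rec, raw_id=rec.raw_id + "_a", bases="".join(a))
    rec_b = replace(rec, raw_id=rec.raw_id + "_b", bases="".join(b))
    return rec_a, rec_b


def slice_region(aln: Alignment, region_map: RegionMap, names: Sequence[str]) -> Alignment:
    """Concatenate the named regions (in map order) into a new alignment."""
    if not names:
        raise ValueError("slice_region: empty region-name list")
    for n in names:
        region_map.region(n)  # raises KeyError on unknown names
    ordered = [r for r in region_map.regions if r.name in set(names)]
    out = []
    for rec in aln:
        parts = [rec.bases[r.start : r.end] for r in ordered]
        out.append(replace(rec, bases="".join(parts)))
    return Alignment(tuple(out))


def sliced_region_map(region_map: RegionMap, names: Sequence[str]) -> RegionMap:
    """Region map describing the coordinate system of slice_region's output."""
    ordered = [r for r in region_map.regions if r.name in set(names)]
    regions = []
    pos = 0
    for r in ordered:
        regions.append(Region(r.name, pos, pos + len(r), r.kind, r.codon_phase_at_start))
        pos += len(r)
    anchors = {
        res: (name, off)
        for res, (name, off) in region_map.residue_anchors.items()
        if name in set(names)
    }
    return RegionMap(tuple(regions), anchors)
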