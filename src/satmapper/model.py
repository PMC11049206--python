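"""Domain types and sequence utilities for satellitome analysis.

A *satDNA family* is a set of near-identical tandemly repeated monomers.
Families are named after the convention ``<G><spp>Sat<NNN>-<RUL>``: the
capitalized genus initial, the first three (lowercase) letters of the
species epithet, ``Sat``, the abundance rank zero-padded to three digits,
and the repeat-unit length in bp (e.g. ``CameSat001-141``).  An optional
trailing tag (e.g. ``-tel`` for the telomeric TTAGG repeat) may follow the
RUL segment.

Quantification against sequencing reads uses one *search library entry*
per family: the dimer of the monomer when the repeat unit is longer than
100 bp, otherwise the shortest head-to-tail concatemer of at least 200 bp,
so that a short read of any phase aligns contiguously within the entry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = [
    "SatDNAFamily",
    "SearchLibraryEntry",
    "Assembly",
    "at_content",
    "name_family",
    "build_search_library",
    "reverse_complement",
    "canonical_rotation",
    "read_consensus_library",
    "FAMILY_NAME_RE",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Naming convention: genus initial, 3-letter species prefix, "Sat",
#: 3-digit rank, "-", RUL; optional extra dash-delimited tag (e.g. "-tel").
FAMILY_NAME_RE = re.compile(r"^[A-Z][a-z]{3}Sat(\d{3})-(\d+)(-[A-Za-z0-9]+)?$")


def _validate_dna(seq: str, *, what: str = "sequence") -> None:
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(
            f"invalid character(s) {sorted(bad)} in {what}; "
            "expected uppercase A/C/G/T/N"
        )


def at_content(seq: str) -> float:
    """Percent A+T of a DNA sequence, ignoring N positions.

    N carries no composition information, so it is excluded from both the
    numerator and the denominator.  Raises ``ValueError`` on an empty or
    all-N sequence, for which the content is undefined.
    """
    if not seq:
        raise ValueError("A+T content undefined for an empty sequence")
    _validate_dna(seq)
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("A+T content undefined for an all-N sequence")
    return 100.0 * (seq.count("A") + seq.count("T")) / denom


def name_family(genus: str, species: str, rank: int, rul: int) -> str:
    """Build a family name following the satellitome naming convention."""
    if not genus or not species:
        raise ValueError("genus and species must be non-empty")
    if rank < 1:
        raise ValueError(f"rank must be >= 1, got {rank}")
    if rank > 999:
        raise ValueError(f"rank {rank} overflows the 3-digit padding")
    if rul < 1:
        raise ValueError(f"repeat unit length must be >= 1, got {rul}")
    if len(species) < 3:
        raise ValueError(f"species epithet {species!r} shorter than 3 letters")
    return f"{genus[0].upper()}{species[:3].lower()}Sat{rank:03d}-{rul}"


def parse_rul_from_name(name: str) -> int:
    """Extract the repeat-unit length segment from a family name.

    The RUL is the first dash-delimited numeric segment, so trailing tags
    (``CameSat035-5-tel`` -> 5) are handled.
    """
    m = FAMILY_NAME_RE.match(name)
    if m is None:
        raise ValueError(f"{name!r} does not follow the family naming convention")
    return int(m.group(2))


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; N maps to N."""
    _validate_dna(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_rotation(monomer: str) -> str:
    """Phase- and strand-invariant representative of a tandem monomer.

    Tandem copies have an arbitrary phase relative to the consensus start
    and may sit on either strand, so family identity is defined up to
    cyclic rotation and reverse complement.  Returns the lexicographically
    smallest string among all cyclic rotations of the monomer and of its
    reverse complement.
    """
    if not monomer:
        raise ValueError("monomer must be non-empty")
    _validate_dna(monomer)
    best = None
    for s in (monomer, reverse_complement(monomer)):
        doubled = s + s
        for i in range(len(s)):
            cand = doubled[i : i + len(s)]
            if best is None or cand < best:
                best = cand
    return best


@dataclass
class SatDNAFamily:
    """One satellite DNA family of the satellitome catalogue.

    ``monomer`` may be empty for table-only records (printed summary rows
    carry no sequence); when present, its length must equal ``rul``.
    ``abundance_percent`` and ``divergence_percent`` are genome percentages
    as printed in satellitome tables (K2P divergence x100).
    """

    name: str
    rank: int
    rul: int
    monomer: str = ""
    genus: str = ""
    species: str = ""
    at_percent: float | None = None
    abundance_percent: float = 0.0
    divergence_percent: float | None = None

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")
        if self.rul < 1:
            raise ValueError(f"rul must be >= 1, got {self.rul}")
        if self.monomer:
            self.monomer = self.monomer.upper()
            _validate_dna(self.monomer, what=f"monomer of {self.name}")
            if len(self.monomer) != self.rul:
                raise ValueError(
                    f"{self.name}: rul={self.rul} but monomer length "
                    f"{len(self.monomer)}"
                )
            if self.at_percent is None:
                self.at_percent = at_content(self.monomer)
        if FAMILY_NAME_RE.match(self.name):
            parsed = parse_rul_from_name(self.name)
            if parsed != self.rul:
                raise ValueError(
                    f"name {self.name!r} encodes RUL {parsed}, got rul={self.rul}"
                )
        if self.at_percent is not None and not 0.0 <= self.at_percent <= 100.0:
            raise ValueError(f"at_percent out of [0, 100]: {self.at_percent}")
        if self.abundance_percent < 0:
            raise ValueError("abundance_percent must be >= 0")

    @property
    def is_telomeric(self) -> bool:
        """Whether this record is the telomeric repeat (name tagged ``-tel``)."""
        return self.name.endswith("-tel")

    @classmethod
    def from_monomer(
        cls,
        monomer: str,
        *,
        genus: str,
        species: str,
        rank: int,
        abundance_percent: float = 0.0,
    ) -> "SatDNAFamily":
        monomer = monomer.upper()
        return cls(
            name=name_family(genus, species, rank, len(monomer)),
            rank=rank,
            rul=len(monomer),
            monomer=monomer,
            genus=genus,
            species=species,
            abundance_percent=abundance_percent,
        )


@dataclass(frozen=True)
class SearchLibraryEntry:
    """Dimer/concatemer of one family's monomer used for read masking."""

    family_id: str
    sequence: str
    copies: int

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if len(self.sequence) % self.copies != 0:
            raise ValueError("sequence length must be copies x monomer length")


def build_search_library(family: SatDNAFamily) -> SearchLibraryEntry:
    """Concatemerize a family's monomer for read quantification.

    Families with RUL > 100 bp use the dimer; shorter families the smallest
    concatemer of at least 200 bp.  At exactly 100 bp the dimer (200 bp)
    satisfies both rules and is used.
    """
    if not family.monomer:
        raise ValueError(f"{family.name}: no consensus monomer available")
    rul = family.rul
    if rul >= 100:
        copies = 2
    else:
        copies = -(-200 // rul)  # ceil(200 / rul)
    return SearchLibraryEntry(
        family_id=family.name, sequence=family.monomer * copies, copies=copies
    )


@dataclass
class Assembly:
    """A chromosome-scale assembly held in memory.

    ``chromosomes`` preserves input order; sequences are uppercase DNA.
    """

    chromosomes: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c for c, _ in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate chromosome ids in assembly")
        self.chromosomes = [(c, s.upper()) for c, s in self.chromosomes]
        for c, s in self.chromosomes:
            _validate_dna(s, what=f"chromosome {c}")

    @property
    def ids(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes}

    @property
    def total_bp(self) -> int:
        return sum(len(s) for _, s in self.chromosomes)

    def sequence(self, chrom: str) -> str:
        for c, s in self.chromosomes:
            if c == chrom:
                return s
        raise KeyError(f"unknown chromosome id {chrom!r}")

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.chromosomes)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Assembly":
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(chromosomes=records)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for cid, seq in self.chromosomes:
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def read_consensus_library(
    path: str | Path,
    *,
    genus: str = "",
    species: str = "",
) -> list[SatDNAFamily]:
    """Load consensus monomers from a one-record-per-family FASTA.

    Record ids matching the naming convention are taken verbatim (rank and
    RUL parsed from the name); any other ids require ``genus``/``species``
    and get auto-named in file order, which is assumed to be abundance
    order for unranked input.
    """
    families: list[SatDNAFamily] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        monomer = str(rec.seq).upper()
        m = FAMILY_NAME_RE.match(rec.id)
        if m:
            families.append(
                SatDNAFamily(
                    name=rec.id,
                    rank=int(m.group(1)),
                    rul=len(monomer),
                    monomer=monomer,
                    genus=genus,
                    species=species,
                )
            )
        else:
            if not (genus and species):
                raise ValueError(
                    f"record {rec.id!r} does not follow the naming convention; "
                    "pass genus and species to auto-name families"
                )
            families.append(
                SatDNAFamily.from_monomer(
                    monomer, genus=genus, species=species, rank=i
                )
            )
    if not families:
        raise ValueError(f"no FASTA records in {path}")
    names = [f.name for f in families]
    if len(set(names)) != len(names):
        raise ValueError("duplicate family names in consensus library")
    return families
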