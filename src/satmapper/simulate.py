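"""Synthetic genomes, planted satDNA arrays, and simulated read sets.

The generator emulates the organization the mapper is built for: long
tandem arrays of a consensus monomer, each copy independently mutated to a
target Kimura-two-parameter divergence, embedded in i.i.d. random
background sequence (A+T-rich by default, mirroring beetle genomes), plus
uniform shotgun read sampling at a chosen coverage.  Every generator is a
pure function of its seed.

Mutation model: for a copy at target divergence ``d`` (substitutions per
site), the number of substitution events is Poisson with mean ``d x L``;
events hit uniform-random positions (multiple hits allowed) and are
transitions with odds ``tstv_ratio`` : 1 against transversions, the two
transversion targets equiprobable.  This is exactly a K2P substitution
process, so the K2P estimator applied to copy-vs-consensus alignments
recovers ``d`` in expectation.  Indels are off by default and available
through ``indel_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotator import RepeatArray
from .model import Assembly, SatDNAFamily, reverse_complement

__all__ = [
    "PlantSpec",
    "SyntheticTruth",
    "mutate_to_divergence",
    "plant_arrays",
    "simulate_reads",
    "write_reads_fasta",
    "write_reads_fastq",
    "DEFAULT_BACKGROUND_GC",
    "MAX_TARGET_DIVERGENCE",
]

#: Background G+C fraction: beetle genomes run A+T-rich (~64% A+T).
DEFAULT_BACKGROUND_GC = 0.36
#: Target divergences at or beyond this saturate the K2P estimator in
#: practice and are refused.
MAX_TARGET_DIVERGENCE = 0.75

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {
    "A": "CT",
    "G": "CT",
    "C": "AG",
    "T": "AG",
}


@dataclass(frozen=True)
class PlantSpec:
    """One planted tandem array: where, how many copies, how diverged."""

    family: SatDNAFamily
    chrom: str
    start: int
    n_copies: int
    target_divergence: float = 0.0
    tstv_ratio: float = 2.0
    strand: str = "+"
    interleaved: bool = False  # allow overlap with other planted intervals

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.n_copies * self.family.rul

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class SyntheticTruth:
    """A generated genome together with its planted ground truth."""

    genome: Assembly
    arrays: list[RepeatArray]
    #: per planted copy: (family, chrom, start, transitions, transversions)
    substitution_log: list[tuple[str, str, int, int, int]] = field(
        default_factory=list
    )

    @property
    def planted_bp(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for arr in self.arrays:
            out[arr.family_id] = out.get(arr.family_id, 0) + arr.length
        return out


def _check_divergence(d: float) -> None:
    if d < 0:
        raise ValueError(f"target divergence must be >= 0, got {d}")
    if d >= MAX_TARGET_DIVERGENCE:
        raise ValueError(
            f"target divergence {d} is beyond the usable K2P domain "
            f"(< {MAX_TARGET_DIVERGENCE})"
        )


def mutate_to_divergence(
    monomer: str,
    d_target: float,
    tstv_ratio: float = 2.0,
    rng: np.random.Generator | int | None = None,
    indel_rate: float = 0.0,
) -> tuple[str, int, int]:
    """One mutated copy of a monomer at expected K2P divergence ``d_target``.

    Returns ``(sequence, transitions, transversions)`` where the counts
    are realized substitution *events* (multiple hits may overwrite each
    other in the sequence).  ``indel_rate`` adds per-site single-base
    insertions/deletions on top of the substitution process.
    """
    _check_divergence(d_target)
    if tstv_ratio <= 0:
        raise ValueError("tstv_ratio must be > 0")
    rng = np.random.default_rng(rng)
    seq = list(monomer)
    L = len(seq)
    n_events = rng.poisson(d_target * L)
    ts = tv = 0
    p_ts = tstv_ratio / (tstv_ratio + 1.0)
    for _ in range(n_events):
        pos = int(rng.integers(L))
        base = seq[pos]
        if base == "N":
            continue
        if rng.random() < p_ts:
            seq[pos] = _TRANSITION_OF[base]
            ts += 1
        else:
            choices = _TRANSVERSIONS_OF[base]
            seq[pos] = choices[int(rng.integers(2))]
            tv += 1
    if indel_rate > 0.0:
        out = []
        alphabet = "ACGT"
        for b in seq:
            r = rng.random()
            if r < indel_rate / 2.0:
                continue  # deletion
            out.append(b)
            if r >= indel_rate / 2.0 and r < indel_rate:
                out.append(alphabet[int(rng.integers(4))])
        seq = out
    return "".join(seq), ts, tv


def _random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = rng.choice(_BASES, size=length, p=probs)
    return draw.tobytes().decode("ascii")


def plant_arrays(
    chrom_lengths: dict[str, int],
    plan: Sequence[PlantSpec],
    background_gc: float = DEFAULT_BACKGROUND_GC,
    rng_seed: int | None = 0,
) -> SyntheticTruth:
    """Generate a genome of random background with planted tandem arrays.

    Arrays are written over the background at their planned coordinates;
    each copy is mutated independently.  Planted intervals must stay
    within chromosome bounds and must not overlap unless flagged
    ``interleaved``.
    """
    if not 0.0 <= background_gc <= 1.0:
        raise ValueError("background_gc must be a fraction in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    chroms: dict[str, list[str]] = {}
    for cid, length in chrom_lengths.items():
        chroms[cid] = list(_random_background(length, background_gc, rng))
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    truth: list[RepeatArray] = []
    sub_log: list[tuple[str, str, int, int, int]] = []
    for spec in plan:
        if spec.chrom not in chroms:
            raise ValueError(f"unknown chromosome {spec.chrom!r} in plan")
        if spec.end > chrom_lengths[spec.chrom]:
            raise ValueError(
                f"planted array [{spec.start}, {spec.end}) exceeds "
                f"{spec.chrom} length {chrom_lengths[spec.chrom]}"
            )
        if not spec.interleaved:
            for s, e in placed[spec.chrom]:
                if spec.start < e and s < spec.end:
                    raise ValueError(
                        f"planted arrays overlap on {spec.chrom}: "
                        f"[{s}, {e}) and [{spec.start}, {spec.end})"
                    )
        placed[spec.chrom].append((spec.start, spec.end))
        pos = spec.start
        for _ in range(spec.n_copies):
            copy, ts, tv = mutate_to_divergence(
                spec.family.monomer,
                spec.target_divergence,
                spec.tstv_ratio,
                rng,
            )
            if spec.strand == "-":
                copy = reverse_complement(copy)
            chroms[spec.chrom][pos : pos + len(copy)] = list(copy)
            sub_log.append((spec.family.name, spec.chrom, pos, ts, tv))
            pos += len(copy)
        truth.append(
            RepeatArray(
                family_id=spec.family.name,
                chrom=spec.chrom,
                start=spec.start,
                end=spec.end,
                strand=spec.strand,
                n_monomers=spec.n_copies,
                mean_identity_percent=100.0,
            )
        )
    genome = Assembly(
        chromosomes=[(cid, "".join(chroms[cid])) for cid in chrom_lengths]
    )
    return SyntheticTruth(genome=genome, arrays=truth, substitution_log=sub_log)


def simulate_reads(
    genome: Assembly,
    read_length: int = 101,
    coverage: float = 1.0,
    rng_seed: int | None = 0,
    paired: bool = False,
    insert_size: int = 350,
    error_rate: float = 0.0,
) -> list[tuple[str, str]]:
    """Uniform shotgun reads from a genome as (id, sequence) pairs.

    Read count is ``round(coverage x genome bp / read_length)``; start
    positions are uniform over valid positions of all chromosomes, both
    strands equiprobable.  ``paired`` emits reads in proper pairs at the
    given insert size (the count still honors the coverage).  Sequencing
    error is off by default; ``error_rate`` adds uniform substitutions.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    min_len = min(genome.lengths.values())
    if read_length > min_len:
        raise ValueError(
            f"read_length {read_length} exceeds shortest chromosome ({min_len} bp)"
        )
    rng = np.random.default_rng(rng_seed)
    n_reads = int(round(coverage * genome.total_bp / read_length))
    span = insert_size if paired else read_length
    starts_per_chrom = {
        cid: max(1, length - span + 1) for cid, length in genome.lengths.items()
    }
    cids = list(starts_per_chrom)
    weights = np.array([starts_per_chrom[c] for c in cids], dtype=float)
    weights /= weights.sum()
    reads: list[tuple[str, str]] = []
    i = 0
    while len(reads) < n_reads:
        cid = cids[int(rng.choice(len(cids), p=weights))]
        seq = genome.sequence(cid)
        start = int(rng.integers(starts_per_chrom[cid]))
        minus = bool(rng.integers(2))
        if paired:
            frag = seq[start : start + span]
            if minus:
                frag = reverse_complement(frag)
            r1 = frag[:read_length]
            r2 = reverse_complement(frag[-read_length:])
            for mate, r in (("/1", r1), ("/2", r2)):
                reads.append((f"read{i:07d}{mate}", r))
            i += 1
        else:
            r = seq[start : start + read_length]
            if minus:
                r = reverse_complement(r)
            reads.append((f"read{i:07d}", r))
            i += 1
    reads = reads[:n_reads]
    if error_rate > 0.0:
        reads = [(rid, _add_errors(r, error_rate, rng)) for rid, r in reads]
    return reads


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    seq = list(read)
    for pos in np.nonzero(rng.random(len(seq)) < rate)[0]:
        base = seq[pos]
        if base == "N":
            continue
        others = [b for b in "ACGT" if b != base]
        seq[pos] = others[int(rng.integers(3))]
    return "".join(seq)


def write_reads_fasta(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f">{rid}\n{seq}\n")


def write_reads_fastq(
    reads: Sequence[tuple[str, str]], path: str | Path, quality_char: str = "I"
) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastx(path: str | Path) -> list[tuple[str, str]]:
    """Load reads from FASTA or FASTQ (qualities ignored)."""
    from Bio import SeqIO

    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, fmt)]
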