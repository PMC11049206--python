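"""In-silico chromosome mapping of satDNA families (the CHRISMAPP core).

Each family's consensus monomer is located on the assembled chromosomes by
similarity search at a percent-identity threshold (70% by default), hits
are merged into tandem arrays, and arrays are serialized as GFF3.

Similarity model
----------------
Identity is defined as matched columns / alignment columns (indel columns
count against identity) under semi-global alignment of the monomer against
a genomic window: the full monomer must align, the genomic ends are free.
Scoring is match +1, mismatch -1, affine gaps costing 2 + g for a gap of
length g (open surcharge 2, extension 1 per column).  The
search itself is a two-stage scan: a vectorized gap-free screen of the
monomer at every genomic offset (which is phase-invariant by construction:
every full monomer copy in a tandem array, whatever its phase relative to
the consensus start, begins at *some* offset), followed by affine
semi-global refinement of the surviving candidates with Biopython's
PairwiseAligner.  On indel-free arrays the two stages agree exactly, since
under this scoring a gap column is strictly worse than a mismatch.

Monomers shorter than 20 bp are a special case: percent identity over so
few columns is meaninglessly permissive at 70%, so these families are
annotated by exact tandem-run detection of at least 4 consecutive copies
(any rotation, either strand) instead of scored alignment.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .model import Assembly, SatDNAFamily, reverse_complement

__all__ = [
    "RepeatHit",
    "RepeatArray",
    "find_monomer_hits",
    "merge_hits_into_arrays",
    "annotate_assembly",
    "write_gff3",
    "read_gff3",
    "write_bed6",
    "binned_density",
    "DEFAULT_MIN_IDENTITY",
    "SHORT_MONOMER_BP",
    "MIN_TANDEM_COPIES",
]

DEFAULT_MIN_IDENTITY = 70.0
#: Monomers below this length are annotated by exact tandem-run detection.
SHORT_MONOMER_BP = 20
#: Minimum consecutive exact copies to call a short-monomer tandem run.
MIN_TANDEM_COPIES = 4
#: Screen slack (percentage points below threshold) passed to refinement,
#: so modest indel divergence is not lost at the gap-free stage.
SCREEN_SLACK = 10.0

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class RepeatHit:
    """One monomer-scale match on a chromosome (0-based, half-open)."""

    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    identity_percent: float
    transitions: int = 0
    transversions: int = 0
    indel_columns: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad hit interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class RepeatArray:
    """A merged run of monomer hits: the unit drawn on chromosome maps."""

    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_monomers: int
    mean_identity_percent: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad array interval [{self.start}, {self.end})")
        if self.n_monomers < 1:
            raise ValueError("array must contain at least one monomer hit")

    @property
    def length(self) -> int:
        return self.end - self.start


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    # affine gaps: a length-g gap costs 2 + g (open surcharge 2, extension
    # 1 per column), so a gap column is strictly worse than a mismatch and
    # the optimum is unique on indel-free sequence
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    # the genomic window's overhang beyond the query is free: dashes at
    # the ends of the query row cost nothing (semi-global alignment)
    aligner.end_deletion_score = 0
    return aligner


_SEMIGLOBAL = _make_aligner()


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _screen_offsets(
    chrom: np.ndarray, monomer: np.ndarray, min_identity: float
) -> np.ndarray:
    """Offsets where the gap-free monomer identity clears the screen."""
    m = len(monomer)
    n = len(chrom) - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.intp)
    matches = np.zeros(n, dtype=np.int32)
    for j in range(m):
        matches += chrom[j : j + n] == monomer[j]
    need = (min_identity - SCREEN_SLACK) / 100.0 * m
    return np.nonzero(matches >= need)[0]


def _alignment_stats(alignment, query: str, window: str):
    """Identity and substitution composition of a semi-global alignment.

    Only columns between the first and last aligned block count (the free
    genomic overhangs are not part of the alignment proper).  Gap and N
    columns are excluded from the substitution classification.
    """
    blocks_t, blocks_q = alignment.aligned
    if len(blocks_t) == 0:
        return None
    t0, t1 = int(blocks_t[0][0]), int(blocks_t[-1][1])
    q0, q1 = int(blocks_q[0][0]), int(blocks_q[-1][1])
    matches = 0
    ts = tv = 0
    aligned_pair_cols = 0
    for (ta, tb), (qa, qb) in zip(blocks_t, blocks_q):
        for k in range(tb - ta):
            a = window[ta + k]
            b = query[qa + k]
            aligned_pair_cols += 1
            if a == b and a != "N":
                matches += 1
            elif a != b and a != "N" and b != "N":
                if (a, b) in _TRANSITIONS:
                    ts += 1
                else:
                    tv += 1
    indel_cols = (t1 - t0 - aligned_pair_cols) + (q1 - q0 - aligned_pair_cols)
    columns = aligned_pair_cols + indel_cols
    if columns == 0:
        return None
    identity = 100.0 * matches / columns
    return t0, t1, q1 - q0, identity, ts, tv, indel_cols


def _refine_candidate(
    chrom_seq: str, query: str, offset: int, flank: int
) -> tuple[int, int, int, float, int, int, int] | None:
    w0 = max(0, offset - flank)
    w1 = min(len(chrom_seq), offset + len(query) + flank)
    window = chrom_seq[w0:w1]
    alignments = _SEMIGLOBAL.align(window, query)
    stats = _alignment_stats(alignments[0], query, window)
    if stats is None:
        return None
    t0, t1, qlen, identity, ts, tv, indels = stats
    return w0 + t0, w0 + t1, qlen, identity, ts, tv, indels


def _resolve_overlaps(
    hits: list[RepeatHit], tolerance: int = 0
) -> list[RepeatHit]:
    """Resolve conflicting same-family hits.

    A hit whose interval is strictly contained in another hit's interval
    is a truncation artifact and is dropped.  Among the rest, hits
    overlapping by more than ``tolerance`` bp conflict and the
    higher-identity one wins (ties: leftmost, '+' before '-'); smaller
    overlaps — boundary jitter from gapped alignments of adjacent copies —
    are allowed to coexist.
    """
    keep = []
    intervals = {(h.start, h.end) for h in hits}
    for h in hits:
        contained = any(
            s <= h.start and h.end <= e and (s, e) != (h.start, h.end)
            for s, e in intervals
        )
        if not contained:
            keep.append(h)
    order = sorted(
        keep, key=lambda h: (-h.identity_percent, h.start, h.end, h.strand)
    )
    accepted: list[RepeatHit] = []
    for h in order:
        clash = any(
            min(h.end, a.end) - max(h.start, a.start) > tolerance
            for a in accepted
        )
        if not clash:
            accepted.append(h)
    accepted.sort(key=lambda h: (h.start, h.end))
    return accepted


def _scored_hits(
    family: SatDNAFamily, chrom_seq: str, chrom_id: str, min_identity: float
) -> list[RepeatHit]:
    chrom_arr = _encode(chrom_seq)
    m = family.rul
    flank = max(8, m // 8)
    hits: list[RepeatHit] = []
    for strand, query in (
        ("+", family.monomer),
        ("-", reverse_complement(family.monomer)),
    ):
        offsets = _screen_offsets(chrom_arr, _encode(query), min_identity)
        for off in offsets:
            refined = _refine_candidate(chrom_seq, query, int(off), flank)
            if refined is None:
                continue
            start, end, qlen, identity, ts, tv, indels = refined
            if identity < min_identity or qlen < 0.5 * m:
                continue
            # ts/tv classification is strand-symmetric, so '-' hits keep
            # the counts computed on the reverse-complemented query
            hits.append(
                RepeatHit(
                    family_id=family.name,
                    chrom=chrom_id,
                    start=start,
                    end=end,
                    strand=strand,
                    identity_percent=identity,
                    transitions=ts,
                    transversions=tv,
                    indel_columns=indels,
                )
            )
    # de-duplicate identical intervals produced by adjacent candidates
    seen: set[tuple[int, int, str]] = set()
    unique = []
    for h in sorted(hits, key=lambda h: (h.start, h.end, h.strand)):
        key = (h.start, h.end, h.strand)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    return _resolve_overlaps(unique, tolerance=m // 10)


def _tandem_run_hits(
    family: SatDNAFamily, chrom_seq: str, chrom_id: str
) -> list[RepeatHit]:
    """Exact tandem-run detection for very short monomers.

    Finds maximal runs of >= MIN_TANDEM_COPIES consecutive exact copies of
    any rotation of the monomer (either strand) and reports one hit per
    full copy.  '+' wins when a run matches both strands (rotation sets of
    a strand-symmetric monomer coincide).
    """
    import re as _re

    m = family.rul
    fwd_rots = {family.monomer[i:] + family.monomer[:i] for i in range(m)}
    rc = reverse_complement(family.monomer)
    rev_rots = {rc[i:] + rc[:i] for i in range(m)} - fwd_rots
    intervals: list[tuple[int, int, str]] = []
    for strand, rots in (("+", fwd_rots), ("-", rev_rots)):
        per_strand: list[tuple[int, int]] = []
        for rot in sorted(rots):
            pat = _re.compile(f"(?:{rot}){{{MIN_TANDEM_COPIES},}}")
            pos = 0
            while True:
                match = pat.search(chrom_seq, pos)
                if match is None:
                    break
                per_strand.append((match.start(), match.end()))
                pos = match.start() + 1
        if not per_strand:
            continue
        per_strand.sort()
        merged = [list(per_strand[0])]
        for s, e in per_strand[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        intervals.extend((s, e, strand) for s, e in merged)
    hits: list[RepeatHit] = []
    for s, e, strand in intervals:
        n_copies = (e - s) // m
        if n_copies < MIN_TANDEM_COPIES:
            continue
        for k in range(n_copies):
            hits.append(
                RepeatHit(
                    family_id=family.name,
                    chrom=chrom_id,
                    start=s + k * m,
                    end=s + (k + 1) * m,
                    strand=strand,
                    identity_percent=100.0,
                )
            )
    return _resolve_overlaps(hits)


def find_monomer_hits(
    family: SatDNAFamily,
    chrom_seq: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    *,
    chrom_id: str = "chr",
) -> list[RepeatHit]:
    """All monomer-scale matches of a family on one chromosome sequence.

    Returns every maximal match with identity >= ``min_identity`` on either
    strand, with at least half of the monomer aligned, sorted by
    (start, end); overlapping same-family hits are resolved to the
    higher-identity one (ties: leftmost).
    """
    if not family.monomer:
        raise ValueError(f"{family.name}: no consensus monomer available")
    if not chrom_seq:
        raise ValueError("empty chromosome sequence")
    if not 0.0 < min_identity <= 100.0:
        raise ValueError(f"min_identity must be in (0, 100], got {min_identity}")
    chrom_seq = chrom_seq.upper()
    if family.rul < SHORT_MONOMER_BP:
        return _tandem_run_hits(family, chrom_seq, chrom_id)
    return _scored_hits(family, chrom_seq, chrom_id, min_identity)


def merge_hits_into_arrays(
    hits: Sequence[RepeatHit], max_gap: int
) -> list[RepeatArray]:
    """Merge consecutive same-strand hits with gaps <= ``max_gap`` bp.

    Input must be same-family hits sorted by (start, end); a run of merged
    hits becomes one :class:`RepeatArray` whose identity is the unweighted
    mean of its hits'.
    """
    if not hits:
        return []
    fams = {h.family_id for h in hits}
    if len(fams) > 1:
        raise ValueError(f"hits from multiple families: {sorted(fams)}")
    for a, b in zip(hits, hits[1:]):
        if (a.chrom, a.start, a.end) > (b.chrom, b.start, b.end):
            raise ValueError("hits must be sorted by (chrom, start, end)")
    arrays: list[RepeatArray] = []
    run: list[RepeatHit] = [hits[0]]
    for h in hits[1:]:
        prev = run[-1]
        if (
            h.chrom == prev.chrom
            and h.strand == prev.strand
            and h.start - prev.end <= max_gap
        ):
            run.append(h)
        else:
            arrays.append(_close_run(run))
            run = [h]
    arrays.append(_close_run(run))
    return arrays


def _close_run(run: list[RepeatHit]) -> RepeatArray:
    return RepeatArray(
        family_id=run[0].family_id,
        chrom=run[0].chrom,
        start=run[0].start,
        end=run[-1].end,
        strand=run[0].strand,
        n_monomers=len(run),
        mean_identity_percent=statistics.fmean(h.identity_percent for h in run),
    )


def annotate_assembly(
    families: Sequence[SatDNAFamily],
    assembly: Assembly,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_gap_factor: float = 1.0,
) -> dict[str, list[RepeatArray]]:
    """Map every family on every chromosome; families are independent.

    ``max_gap_factor`` scales the hit-merging gap: hits closer than
    ``max_gap_factor x RUL`` bp join one array.
    """
    if not assembly.chromosomes:
        raise ValueError("empty assembly")
    names = [f.name for f in families]
    if len(set(names)) != len(names):
        raise ValueError("family names must be unique")
    out: dict[str, list[RepeatArray]] = {}
    for family in families:
        arrays: list[RepeatArray] = []
        max_gap = max(1, int(round(max_gap_factor * family.rul)))
        for chrom_id, seq in assembly:
            hits = find_monomer_hits(
                family, seq, min_identity, chrom_id=chrom_id
            )
            arrays.extend(merge_hits_into_arrays(hits, max_gap))
        out[family.name] = arrays
    return out


# ---------------------------------------------------------------------------
# GFF3 / BED serialization (0-based half-open internally, GFF3 1-based
# inclusive on disk)

_GFF_SOURCE = "chrismapp"
_GFF_TYPE = "satellite_DNA"


def write_gff3(
    arrays: Iterable[RepeatArray], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, arr in enumerate(arrays, start=1):
            attrs = (
                f"ID=satarray{i:06d};Name={arr.family_id};"
                f"n_monomers={arr.n_monomers};"
                f"mean_identity={arr.mean_identity_percent:.4f}"
            )
            fh.write(
                "\t".join(
                    [
                        arr.chrom,
                        _GFF_SOURCE,
                        _GFF_TYPE,
                        str(arr.start + 1),
                        str(arr.end),
                        f"{arr.mean_identity_percent:.2f}",
                        arr.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[RepeatArray]:
    """Parse a chrismapp GFF3 back into arrays (inverse of write_gff3)."""
    arrays: list[RepeatArray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, _src, _type, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i = int(start) - 1
                end_i = int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            kv = {}
            for item in attrs.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k] = v
            missing = {"Name", "n_monomers", "mean_identity"} - kv.keys()
            if missing:
                raise ValueError(
                    f"{path}:{lineno}: missing attribute(s) {sorted(missing)}"
                )
            try:
                arrays.append(
                    RepeatArray(
                        family_id=kv["Name"],
                        chrom=chrom,
                        start=start_i,
                        end=end_i,
                        strand=strand,
                        n_monomers=int(kv["n_monomers"]),
                        mean_identity_percent=float(kv["mean_identity"]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return arrays


def write_bed6(arrays: Iterable[RepeatArray], path: str | Path) -> None:
    """BED6 export: 0-based half-open, score = mean identity x 10."""
    with open(path, "w") as fh:
        for arr in arrays:
            score = min(1000, int(round(arr.mean_identity_percent * 10)))
            fh.write(
                f"{arr.chrom}\t{arr.start}\t{arr.end}\t{arr.family_id}\t"
                f"{score}\t{arr.strand}\n"
            )


def binned_density(
    arrays: Sequence[RepeatArray],
    chrom_length: int,
    bin_size: int = 100_000,
) -> dict[str, np.ndarray]:
    """Occupied bp per genomic bin, per family, on one chromosome.

    An array straddling a bin boundary contributes proportionally to each
    bin it covers, so per-family bin sums equal total array bp.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = -(-chrom_length // bin_size)
    out: dict[str, np.ndarray] = {}
    for arr in arrays:
        if arr.end > chrom_length:
            raise ValueError(
                f"array [{arr.start}, {arr.end}) exceeds chromosome length "
                f"{chrom_length}"
            )
        dens = out.setdefault(arr.family_id, np.zeros(n_bins))
        first = arr.start // bin_size
        last = (arr.end - 1) // bin_size
        for b in range(first, last + 1):
            lo = max(arr.start, b * bin_size)
            hi = min(arr.end, (b + 1) * bin_size)
            dens[b] += hi - lo
    return out
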