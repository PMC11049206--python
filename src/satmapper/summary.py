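"""Satellitome-level summary statistics and family ranking/naming.

Reproduces the catalogue-style summary of a satellitome table: number of
families, total genome fraction, top-k fraction, divergence range and
mean, repeat-unit-length range and histogram.

Convention: the telomeric repeat (family name tagged ``-tel``) is part of
the catalogue — it contributes to counts, totals, the mean divergence and
the RUL range — but is excluded from the *divergence extremes*, which
describe the range of satDNA families proper.  Telomeric repeats are a
distinct, universally conserved repeat class whose low divergence is not
informative about satellitome turnover.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .model import FAMILY_NAME_RE, SatDNAFamily, name_family
from .quantify import MaskingResult

__all__ = [
    "SatellitomeSummary",
    "summarize",
    "rank_and_name",
    "load_table_fixture",
    "packaged_table_path",
    "RUL_BIN_BP",
]

#: RUL histogram bin width in bp (bins [1-100], [101-200], ...).
RUL_BIN_BP = 100

_FIXTURE_COLUMNS = [
    "family",
    "genome_percent",
    "divergence_k2p",
    "rul_bp",
    "at_percent",
]


@dataclass
class SatellitomeSummary:
    n_families: int
    total_percent: float
    top_k: int
    top_k_percent: float
    min_divergence: float
    min_divergence_family: str
    max_divergence: float
    max_divergence_family: str
    mean_divergence: float
    min_abundance: float
    min_abundance_family: str
    min_rul: int
    min_rul_family: str
    max_rul: int
    max_rul_family: str
    rul_histogram: dict[int, int] = field(default_factory=dict)

    @property
    def modal_rul_bin(self) -> int:
        """Left edge (bp) of the most populated RUL bin."""
        return max(self.rul_histogram, key=lambda b: (self.rul_histogram[b], -b))

    def to_rows(self) -> list[tuple[str, object]]:
        rows = [
            ("n_families", self.n_families),
            ("total_percent", round(self.total_percent, 4)),
            (f"top_{self.top_k}_percent", round(self.top_k_percent, 4)),
            ("mean_divergence", round(self.mean_divergence, 4)),
            ("min_divergence", self.min_divergence),
            ("min_divergence_family", self.min_divergence_family),
            ("max_divergence", self.max_divergence),
            ("max_divergence_family", self.max_divergence_family),
            ("min_abundance", self.min_abundance),
            ("min_abundance_family", self.min_abundance_family),
            ("min_rul", self.min_rul),
            ("min_rul_family", self.min_rul_family),
            ("max_rul", self.max_rul),
            ("max_rul_family", self.max_rul_family),
        ]
        for left in sorted(self.rul_histogram):
            rows.append((f"rul_bin_{left}_{left + RUL_BIN_BP - 1}",
                         self.rul_histogram[left]))
        return rows


def summarize(families: Sequence[SatDNAFamily], k: int = 3) -> SatellitomeSummary:
    """Aggregate a satellitome catalogue into summary statistics.

    ``k`` selects how many of the most abundant families the ``top_k``
    fraction covers.  Divergence extremes are taken over non-telomeric
    families (see module docstring); all other statistics cover the full
    catalogue.
    """
    if not families:
        raise ValueError("cannot summarize an empty satellitome")
    with_div = [f for f in families if f.divergence_percent is not None]
    if not with_div:
        raise ValueError("no family carries a divergence value")
    ranked = sorted(families, key=lambda f: -f.abundance_percent)
    proper = [f for f in with_div if not f.is_telomeric] or with_div
    min_div = min(proper, key=lambda f: f.divergence_percent)
    max_div = max(proper, key=lambda f: f.divergence_percent)
    min_ab = min(families, key=lambda f: f.abundance_percent)
    min_rul = min(families, key=lambda f: f.rul)
    max_rul = max(families, key=lambda f: f.rul)
    hist: dict[int, int] = {}
    for f in families:
        left = ((f.rul - 1) // RUL_BIN_BP) * RUL_BIN_BP + 1
        hist[left] = hist.get(left, 0) + 1
    return SatellitomeSummary(
        n_families=len(families),
        total_percent=sum(f.abundance_percent for f in families),
        top_k=k,
        top_k_percent=sum(f.abundance_percent for f in ranked[:k]),
        min_divergence=min_div.divergence_percent,
        min_divergence_family=min_div.name,
        max_divergence=max_div.divergence_percent,
        max_divergence_family=max_div.name,
        mean_divergence=(
            sum(f.divergence_percent for f in with_div) / len(with_div)
        ),
        min_abundance=min_ab.abundance_percent,
        min_abundance_family=min_ab.name,
        min_rul=min_rul.rul,
        min_rul_family=min_rul.name,
        max_rul=max_rul.rul,
        max_rul_family=max_rul.name,
        rul_histogram=hist,
    )


def rank_and_name(
    families: Sequence[SatDNAFamily],
    genus: str,
    species: str,
    masking: Sequence[MaskingResult] | None = None,
) -> list[SatDNAFamily]:
    """Re-rank families by descending abundance and regenerate their names.

    Ties are broken by descending masked bp (when masking results are
    given) and then by input order, so the ranking is deterministic.
    """
    masked = {}
    if masking is not None:
        masked = {r.family_id: r.masked_bp for r in masking}
    order = sorted(
        range(len(families)),
        key=lambda i: (
            -families[i].abundance_percent,
            -masked.get(families[i].name, 0),
            i,
        ),
    )
    renamed = []
    for rank, i in enumerate(order, start=1):
        f = families[i]
        renamed.append(
            SatDNAFamily(
                name=name_family(genus, species, rank, f.rul),
                rank=rank,
                rul=f.rul,
                monomer=f.monomer,
                genus=genus,
                species=species,
                at_percent=f.at_percent,
                abundance_percent=f.abundance_percent,
                divergence_percent=f.divergence_percent,
            )
        )
    assert len({f.name for f in renamed}) == len(renamed)
    return renamed


def load_table_fixture(path: str | Path) -> list[SatDNAFamily]:
    """Load a satellitome summary table (TSV) into family records.

    Expected header: ``family  genome_percent  divergence_k2p  rul_bp
    at_percent``.  Rows carry no monomer sequence; rank is the row order
    (tables are printed in abundance order).  Malformed rows raise
    ``ValueError`` with the offending row number.
    """
    families: list[SatDNAFamily] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _FIXTURE_COLUMNS:
            raise ValueError(
                f"{path}: bad header {header!r}, expected {_FIXTURE_COLUMNS}"
            )
        for rowno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(
                    f"{path}: row {rowno}: expected 5 columns, got {len(fields)}"
                )
            name, ab, div, rul, at = fields
            if not FAMILY_NAME_RE.match(name):
                raise ValueError(
                    f"{path}: row {rowno}: bad family name {name!r}"
                )
            try:
                families.append(
                    SatDNAFamily(
                        name=name,
                        rank=len(families) + 1,
                        rul=int(rul),
                        abundance_percent=float(ab),
                        divergence_percent=float(div),
                        at_percent=float(at),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {rowno}: {exc}") from exc
    if not families:
        raise ValueError(f"{path}: no data rows")
    return families


def packaged_table_path() -> Path:
    """Path of the packaged Chrysolina americana satellitome table."""
    return Path(
        importlib.resources.files("satmapper").joinpath("data/table2.tsv")
    )


def write_summary_tsv(summary: SatellitomeSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("statistic\tvalue\n")
        for key, value in summary.to_rows():
            fh.write(f"{key}\t{value}\n")
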