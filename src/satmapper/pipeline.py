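"""End-to-end orchestration: annotate -> quantify -> summarize -> plot.

``run_pipeline`` takes a configuration mapping (mirroring the CLI flags),
executes every stage, writes all artifacts under an output directory and
returns their paths.  A structured JSON log records the package version,
parameters and seed, so a run is reproducible from its log alone.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .annotator import annotate_assembly, write_gff3
from .model import Assembly, read_consensus_library
from .quantify import mask_and_quantify, repeat_landscape
from .simulate import read_fastx
from .summary import summarize, write_summary_tsv
from .viz import MapFigureSpec, plot_chromosome_maps, plot_repeat_landscape

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

_REQUIRED_KEYS = ("assembly", "library", "reads", "out_dir")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: Mapping[str, Any]) -> dict[str, Path]:
    """Run annotate -> quantify -> landscape -> summarize -> plot.

    Required config keys: ``assembly`` (FASTA), ``library`` (consensus
    FASTA), ``reads`` (FASTA/FASTQ), ``out_dir``.  Optional: ``min_identity``
    (default 70), ``max_gap_factor`` (1.0), ``top_k`` (5), ``bin_width``
    (1.0), ``seed``, ``genus``, ``species``.
    """
    missing = [k for k in _REQUIRED_KEYS if k not in config]
    if missing:
        raise PipelineError(f"missing config key(s): {', '.join(missing)}")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    min_identity = float(config.get("min_identity", 70.0))
    max_gap_factor = float(config.get("max_gap_factor", 1.0))
    top_k = int(config.get("top_k", 5))
    bin_width = float(config.get("bin_width", 1.0))

    assembly = _stage("load-assembly")(Assembly.from_fasta)(config["assembly"])
    families = _stage("load-library")(read_consensus_library)(
        config["library"],
        genus=config.get("genus", ""),
        species=config.get("species", ""),
    )
    reads = _stage("load-reads")(read_fastx)(config["reads"])

    logger.info("annotating %d families on %d chromosomes",
                len(families), len(assembly.chromosomes))
    annotations = _stage("annotate")(annotate_assembly)(
        families, assembly, min_identity, max_gap_factor
    )
    gff_path = out_dir / "annotation.gff3"
    all_arrays = [a for fam in families for a in annotations[fam.name]]
    all_arrays.sort(key=lambda a: (a.chrom, a.start, a.end, a.family_id))
    _stage("write-gff3")(write_gff3)(all_arrays, gff_path)

    logger.info("masking %d reads", len(reads))
    results = _stage("quantify")(mask_and_quantify)(
        reads, families, min_identity
    )
    quant_path = out_dir / "quantification.tsv"
    with open(quant_path, "w") as fh:
        fh.write("family\tmasked_bp\tgenome_percent\tdivergence_k2p\n")
        for res in results:
            div = res.divergence_percent
            fh.write(
                f"{res.family_id}\t{res.masked_bp}\t"
                f"{res.abundance_percent:.4f}\t"
                f"{'NA' if div is None else f'{div:.2f}'}\n"
            )

    landscape = _stage("landscape")(repeat_landscape)(results, bin_width)
    landscape_path = out_dir / "landscape.tsv"
    landscape.to_csv(landscape_path, sep="\t", float_format="%.6f")

    for fam, res in zip(families, results):
        fam.abundance_percent = res.abundance_percent
        if res.divergence_percent is not None:
            fam.divergence_percent = res.divergence_percent
    summary = _stage("summarize")(summarize)(families, k=min(3, len(families)))
    summary_path = out_dir / "summary.tsv"
    write_summary_tsv(summary, summary_path)

    fig_path = out_dir / "chromosome_maps.svg"
    _stage("plot")(plot_chromosome_maps)(
        annotations,
        MapFigureSpec(chrom_lengths=assembly.lengths, top_k=top_k),
        fig_path,
    )
    landscape_fig = out_dir / "landscape.svg"
    _stage("plot")(plot_repeat_landscape)(landscape, landscape_fig)

    log_path = out_dir / "run_log.json"
    log = {
        "satmapper_version": __version__,
        "python": platform.python_version(),
        "parameters": {
            "min_identity": min_identity,
            "max_gap_factor": max_gap_factor,
            "top_k": top_k,
            "bin_width": bin_width,
            "seed": config.get("seed"),
        },
        "inputs": {
            "assembly": str(config["assembly"]),
            "library": str(config["library"]),
            "reads": str(config["reads"]),
        },
        "n_families": len(families),
        "n_chromosomes": len(assembly.chromosomes),
        "n_reads": len(reads),
    }
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return {
        "gff3": gff_path,
        "quantification": quant_path,
        "landscape": landscape_path,
        "summary": summary_path,
        "chromosome_maps": fig_path,
        "landscape_figure": landscape_fig,
        "log": log_path,
    }
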