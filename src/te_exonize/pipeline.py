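"""Workflow orchestration: configuration, manifests and the end-to-end
exonization and polyadenylation analyses.

Workflows compose the library modules over files in the formats the
package reads (GTF, BED6, TSV count tables, read-end TSV) and write
their tables plus a machine-readable run manifest (tool version, seed,
thresholds, output digests) so a rerun on identical inputs is
verifiably bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import read_annotation
from .apa import (
    assign_regions_to_genes,
    collapse_read_ends,
    count_ends,
    differential_polya,
    read_ends_tsv,
)
from .diffstats import Design
from .fragmentation import ClassifyThresholds, run_fragmentation_pipeline
from .intervals import GenomicInterval
from .peaks import read_peaks_bed, write_peaks_bed, assign_host_genes, intronic_peaks

__all__ = ["PipelineConfig", "run_exonization_workflow", "run_apa_workflow"]


@dataclass
class PipelineConfig:
    """Paths and thresholds of the end-to-end workflows.

    Threshold defaults are the published operating points: minimum
    junction/gene support 10 reads, peak classification at padj < 0.05
    with usage change > 2 (control band +/- 0.5), polyA collapse pad 50
    nt with 20-read support and a 20-percentage-point shift, stringent
    panel splicing index 1% with 500-read ubiquitous support, and a 500
    nt splice-site survey window.
    """

    gtf: str = ""
    repeats: str = ""
    peaks_bed: str = ""
    exon_counts: str = ""
    peak_counts: str = ""
    design: str = ""
    read_ends: str = ""
    out_dir: str = "results"
    seed: int = 0
    min_total_reads: int = 10
    peak_padj: float = 0.05
    peak_lfc: float = 2.0
    control_band: float = 0.5
    apa_pad: int = 50
    apa_min_reads: int = 20
    apa_min_shift: float = 0.20
    panel_si: float = 0.01
    panel_reads: int = 500
    survey_window: int = 500

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # output location must not change the science
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(out: Path, config: PipelineConfig, outputs: list[Path]) -> Path:
    manifest = {
        "tool": "te-exonize",
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "outputs": {p.name: _file_digest(p) for p in sorted(outputs)},
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _header(config: PipelineConfig) -> str:
    return f"# te-exonize {__version__} seed={config.seed} config={config.digest()}\n"


def _require(path: str, what: str) -> Path:
    if not path or not Path(path).exists():
        raise FileNotFoundError(f"missing {what}: {path!r}")
    return Path(path)


def run_exonization_workflow(config: PipelineConfig) -> dict:
    """Merged/intronic peaks -> usage scan -> fragmentation -> labels.

    Reads the annotation, the merged peak BED, the exon and peak count
    tables and the design; writes intronic peaks, the per-gene
    classification table and a manifest.  Returns a summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gtf = _require(config.gtf, "gene annotation (GTF)")
    peaks_path = _require(config.peaks_bed, "merged peak BED")
    exon_path = _require(config.exon_counts, "exon count table")
    peak_count_path = _require(config.peak_counts, "peak count table")
    design_path = _require(config.design, "design table")

    genome = read_annotation(gtf, config.repeats or None)
    peaks = read_peaks_bed(peaks_path)
    design = Design.from_frame(pd.read_csv(design_path, sep="\t", comment="#"))

    assigned = assign_host_genes(peaks, genome.genes)
    intronic = intronic_peaks(assigned, genome.genes)
    outputs = []
    intronic_bed = out / "intronic_peaks.bed"
    write_peaks_bed(intronic, intronic_bed)
    outputs.append(intronic_bed)

    exon_counts = pd.read_csv(exon_path, sep="\t", index_col=0, comment="#")
    peak_counts = pd.read_csv(peak_count_path, sep="\t", index_col=0, comment="#")

    exon_hosts = {fid: fid.split(":")[0] for fid in exon_counts.index}
    exon_intervals = {}
    for gene in genome.genes.values():
        for k, exon in enumerate(gene.exons):
            exon_intervals[f"{gene.gene_id}:exon{k}"] = exon

    thresholds = ClassifyThresholds(
        padj_max=config.peak_padj,
        up_lfc_min=config.peak_lfc,
        control_band=config.control_band,
    )
    table = run_fragmentation_pipeline(
        genome.genes,
        intronic,
        exon_counts,
        peak_counts,
        exon_hosts,
        exon_intervals,
        design,
        thresholds,
    )
    class_path = out / "gene_classification.tsv"
    with open(class_path, "w") as fh:
        fh.write(_header(config))
        table.to_csv(fh, sep="\t")
    outputs.append(class_path)

    manifest = _write_manifest(out, config, outputs)
    labels = table["label"].value_counts().to_dict() if len(table) else {}
    return {
        "n_peaks": len(peaks),
        "n_intronic": len(intronic),
        "n_genes_classified": int(len(table)),
        "labels": {str(k): int(v) for k, v in labels.items()},
        "manifest": str(manifest),
    }


def run_apa_workflow(config: PipelineConfig) -> dict:
    """Read-end collapse -> per-gene fractions -> differential polyA calls."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gtf = _require(config.gtf, "gene annotation (GTF)")
    ends_path = _require(config.read_ends, "read-end table")
    design_path = _require(config.design, "design table")

    genome = read_annotation(gtf)
    ends = read_ends_tsv(ends_path)
    design = Design.from_frame(pd.read_csv(design_path, sep="\t", comment="#"))

    regions = collapse_read_ends(ends, pad=config.apa_pad)
    count_ends(regions, ends, design.condition)
    assign_regions_to_genes(regions, genome.genes)
    calls = differential_polya(
        regions, min_reads=config.apa_min_reads, min_shift=config.apa_min_shift
    )

    outputs = []
    regions_bed = out / "polya_regions.bed"
    with open(regions_bed, "w") as fh:
        for r in regions:
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.host_gene or '.'}\t0\t{iv.strand}\n"
            )
    outputs.append(regions_bed)
    calls_path = out / "polya_calls.tsv"
    with open(calls_path, "w") as fh:
        fh.write(_header(config))
        calls.to_csv(fh, sep="\t")
    outputs.append(calls_path)

    manifest = _write_manifest(out, config, outputs)
    return {
        "n_regions": len(regions),
        "n_genes": int(len(calls)),
        "n_called": int(calls["called"].sum()) if len(calls) else 0,
        "manifest": str(manifest),
    }
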