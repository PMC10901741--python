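"""Exonization / early-termination detection via gene fragmentation.

The workflow: RNA-seq reads are counted on annotated exons and on
intronic RBP peaks; each peak is tested for differential usage within
its host gene (knockdown vs. control).  Per gene, the peak with the
lowest raw p-value becomes the *reference peak*; exons strictly 5' of it
(in transcription direction) form the *pre* fragment and exons strictly
3' the *post* fragment.  Aggregated pre/post counts are tested for
differential expression: a gene whose intronic peak gains usage while
its downstream exons drop is the signature of exonization with premature
termination (the peak acts as a gene trap).

Classification thresholds (padj < 0.05 and log2 usage change > 2 for
"upregulated"; padj > 0.05 and change in (-0.5, 0.5) for "control") are
the defaults of :class:`ClassifyThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffstats import Design, moderated_count_test, relative_usage_test
from .intervals import Gene, GenomicInterval
from .peaks import Peak

__all__ = [
    "GeneFragmentation",
    "PeakClassification",
    "ClassifyThresholds",
    "peak_usage_scan",
    "select_reference_peak",
    "fragment_gene_at_peak",
    "prepost_differential",
    "classify_genes",
    "run_fragmentation_pipeline",
]


@dataclass
class GeneFragmentation:
    """A gene split into exon sets up- and downstream of its reference peak."""

    gene_id: str
    reference_peak: Peak
    pre_exons: list[GenomicInterval]
    post_exons: list[GenomicInterval]

    @property
    def empty_post(self) -> bool:
        return not self.post_exons

    @property
    def empty_pre(self) -> bool:
        return not self.pre_exons


@dataclass
class ClassifyThresholds:
    """Classification bands for reference-peak usage results."""

    padj_max: float = 0.05
    up_lfc_min: float = 2.0
    control_band: float = 0.5


@dataclass
class PeakClassification:
    gene_id: str
    label: str  # upregulated | control | other
    peak_padj: float
    peak_log2fc: float
    pre_log2fc: float = float("nan")
    post_log2fc: float = float("nan")


def peak_usage_scan(
    exon_counts: pd.DataFrame,
    peak_counts: pd.DataFrame,
    peak_hosts: Mapping[str, str],
    exon_hosts: Mapping[str, str],
    design: Design,
) -> pd.DataFrame:
    """Differential usage of every intronic peak within its host gene.

    ``exon_counts`` and ``peak_counts`` are feature x sample tables;
    ``*_hosts`` map feature ids to gene ids.  The group total of a peak is
    the summed exon + intronic-peak counts of its gene (the full counting
    reference, as when exons and peaks are quantified together).  Peaks
    without a host gene are skipped with a warning column rather than an
    error.

    Returns the relative-usage result table indexed by peak id, with a
    ``gene_id`` column.
    """
    samples = list(design.samples)
    gene_totals: dict[str, np.ndarray] = {}
    for table, hosts in ((exon_counts, exon_hosts), (peak_counts, peak_hosts)):
        mat = table[samples].to_numpy(dtype=float)
        for i, fid in enumerate(table.index):
            g = hosts.get(fid)
            if g is None:
                continue
            if g in gene_totals:
                gene_totals[g] = gene_totals[g] + mat[i]
            else:
                gene_totals[g] = mat[i].copy()

    rows = []
    index = []
    genes = []
    pk = peak_counts[samples].to_numpy(dtype=float)
    for i, pid in enumerate(peak_counts.index):
        g = peak_hosts.get(pid)
        if g is None or g not in gene_totals:
            continue
        rows.append((pk[i], gene_totals[g]))
        index.append(pid)
        genes.append(g)
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "base_mean", "share_control", "share_treatment",
                     "log2fc", "se", "p", "padj"]
        )
    fmat = pd.DataFrame([r[0] for r in rows], index=index, columns=samples)
    gmat = pd.DataFrame([r[1] for r in rows], index=index, columns=samples)
    res = relative_usage_test(fmat, gmat, design)
    res.insert(0, "gene_id", genes)
    return res


def select_reference_peak(
    gene_id: str,
    peak_results: pd.DataFrame,
    peaks_by_id: Mapping[str, Peak],
) -> Peak | None:
    """The gene's peak with minimal raw p; ties go to the leftmost peak.

    Returns None when the gene has no tested peak (gene excluded).
    """
    sub = peak_results[peak_results["gene_id"] == gene_id].dropna(subset=["p"])
    if sub.empty:
        return None
    candidates = sorted(
        sub.index,
        key=lambda pid: (
            sub.at[pid, "p"],
            peaks_by_id[pid].interval.start,
            pid,
        ),
    )
    return peaks_by_id[candidates[0]]


def fragment_gene_at_peak(gene: Gene, reference_peak: Peak) -> GeneFragmentation:
    """Split a gene's exons into pre- and post-peak sets.

    Pre = exons wholly 5' of the peak in transcription direction, post =
    exons wholly 3'; on the minus strand 5'/3' are genomically reversed.
    Exons overlapping the peak span belong to neither (their reads were
    masked during counting).  A peak outside the gene footprint is an
    error; a peak in the first/last intron legitimately leaves pre/post
    empty.
    """
    iv = reference_peak.interval
    from .intervals import flatten_gene

    fp = flatten_gene(gene)
    if iv.chrom != gene.chrom or iv.start < fp.start or iv.end > fp.end:
        raise ValueError(
            f"reference peak {iv} outside gene {gene.gene_id} footprint {fp}"
        )
    upstream = [e for e in gene.exons if e.end <= iv.start]
    downstream = [e for e in gene.exons if e.start >= iv.end]
    if gene.strand == "-":
        pre, post = downstream, upstream
    else:
        pre, post = upstream, downstream
    return GeneFragmentation(gene.gene_id, reference_peak, pre, post)


def prepost_differential(
    fragmentations: Sequence[GeneFragmentation],
    exon_counts: pd.DataFrame,
    exon_intervals: Mapping[str, GenomicInterval],
    exon_hosts: Mapping[str, str],
    design: Design,
) -> pd.DataFrame:
    """Aggregate exon counts per pre/post fragment and test each side.

    Counts of member exons are summed per sample; both aggregate tables
    are tested with the moderated count test (no fold-change threshold).
    Genes with an empty pre or post side get NaN on that side.

    Returns a gene-indexed frame with ``pre_log2fc, pre_p, pre_padj,
    post_log2fc, post_p, post_padj``.
    """
    samples = list(design.samples)
    mat = exon_counts[samples].to_numpy(dtype=float)
    exon_pos = {fid: i for i, fid in enumerate(exon_counts.index)}

    def member_ids(gene_id: str, wanted: list[GenomicInterval]) -> list[str]:
        keys = {(w.chrom, w.start, w.end) for w in wanted}
        out = []
        for fid, host in exon_hosts.items():
            if host != gene_id or fid not in exon_pos:
                continue
            iv = exon_intervals.get(fid)
            if iv is not None and (iv.chrom, iv.start, iv.end) in keys:
                out.append(fid)
        return out

    agg_rows = {}
    sides = {}
    for frag in fragmentations:
        for side, exons in (("pre", frag.pre_exons), ("post", frag.post_exons)):
            ids = member_ids(frag.gene_id, exons)
            if not ids:
                continue
            total = mat[[exon_pos[i] for i in ids]].sum(axis=0)
            key = f"{frag.gene_id}__{side}"
            agg_rows[key] = total
            sides[key] = (frag.gene_id, side)

    out = pd.DataFrame(
        index=[f.gene_id for f in fragmentations],
        columns=["pre_log2fc", "pre_p", "pre_padj", "post_log2fc", "post_p", "post_padj"],
        dtype=float,
    )
    if not agg_rows:
        return out
    agg = pd.DataFrame.from_dict(agg_rows, orient="index", columns=samples)
    res = moderated_count_test(agg, design, min_total=0)
    for key, row in res.iterrows():
        gene_id, side = sides[key]
        out.at[gene_id, f"{side}_log2fc"] = row["log2fc"]
        out.at[gene_id, f"{side}_p"] = row["p"]
        out.at[gene_id, f"{side}_padj"] = row["padj"]
    return out


def classify_genes(
    peak_results: pd.DataFrame,
    reference_peaks: Mapping[str, str],
    prepost: pd.DataFrame | None = None,
    thresholds: ClassifyThresholds | None = None,
) -> list[PeakClassification]:
    """Label genes by their reference peak's usage statistics.

    upregulated: padj < padj_max and log2fc > up_lfc_min;
    control: padj > padj_max and log2fc within +/- control_band;
    everything else (including filtered/NaN padj): other.
    """
    th = thresholds or ClassifyThresholds()
    out = []
    for gene_id, peak_id in reference_peaks.items():
        row = peak_results.loc[peak_id]
        padj = float(row["padj"])
        lfc = float(row["log2fc"])
        if np.isfinite(padj) and padj < th.padj_max and lfc > th.up_lfc_min:
            label = "upregulated"
        elif np.isfinite(padj) and padj > th.padj_max and -th.control_band < lfc < th.control_band:
            label = "control"
        else:
            label = "other"
        pre = post = float("nan")
        if prepost is not None and gene_id in prepost.index:
            pre = float(prepost.at[gene_id, "pre_log2fc"])
            post = float(prepost.at[gene_id, "post_log2fc"])
        out.append(PeakClassification(gene_id, label, padj, lfc, pre, post))
    return out


def run_fragmentation_pipeline(
    genes: Mapping[str, Gene],
    intronic: Sequence[Peak],
    exon_counts: pd.DataFrame,
    peak_counts: pd.DataFrame,
    exon_hosts: Mapping[str, str],
    exon_intervals: Mapping[str, GenomicInterval],
    design: Design,
    thresholds: ClassifyThresholds | None = None,
) -> pd.DataFrame:
    """End-to-end gene classification from counts and intronic peaks.

    Returns a per-gene table: reference peak coordinates, peak usage
    effect and padj, pre/post fold changes, and the classification label.
    """
    peaks_by_id = {p.peak_id: p for p in intronic}
    peak_hosts = {p.peak_id: p.host_gene for p in intronic}
    usage = peak_usage_scan(exon_counts, peak_counts, peak_hosts, exon_hosts, design)

    reference: dict[str, str] = {}
    fragmentations = []
    for gene_id in sorted(set(usage["gene_id"])):
        ref = select_reference_peak(gene_id, usage, peaks_by_id)
        if ref is None or gene_id not in genes:
            continue
        reference[gene_id] = ref.peak_id
        fragmentations.append(fragment_gene_at_peak(genes[gene_id], ref))

    prepost = prepost_differential(
        fragmentations, exon_counts, exon_intervals, exon_hosts, design
    )
    classes = classify_genes(usage, reference, prepost, thresholds)

    rows = []
    for c in classes:
        ref = peaks_by_id[reference[c.gene_id]]
        rows.append(
            {
                "gene_id": c.gene_id,
                "peak_chrom": ref.interval.chrom,
                "peak_start": ref.interval.start,
                "peak_end": ref.interval.end,
                "peak_log2fc": c.peak_log2fc,
                "peak_padj": c.peak_padj,
                "pre_log2fc": c.pre_log2fc,
                "post_log2fc": c.post_log2fc,
                "label": c.label,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["peak_chrom", "peak_start", "peak_end", "peak_log2fc",
                 "peak_padj", "pre_log2fc", "post_log2fc", "label"]
    )
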