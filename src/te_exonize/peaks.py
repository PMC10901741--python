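"""Merged RBP peak universes, host-gene assignment and intronic peaks.

Per-profile peak sets (e.g. SAFB1/SAFB2/SLTM CLIP-style profiles) are
merged strand-aware into a single peak universe; each merged peak keeps
the set of profiles that contributed to it.  Peaks fully contained in a
gene footprint on the same strand are *within-gene*; after masking all
annotated exons the surviving sub-peaks are *intronic* — the candidate
set for exonization and early-termination analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    Gene,
    GenomicInterval,
    Strand,
    flatten_gene,
    reduce_intervals,
    subtract_intervals,
)

__all__ = [
    "Peak",
    "PeakCountMatrix",
    "merge_peak_sets",
    "assign_host_genes",
    "intronic_peaks",
    "build_peak_count_matrix",
]


@dataclass
class Peak:
    """An RBP-bound interval with provenance."""

    interval: GenomicInterval
    sources: frozenset[str]
    host_gene: str | None = None
    intronic: bool = False
    ambiguous_host: bool = False

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("peak must have at least one source profile")
        if self.intronic and self.host_gene is None:
            raise ValueError("intronic peak must have a host gene")

    @property
    def peak_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


@dataclass
class PeakCountMatrix:
    """Non-negative integer peak x profile count matrix."""

    peaks: list[Peak]
    profiles: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peaks), len(self.profiles)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.peaks)} peaks x {len(self.profiles)} profiles"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts in peak count matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[p.peak_id for p in self.peaks],
            columns=self.profiles,
        )


def merge_peak_sets(
    peak_sets: Mapping[str, Sequence[GenomicInterval]]
) -> list[Peak]:
    """Merge per-profile peak intervals into a unified, strand-aware universe.

    Overlapping or touching intervals on the same chromosome and strand are
    merged; the merged peak's ``sources`` is the union of profiles whose
    intervals contributed bases to it.  Unstranded input peaks are rejected.
    """
    for profile, ivs in peak_sets.items():
        for iv in ivs:
            if iv.strand == Strand.UNSTRANDED:
                raise ValueError(f"profile {profile}: unstranded peak {iv}")
    merged = reduce_intervals(
        [iv for ivs in peak_sets.values() for iv in ivs], strand_aware=True
    )
    peaks = []
    for iv in merged:
        sources = frozenset(
            profile
            for profile, ivs in peak_sets.items()
            if any(iv.overlaps(p) and iv.strand == p.strand for p in ivs)
        )
        peaks.append(Peak(iv, sources))
    return peaks


def assign_host_genes(
    peaks: Sequence[Peak],
    genes: Mapping[str, Gene] | Sequence[Gene],
    mode: str = "contained",
) -> list[Peak]:
    """Assign each peak to a host gene footprint on the same strand.

    ``mode="contained"`` (default) requires full containment of the peak in
    the gene footprint — the strict reading of "located inside";
    ``mode="overlap"`` accepts any overlap.  A peak eligible for several
    genes goes to the one with the longest overlap, ties to the
    lexicographically smallest gene_id, and is flagged ``ambiguous_host``.
    """
    if mode not in ("contained", "overlap"):
        raise ValueError(f"unknown assignment mode {mode!r}")
    gene_list = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    footprints = sorted(
        ((flatten_gene(g), g.gene_id) for g in gene_list),
        key=lambda t: (t[0].chrom, t[0].start),
    )
    out: list[Peak] = []
    for peak in peaks:
        iv = peak.interval
        candidates: list[tuple[int, str]] = []  # (-overlap, gene_id)
        for fp, gene_id in footprints:
            if fp.chrom != iv.chrom or fp.strand != iv.strand:
                continue
            if mode == "contained":
                if fp.contains(iv):
                    candidates.append((-iv.length, gene_id))
            else:
                ov = min(fp.end, iv.end) - max(fp.start, iv.start)
                if ov > 0:
                    candidates.append((-ov, gene_id))
        if candidates:
            candidates.sort()
            out.append(
                replace(
                    peak,
                    host_gene=candidates[0][1],
                    ambiguous_host=len({g for _, g in candidates}) > 1,
                )
            )
        else:
            out.append(replace(peak, host_gene=None, ambiguous_host=False))
    return out


def intronic_peaks(
    peaks: Sequence[Peak],
    genes: Mapping[str, Gene] | Sequence[Gene],
    min_length: int = 1,
    strand_aware_mask: bool = True,
) -> list[Peak]:
    """Mask exon-overlapping peak portions; keep the intronic remainders.

    Any annotated exon (of any gene, on the peak's strand when
    ``strand_aware_mask``) masks its bases out of every within-gene peak.
    Surviving sub-peaks of length >= ``min_length`` are returned flagged
    intronic, inheriting sources and host gene; a peak fully covered by
    exons disappears.
    """
    gene_list = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    exons_by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for g in gene_list:
        for e in g.exons:
            exons_by_key.setdefault((e.chrom, e.strand), []).append(e)
            exons_by_key.setdefault((e.chrom, "*"), []).append(e)
    out: list[Peak] = []
    for peak in peaks:
        if peak.host_gene is None:
            continue
        iv = peak.interval
        key = (iv.chrom, iv.strand) if strand_aware_mask else (iv.chrom, "*")
        mask = exons_by_key.get(key, [])
        for sub in subtract_intervals([iv], mask):
            if sub.length >= min_length:
                out.append(
                    Peak(
                        sub,
                        peak.sources,
                        host_gene=peak.host_gene,
                        intronic=True,
                        ambiguous_host=peak.ambiguous_host,
                    )
                )
    return out


def build_peak_count_matrix(
    merged_peaks: Sequence[Peak],
    per_profile_counts: Mapping[str, Mapping[str, int]],
) -> PeakCountMatrix:
    """Assemble the unified peak x profile count matrix.

    ``per_profile_counts`` maps profile -> {peak_id: count}; a profile
    missing a peak contributes 0 in that cell.  Peak order follows
    ``merged_peaks``; profile order is the sorted profile names.
    """
    profiles = sorted(per_profile_counts)
    counts = np.zeros((len(merged_peaks), len(profiles)), dtype=np.int64)
    for j, profile in enumerate(profiles):
        table = per_profile_counts[profile]
        for i, peak in enumerate(merged_peaks):
            c = int(table.get(peak.peak_id, 0))
            if c < 0:
                raise ValueError(
                    f"negative count for peak {peak.peak_id} in profile {profile}"
                )
            counts[i, j] = c
    return PeakCountMatrix(list(merged_peaks), profiles, counts)


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """BED6 writer; the name field carries sources (and host gene if set)."""
    with open(path, "w") as fh:
        for peak in peaks:
            iv = peak.interval
            name = ",".join(sorted(peak.sources))
            if peak.host_gene:
                name += f"|{peak.host_gene}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_peaks_bed(path: str | Path) -> list[Peak]:
    from .annotation import read_bed6

    peaks = []
    for iv, name in read_bed6(path):
        if "|" in name:
            src, host = name.split("|", 1)
        else:
            src, host = name, None
        peaks.append(Peak(iv, frozenset(src.split(",")), host_gene=host))
    return peaks
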