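"""Alternative polyadenylation from long-read 3' end coordinates.

Single-base read-end positions (e.g. from direct RNA long reads, whose
3' ends fall near the cleavage/polyadenylation site) are padded by
+/- ``pad`` nt and collapsed into disjoint putative polyadenylation
regions per chromosome and strand.  Per gene, the fraction of reads
ending in each region is compared between conditions; a gene whose
isoform contributions shift by at least ``min_shift`` (default 20
percentage points) at sufficient read support (default 20 reads) is
called differentially polyadenylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import Gene, GenomicInterval, flatten_gene, reduce_intervals

__all__ = [
    "ReadEnd",
    "PolyARegion",
    "collapse_read_ends",
    "count_ends",
    "differential_polya",
]


@dataclass(frozen=True)
class ReadEnd:
    """A single-base 3' read-end coordinate from one sample."""

    chrom: str
    pos: int
    strand: str
    sample: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("read end position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("read ends must be stranded")


@dataclass
class PolyARegion:
    """A collapsed putative polyadenylation region with per-condition counts."""

    interval: GenomicInterval
    host_gene: str | None = None
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def region_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


def collapse_read_ends(read_ends: Sequence[ReadEnd], pad: int = 50) -> list[PolyARegion]:
    """Pad each end by +/- ``pad`` nt and merge overlapping intervals.

    Collapse is strand-aware (ends on opposite strands never merge) and
    clips at position 0.  Every input end lies inside exactly one output
    region; the output is independent of input order and idempotent
    under re-collapse.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    ivs = [
        GenomicInterval(e.chrom, max(e.pos - pad, 0), e.pos + pad + 1, e.strand)
        for e in read_ends
    ]
    return [PolyARegion(iv) for iv in reduce_intervals(ivs, strand_aware=True)]


def count_ends(
    regions: Sequence[PolyARegion],
    read_ends: Sequence[ReadEnd],
    condition: Mapping[str, str],
) -> list[PolyARegion]:
    """Count reads ending inside each region, per condition.

    ``condition`` maps sample -> condition label.  Counting conserves
    reads exactly: every end must fall inside some region (guaranteed
    when the regions come from :func:`collapse_read_ends` on the same
    ends); an orphan end raises an internal-consistency error.
    """
    by_key: dict[tuple[str, str], list[PolyARegion]] = {}
    for r in regions:
        r.counts = {}
        by_key.setdefault((r.interval.chrom, r.interval.strand), []).append(r)
    ends_by_key: dict[tuple[str, str], list[ReadEnd]] = {}
    for e in read_ends:
        ends_by_key.setdefault((e.chrom, e.strand), []).append(e)
    for key, es in ends_by_key.items():
        rs = by_key.get(key)
        if not rs:
            raise RuntimeError(
                f"internal consistency error: read ends on {key} outside all regions"
            )
        rs.sort(key=lambda r: r.interval.start)
        starts = np.array([r.interval.start for r in rs])
        stops = np.array([r.interval.end for r in rs])
        pos = np.array([e.pos for e in es])
        idx = np.searchsorted(starts, pos, side="right") - 1
        bad = (idx < 0) | (pos >= stops[np.clip(idx, 0, None)])
        if bad.any():
            raise RuntimeError(
                f"internal consistency error: read end {es[int(np.argmax(bad))]} "
                "outside all regions"
            )
        for e, i in zip(es, idx):
            cond = condition[e.sample]
            counts = rs[int(i)].counts
            counts[cond] = counts.get(cond, 0) + 1
    return list(regions)


def assign_regions_to_genes(
    regions: Sequence[PolyARegion], genes: Mapping[str, Gene] | Sequence[Gene]
) -> list[PolyARegion]:
    """Assign each region to the gene footprint containing its midpoint
    on the same strand; unassignable regions keep ``host_gene=None``."""
    gene_list = list(genes.values()) if isinstance(genes, Mapping) else list(genes)
    footprints = sorted(
        ((flatten_gene(g), g.gene_id) for g in gene_list),
        key=lambda t: (t[0].chrom, t[0].start, t[1]),
    )
    for r in regions:
        mid = (r.interval.start + r.interval.end) // 2
        r.host_gene = None
        for fp, gid in footprints:
            if (
                fp.chrom == r.interval.chrom
                and fp.strand == r.interval.strand
                and fp.contains_pos(mid)
            ):
                r.host_gene = gid
                break
    return list(regions)


def differential_polya(
    regions: Sequence[PolyARegion],
    min_reads: int = 20,
    min_shift: float = 0.20,
    conditions: tuple[str, str] = ("control", "treatment"),
) -> pd.DataFrame:
    """Per-gene differential polyA-site usage call.

    For each gene (regions must carry ``host_gene``; unassigned regions
    are dropped) and condition, fraction(region) = reads ending in the
    region / reads ending in the gene.  A gene is *called* iff its total
    reads (both conditions summed) >= ``min_reads`` AND the largest
    absolute per-region fraction shift between conditions >=
    ``min_shift`` — both thresholds inclusive ("at least" semantics).
    Genes with zero reads in one condition have undefined fractions on
    that side and are reported as not callable with a reason.

    Returns a gene-indexed frame: n_reads, n_regions, max_shift, called,
    reason.
    """
    ctrl, trt = conditions
    by_gene: dict[str, list[PolyARegion]] = {}
    for r in regions:
        if r.host_gene is not None:
            by_gene.setdefault(r.host_gene, []).append(r)

    rows = []
    for gene_id in sorted(by_gene):
        rs = by_gene[gene_id]
        n_c = sum(r.counts.get(ctrl, 0) for r in rs)
        n_t = sum(r.counts.get(trt, 0) for r in rs)
        total = n_c + n_t
        if n_c == 0 or n_t == 0:
            rows.append(
                {
                    "gene_id": gene_id,
                    "n_reads": total,
                    "n_regions": len(rs),
                    "max_shift": float("nan"),
                    "called": False,
                    "reason": "fractions undefined: no reads in one condition",
                }
            )
            continue
        shifts = [
            abs(r.counts.get(trt, 0) / n_t - r.counts.get(ctrl, 0) / n_c) for r in rs
        ]
        max_shift = max(shifts)
        called = total >= min_reads and max_shift >= min_shift - 1e-12
        reason = ""
        if total < min_reads:
            reason = f"fewer than {min_reads} reads"
        elif not called:
            reason = f"max shift {max_shift:.3f} below {min_shift}"
        rows.append(
            {
                "gene_id": gene_id,
                "n_reads": total,
                "n_regions": len(rs),
                "max_shift": max_shift,
                "called": called,
                "reason": reason,
            }
        )
    return (
        pd.DataFrame(rows).set_index("gene_id")
        if rows
        else pd.DataFrame(
            columns=["n_reads", "n_regions", "max_shift", "called", "reason"]
        )
    )


def read_ends_tsv(path: str | Path) -> list[ReadEnd]:
    """Read a (chrom, pos, strand, sample) TSV of 3' read ends."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    return [
        ReadEnd(str(r.chrom), int(r.pos), str(r.strand), str(r.sample))
        for r in frame.itertuples()
    ]


def write_ends_tsv(ends: Sequence[ReadEnd], path: str | Path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("chrom\tpos\tstrand\tsample\n")
        for e in ends:
            fh.write(f"{e.chrom}\t{e.pos}\t{e.strand}\t{e.sample}\n")
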