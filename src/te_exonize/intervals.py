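"""Genomic coordinate model and interval algebra.

All coordinates in this package are 0-based, half-open (BED convention):
``start`` is the first base of a feature and ``end`` is one past the last.
Input formats that use 1-based inclusive coordinates (GTF, repeatMasker
``.out``, ``SJ.out.tab``) are converted at the I/O boundary, never inside
the algebra.

The central operations are

* :func:`reduce_intervals` — merge overlapping/touching intervals
  (the classic ``reduce`` of interval libraries),
* :func:`subtract_intervals` — per-base set difference,
* :func:`fragment_by_priority` — split a gene footprint into disjoint
  labeled fragments where every base is attributed to the
  highest-priority feature covering it (exon > repeat > intron, etc.),
  the reference construction used for fragment-level read counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "Strand",
    "GenomicInterval",
    "Gene",
    "RepeatElement",
    "LabeledFragment",
    "reduce_intervals",
    "subtract_intervals",
    "intersect_length",
    "flatten_gene",
    "fragment_by_priority",
]


class Strand:
    """Strand constants: ``+``, ``-`` and ``.`` (unstranded)."""

    PLUS = "+"
    MINUS = "-"
    UNSTRANDED = "."

    VALID = frozenset({"+", "-", "."})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome.

    Raises ``ValueError`` on empty or inverted intervals: ``start < end``
    is a hard invariant, so downstream length arithmetic never sees
    zero-length features.
    """

    chrom: str
    start: int
    end: int
    strand: str = Strand.UNSTRANDED

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in Strand.VALID:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class Gene:
    """A gene as a flattened union of exons (no transcript model).

    ``exons`` must share the gene's chromosome and strand and be contained
    in ``interval``; they are stored reduced (disjoint, sorted).
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        for exon in self.exons:
            if exon.chrom != self.interval.chrom or exon.strand != self.interval.strand:
                raise ValueError(
                    f"gene {self.gene_id}: exon {exon} not on gene chrom/strand"
                )
            if not self.interval.contains(exon):
                raise ValueError(
                    f"gene {self.gene_id}: exon {exon} outside gene interval"
                )
        self.exons = reduce_intervals(self.exons, strand_aware=True)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class RepeatElement:
    """A repeatMasker-style repeat instance with family and class labels."""

    interval: GenomicInterval
    family: str
    class_name: str = ""

    def __post_init__(self) -> None:
        if not self.family:
            raise ValueError("repeat family must be non-empty")
        if self.interval.strand == Strand.UNSTRANDED:
            raise ValueError("repeat elements must be stranded")


# Fragment labels, in the package's canonical vocabulary.
FRAGMENT_LABELS = ("exon", "repeat", "peak", "intron")


@dataclass(frozen=True)
class LabeledFragment:
    """One disjoint piece of a priority-fragmented gene."""

    interval: GenomicInterval
    label: str
    source_id: str
    host_gene: str

    def __post_init__(self) -> None:
        if self.label not in FRAGMENT_LABELS:
            raise ValueError(f"unknown fragment label {self.label!r}")


def _merge_sorted(ivs: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge a chrom/strand-homogeneous, start-sorted interval list."""
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end)
        else:
            merged.append(iv)
    return merged


def reduce_intervals(
    intervals: Iterable[GenomicInterval], strand_aware: bool = True
) -> list[GenomicInterval]:
    """Merge overlapping and touching intervals.

    Touching intervals ([10,20) and [20,30)) are merged, matching
    reduce semantics with zero minimum gap.  With ``strand_aware`` the
    merge never crosses strands; without it, strand information collapses
    to unstranded whenever inputs disagree.

    Returns intervals sorted by (chrom, start), pairwise disjoint, whose
    union is exactly the union of input bases.
    """
    ivs = list(intervals)
    if not ivs:
        return []
    out: list[GenomicInterval] = []
    if strand_aware:
        keys = sorted({(iv.chrom, iv.strand) for iv in ivs})
        for chrom, strand in keys:
            group = sorted(
                (iv for iv in ivs if iv.chrom == chrom and iv.strand == strand),
                key=lambda iv: (iv.start, iv.end),
            )
            out.extend(_merge_sorted(group))
    else:
        for chrom in sorted({iv.chrom for iv in ivs}):
            group = sorted(
                (iv for iv in ivs if iv.chrom == chrom),
                key=lambda iv: (iv.start, iv.end),
            )
            strands = {iv.strand for iv in group}
            strand = strands.pop() if len(strands) == 1 else Strand.UNSTRANDED
            group = [replace(iv, strand=strand) for iv in group]
            out.extend(_merge_sorted(group))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end, iv.strand))
    return out


def subtract_intervals(
    intervals: Sequence[GenomicInterval], mask: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Per-base difference ``intervals \\ mask``.

    Strand is ignored on the mask side (a mask base removes the base on
    either strand); callers wanting strand-aware masking pre-filter the
    mask.  Output fragments inherit the strand of their source interval.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in reduce_intervals(mask, strand_aware=False):
        by_chrom.setdefault(m.chrom, []).append(m)
    out: list[GenomicInterval] = []
    for iv in intervals:
        cursor = iv.start
        for m in by_chrom.get(iv.chrom, ()):
            if m.end <= cursor or m.start >= iv.end:
                continue
            if m.start > cursor:
                out.append(replace(iv, start=cursor, end=m.start))
            cursor = max(cursor, m.end)
            if cursor >= iv.end:
                break
        if cursor < iv.end:
            out.append(replace(iv, start=cursor, end=iv.end))
    return out


def intersect_length(
    intervals: Sequence[GenomicInterval], other: Sequence[GenomicInterval]
) -> int:
    """Number of bases covered by both interval sets (strand ignored)."""
    a = reduce_intervals(intervals, strand_aware=False)
    b = reduce_intervals(other, strand_aware=False)
    total = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in a:
        for m in by_chrom.get(iv.chrom, ()):
            lo = max(iv.start, m.start)
            hi = min(iv.end, m.end)
            if lo < hi:
                total += hi - lo
    return total


def flatten_gene(gene: Gene) -> GenomicInterval:
    """Genomic footprint of a gene: (min exon start, max exon end).

    This is the search space for within-gene queries; the gene's stored
    interval may be wider (e.g. annotated UTR bounds) but the footprint
    is derived from exons alone.
    """
    start = min(e.start for e in gene.exons)
    end = max(e.end for e in gene.exons)
    return GenomicInterval(gene.chrom, start, end, gene.strand)


def fragment_by_priority(
    gene: Gene,
    repeats: Sequence[RepeatElement] = (),
    peaks: Sequence[GenomicInterval] = (),
    priority: Sequence[str] = ("exon", "repeat", "intron"),
) -> list[LabeledFragment]:
    """Split a gene footprint into disjoint labeled fragments.

    Every base of the footprint is labeled by the highest-priority feature
    covering it; uncovered bases are ``intron``.  Adjacent bases with the
    same label *and* source are merged into one fragment, so e.g. an exon
    partially shadowing a repeat yields the visible remainder of the
    repeat as a single fragment.

    ``priority`` is a total order, highest first; ``intron`` need not be
    listed (it is implicitly lowest).  Labels not in ``priority`` are
    rejected.
    """
    order = list(priority)
    if "intron" not in order:
        order.append("intron")
    for lab in order:
        if lab not in FRAGMENT_LABELS:
            raise ValueError(f"unknown label in priority: {lab!r}")
    rank = {lab: i for i, lab in enumerate(order)}
    if "repeat" not in rank:
        rank["repeat"] = len(rank) + 10
    if "peak" not in rank:
        rank["peak"] = len(rank) + 11

    footprint = flatten_gene(gene)

    # (rank, start, end, label, source_id); clipped to the footprint
    features: list[tuple[int, int, int, str, str]] = []
    if "exon" in order:
        for i, exon in enumerate(gene.exons):
            features.append(
                (rank["exon"], exon.start, exon.end, "exon", f"{gene.gene_id}:exon{i}")
            )
    for rep in repeats:
        if rep.interval.chrom != footprint.chrom:
            continue
        lo = max(rep.interval.start, footprint.start)
        hi = min(rep.interval.end, footprint.end)
        if lo < hi and "repeat" in order:
            features.append((rank["repeat"], lo, hi, "repeat", rep.family))
    for j, pk in enumerate(peaks):
        if pk.chrom != footprint.chrom:
            continue
        lo = max(pk.start, footprint.start)
        hi = min(pk.end, footprint.end)
        if lo < hi and "peak" in order:
            features.append((rank["peak"], lo, hi, "peak", f"peak{j}"))

    bounds = {footprint.start, footprint.end}
    for _, lo, hi, _, _ in features:
        bounds.add(lo)
        bounds.add(hi)
    cuts = sorted(b for b in bounds if footprint.start <= b <= footprint.end)

    segments: list[tuple[int, int, str, str]] = []
    for lo, hi in zip(cuts, cuts[1:]):
        best: tuple[int, int, int, str, str] | None = None
        for feat in features:
            if feat[1] <= lo and hi <= feat[2]:
                # ties broken by start then source for determinism
                if best is None or feat[:1] < best[:1] or (
                    feat[0] == best[0] and (feat[1], feat[4]) < (best[1], best[4])
                ):
                    best = feat
        if best is None:
            segments.append((lo, hi, "intron", gene.gene_id))
        else:
            segments.append((lo, hi, best[3], best[4]))

    merged: list[tuple[int, int, str, str]] = []
    for seg in segments:
        if merged and merged[-1][2] == seg[2] and merged[-1][3] == seg[3] and merged[-1][1] == seg[0]:
            merged[-1] = (merged[-1][0], seg[1], seg[2], seg[3])
        else:
            merged.append(seg)

    return [
        LabeledFragment(
            GenomicInterval(footprint.chrom, lo, hi, footprint.strand),
            label,
            source,
            gene.gene_id,
        )
        for lo, hi, label, source in merged
    ]
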