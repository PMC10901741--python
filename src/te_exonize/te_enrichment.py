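"""Strand-separated TE composition and log2 observed/expected enrichment.

For a set of stranded regions (peaks, clusters of peaks, gene bodies) and
a repeat annotation, :func:`te_fractions` computes, per repeat family and
orientation (sense = repeat strand equals region strand), the fraction of
total region length covered.  :func:`log2_enrichment` compares an observed
composition (e.g. in RBP peaks) to an expected one (e.g. in the genes that
host those peaks): a positive value means the family is over-represented
in the regions relative to random placement on transcripts.

Sequence composition statistics (adenosine content, purine-rich k-mer
density against a mononucleotide-shuffled background) live here too,
because A-rich, purine-rich TE bodies are the binding substrate the
enrichment is probing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RepeatElement, reduce_intervals

__all__ = [
    "TEFractionTable",
    "EnrichmentTable",
    "te_fractions",
    "log2_enrichment",
    "nucleotide_composition",
    "purine_kmer_enrichment",
]

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass
class TEFractionTable:
    """Fraction of region length covered, per (family, orientation)."""

    fractions: dict[tuple[str, str], float]
    total_length: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"family": fam, "orientation": ori, "fraction": frac}
            for (fam, ori), frac in sorted(self.fractions.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class EnrichmentTable:
    """log2(observed/expected) per (family, orientation).

    Cells where a fraction is zero carry an IEEE sentinel (+/-inf for
    one-sided zeros, nan for 0/0) and are listed in ``flagged``.
    """

    log2_enrichment: dict[tuple[str, str], float]
    flagged: dict[tuple[str, str], str] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": fam,
                "orientation": ori,
                "log2_enrichment": val,
                "flag": self.flagged.get((fam, ori), ""),
            }
            for (fam, ori), val in sorted(self.log2_enrichment.items())
        ]
        return pd.DataFrame(rows)


def te_fractions(
    regions: Sequence[GenomicInterval],
    repeats: Sequence[RepeatElement],
    families: Sequence[str] | None = None,
) -> TEFractionTable:
    """Per-(family, orientation) fraction of total region length covered.

    Overlapping same-family repeats are counted once per base; the
    denominator is the total region length including repeat-free bases.
    Orientation is relative to each region's strand.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("te_fractions: empty region set (fraction undefined)")
    if families is None:
        families = sorted({r.family for r in repeats})
    famset = set(families)

    total = sum(r.length for r in regions)
    # reduced repeat intervals per (family, strand)
    by_fam_strand: dict[tuple[str, str], list[GenomicInterval]] = {}
    for rep in repeats:
        if rep.family in famset:
            by_fam_strand.setdefault((rep.family, rep.interval.strand), []).append(
                rep.interval
            )
    by_fam_strand = {
        k: reduce_intervals(v, strand_aware=False) for k, v in by_fam_strand.items()
    }

    covered: dict[tuple[str, str], int] = {
        (fam, ori): 0 for fam in families for ori in (SENSE, ANTISENSE)
    }
    for region in regions:
        for (fam, rep_strand), ivs in by_fam_strand.items():
            ori = SENSE if rep_strand == region.strand else ANTISENSE
            for iv in ivs:
                if iv.chrom != region.chrom:
                    continue
                lo = max(iv.start, region.start)
                hi = min(iv.end, region.end)
                if lo < hi:
                    covered[(fam, ori)] += hi - lo
    fractions = {k: v / total for k, v in covered.items()}
    return TEFractionTable(fractions, total)


def log2_enrichment(
    observed: TEFractionTable, expected: TEFractionTable
) -> EnrichmentTable:
    """log2(observed fraction / expected fraction), cellwise.

    Zero fractions produce flagged IEEE sentinels rather than silent
    omissions: 0/positive -> -inf, positive/0 -> +inf, 0/0 -> nan.
    """
    if set(observed.fractions) != set(expected.fractions):
        raise ValueError("observed and expected tables cover different cells")
    values: dict[tuple[str, str], float] = {}
    flagged: dict[tuple[str, str], str] = {}
    for key, obs in observed.fractions.items():
        exp = expected.fractions[key]
        if obs > 0 and exp > 0:
            values[key] = math.log2(obs / exp)
        elif obs == 0 and exp == 0:
            values[key] = float("nan")
            flagged[key] = "undefined (0/0)"
        elif obs == 0:
            values[key] = float("-inf")
            flagged[key] = "absent in observed"
        else:
            values[key] = float("inf")
            flagged[key] = "absent in expected"
    return EnrichmentTable(values, flagged)


_PURINES = frozenset("AG")
_CANONICAL = frozenset("ACGTU")


def nucleotide_composition(seq: str, skip_ambiguous: bool = True) -> dict[str, float]:
    """Fractions of A, C, G, T (U counted as T).

    IUPAC ambiguity codes are excluded from the denominator by default.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper().replace("U", "T")
    if skip_ambiguous:
        counted = [b for b in seq if b in "ACGT"]
    else:
        counted = list(seq)
    if not counted:
        raise ValueError("sequence contains no canonical bases")
    n = len(counted)
    return {b: counted.count(b) / n for b in "ACGT"}


def purine_kmer_enrichment(
    seq: str,
    k: int = 6,
    purine_threshold: float = 1.0,
    n_shuffles: int = 100,
    seed: int = 0,
) -> dict[str, float]:
    """Density of purine-rich k-mers vs. a mononucleotide-shuffled null.

    A window of length ``k`` is purine-rich iff its A+G fraction is at
    least ``purine_threshold``.  The null preserves mononucleotide
    composition exactly (a permutation of the sequence), so any ratio > 1
    reflects purine *clustering*, not purine content.  The empirical
    p-value uses the add-one convention, (1 + #null >= observed)/(n + 1).
    """
    if not 0 < purine_threshold <= 1:
        raise ValueError("purine_threshold must be in (0, 1]")
    if k < 3:
        raise ValueError("k must be >= 3")
    seq = seq.upper().replace("U", "T")
    if k > len(seq):
        raise ValueError(f"k={k} exceeds sequence length {len(seq)}")

    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_purine = np.isin(arr, [b"A", b"G"]).astype(np.float64)

    def density(pur: np.ndarray) -> float:
        window = np.convolve(pur, np.ones(k), mode="valid") / k
        return float(np.mean(window >= purine_threshold - 1e-12))

    observed = density(is_purine)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        null[i] = density(rng.permutation(is_purine))
    mean_null = float(null.mean())
    ratio = observed / mean_null if mean_null > 0 else float("inf")
    pval = float((1 + np.sum(null >= observed - 1e-12)) / (n_shuffles + 1))
    return {
        "observed_density": observed,
        "mean_shuffled_density": mean_null,
        "ratio": ratio,
        "p_value": pval,
    }
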