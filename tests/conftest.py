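"""Shared fixtures and brute-force oracles for the test suite.

The oracles here are deliberately naive (per-base occupancy arrays,
exhaustive scans) and independent of the interval algebra they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from te_exonize.intervals import GenomicInterval


def coverage_oracle(intervals, chrom_len: int, chrom: str = "chr1", strand=None):
    """Per-base occupancy array for one chromosome (optionally one strand)."""
    cov = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        if iv.chrom != chrom:
            continue
        if strand is not None and iv.strand != strand:
            continue
        cov[iv.start : iv.end] = True
    return cov


def runs_from_coverage(cov: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) half-open pairs."""
    padded = np.concatenate([[False], cov, [False]]).astype(int)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def random_intervals(rng, n, chrom_len, chrom="chr1", strands=("+", "-"), max_len=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, chrom_len - 2))
        length = int(rng.integers(1, min(max_len, chrom_len - start)))
        out.append(
            GenomicInterval(chrom, start, start + length, str(rng.choice(strands)))
        )
    return out


@pytest.fixture(scope="session")
def default_sim():
    """The standard simulated study: genome, truth, counts, design."""
    from te_exonize.diffstats import Design
    from te_exonize.simulate import SimulationSpec, simulate_counts, simulate_genome

    spec = SimulationSpec(seed=11)
    genome, truth = simulate_genome(spec)
    exon_counts, peak_counts, junctions = simulate_counts(genome, truth, spec)
    design = Design(spec.samples, spec.condition)
    return {
        "spec": spec,
        "genome": genome,
        "truth": truth,
        "exon_counts": exon_counts,
        "peak_counts": peak_counts,
        "junctions": junctions,
        "design": design,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
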