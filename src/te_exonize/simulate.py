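"""Seed-deterministic synthetic genomes, counts, read ends and peak profiles.

The generators produce toy data with the statistical structure the
pipeline is built for, at desk scale:

* an annotated genome: genes with exon/intron structure on one toy
  chromosome, intronic TE insertions with configurable family mix and
  strand bias, A-rich sense-TE sequence bodies, and one intronic RBP
  peak per TE-bearing gene;
* negative-binomial exon/peak/junction counts for a control-vs-knockdown
  design, with planted exonization events (the intronic peak gains usage
  in the knockdown while downstream exons drop — the gene-trap
  signature) and a planted novel junction into the peak;
* long-read 3' end coordinates with planted polyA-isoform switches;
* a peak x profile count matrix with planted cluster signatures;
* placement generators for TE-enrichment null and plant experiments;
* a hand-constructed splice-junction panel in which every decoy junction
  violates exactly one rule of the stringent filter chain.

Every generator takes an explicit seed (or a spec carrying one) and is
byte-identical across reruns; planted effects are recorded in a
:class:`GroundTruth` so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedGenome
from .apa import ReadEnd
from .intervals import Gene, GenomicInterval, RepeatElement
from .junctions import Junction
from .peaks import Peak, PeakCountMatrix

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "simulate_genome",
    "simulate_counts",
    "simulate_read_ends",
    "simulate_peak_profiles",
    "simulate_enrichment_peaks",
    "stringent_panel_fixture",
]


@dataclass
class SimulationSpec:
    """All tunable knobs of the simulator, with desk-scale defaults.

    Defaults define the standard study conditions: 500 genes on one toy
    chromosome, 3+3 replicates, 10% of peak-bearing genes with a planted
    exonization (peak usage x8 in knockdown, downstream exons x0.5) and
    a 30-percentage-point polyA-isoform switch in switched genes.
    """

    seed: int = 0
    chrom: str = "chrS"
    n_genes: int = 500
    n_exons_range: tuple[int, int] = (3, 8)
    exon_length_range: tuple[int, int] = (80, 400)
    intron_length_range: tuple[int, int] = (800, 3000)
    intergenic_range: tuple[int, int] = (1000, 3000)
    # TE insertions
    te_families: tuple[str, ...] = ("L1", "Alu", "TcMar-Tigger")
    te_family_weights: tuple[float, ...] = (0.5, 0.3, 0.2)
    te_insertion_prob: float = 0.7  # per intron
    te_sense_prob: float = 0.5
    te_length_range: tuple[int, int] = (200, 900)
    te_a_fraction: float = 0.40  # adenosine content of sense TE bodies
    # peaks
    peak_profiles: tuple[str, ...] = ("SAFB1", "SAFB2", "SLTM")
    # planted effects
    exonized_fraction: float = 0.10
    peak_share_multiplier: float = 8.0
    post_peak_multiplier: float = 0.5
    apa_switched_fraction: float = 0.15
    apa_switch_pp: float = 0.30
    apa_reads_per_gene: int = 1000
    apa_jitter: int = 10
    # noise
    nb_mean_exon: float = 150.0
    nb_mean_peak: float = 60.0
    nb_dispersion: float = 0.05
    replicates: int = 3
    depth_sigma: float = 0.1  # lognormal sd of per-sample depth factors

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one simulator component."""
        return np.random.default_rng([self.seed, stream])

    @property
    def samples(self) -> list[str]:
        r = self.replicates
        return [f"control_{i+1}" for i in range(r)] + [f"kd_{i+1}" for i in range(r)]

    @property
    def condition(self) -> dict[str, str]:
        return {
            s: ("control" if s.startswith("control") else "treatment")
            for s in self.samples
        }


@dataclass
class GeneTruth:
    exonized: bool = False
    apa_switched: bool = False
    peak_id: str | None = None
    peak_intron_index: int | None = None
    polya_positions: list[int] = field(default_factory=list)
    polya_fractions_control: list[float] = field(default_factory=list)
    polya_fractions_treatment: list[float] = field(default_factory=list)
    novel_junction_id: str | None = None


@dataclass
class GroundTruth:
    """Planted effects per gene, and the simulated intronic peak set."""

    genes: dict[str, GeneTruth] = field(default_factory=dict)
    peaks: list[Peak] = field(default_factory=list)

    def exonized_genes(self) -> list[str]:
        return sorted(g for g, t in self.genes.items() if t.exonized)

    def switched_genes(self) -> list[str]:
        return sorted(g for g, t in self.genes.items() if t.apa_switched)


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative binomial with mean/dispersion parameterization."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_genome(spec: SimulationSpec) -> tuple[AnnotatedGenome, GroundTruth]:
    """Generate the annotated toy genome and its ground truth.

    Gene structures, intronic TE insertions and intronic peaks are laid
    out left to right on one chromosome; each TE-bearing gene receives
    one intronic peak placed inside a TE (sense insertions preferred),
    and the exonized/APA-switched flags are drawn here so every
    downstream generator sees the same plan.
    """
    rng = spec.rng(1)
    lo_e, hi_e = spec.n_exons_range
    genes: dict[str, Gene] = {}
    repeats: list[RepeatElement] = []
    truth = GroundTruth()

    cursor = 1000
    te_records: dict[str, list[tuple[RepeatElement, int]]] = {}
    intron_spans: dict[str, list[GenomicInterval]] = {}
    for gi in range(spec.n_genes):
        gene_id = f"G{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(lo_e, hi_e + 1))
        exon_lens = rng.integers(*spec.exon_length_range, size=n_exons)
        intron_lens = rng.integers(*spec.intron_length_range, size=n_exons - 1)
        exons = []
        pos = cursor
        introns = []
        for k in range(n_exons):
            exons.append(GenomicInterval(spec.chrom, pos, pos + int(exon_lens[k]), strand))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                introns.append(GenomicInterval(spec.chrom, pos, pos + int(intron_lens[k]), strand))
                pos += int(intron_lens[k])
        interval = GenomicInterval(spec.chrom, cursor, pos, strand)
        genes[gene_id] = Gene(gene_id, interval, exons)
        intron_spans[gene_id] = introns
        cursor = pos + int(rng.integers(*spec.intergenic_range))

        # TE insertions per intron
        gene_tes: list[tuple[RepeatElement, int]] = []
        for ii, intron in enumerate(introns):
            if rng.random() >= spec.te_insertion_prob:
                continue
            max_len = min(spec.te_length_range[1], intron.length - 40)
            if max_len < spec.te_length_range[0]:
                continue
            te_len = int(rng.integers(spec.te_length_range[0], max_len + 1))
            offset = int(rng.integers(20, intron.length - te_len - 20 + 1))
            te_strand = strand if rng.random() < spec.te_sense_prob else (
                "-" if strand == "+" else "+"
            )
            family = str(
                rng.choice(spec.te_families, p=np.array(spec.te_family_weights))
            )
            rep = RepeatElement(
                GenomicInterval(
                    spec.chrom, intron.start + offset, intron.start + offset + te_len, te_strand
                ),
                family,
                family.split("-")[0],
            )
            repeats.append(rep)
            gene_tes.append((rep, ii))
        te_records[gene_id] = gene_tes
        truth.genes[gene_id] = GeneTruth()

    # one intronic peak per TE-bearing gene, inside a TE, sense preferred
    for gene_id, gene_tes in te_records.items():
        if not gene_tes:
            continue
        gene = genes[gene_id]
        sense = [(r, ii) for r, ii in gene_tes if r.interval.strand == gene.strand]
        rep, intron_index = (sense or gene_tes)[int(rng.integers(len(sense or gene_tes)))]
        iv = rep.interval
        width = min(max(iv.length // 2, 60), iv.length)
        start = iv.start + int(rng.integers(0, iv.length - width + 1))
        n_src = int(rng.integers(1, len(spec.peak_profiles) + 1))
        sources = frozenset(
            rng.choice(spec.peak_profiles, size=n_src, replace=False).tolist()
        )
        peak = Peak(
            GenomicInterval(spec.chrom, start, start + width, gene.strand),
            sources,
            host_gene=gene_id,
            intronic=True,
        )
        truth.peaks.append(peak)
        truth.genes[gene_id].peak_id = peak.peak_id
        truth.genes[gene_id].peak_intron_index = intron_index

    # planted effects among peak-bearing genes
    peaked = sorted(g for g, t in truth.genes.items() if t.peak_id is not None)
    n_exo = int(round(spec.exonized_fraction * len(peaked)))
    exo = rng.choice(peaked, size=n_exo, replace=False)
    for g in exo:
        truth.genes[g].exonized = True
    n_switch = int(round(spec.apa_switched_fraction * spec.n_genes))
    switched = rng.choice(sorted(truth.genes), size=n_switch, replace=False)
    for g in switched:
        truth.genes[g].apa_switched = True

    # chromosome sequence: uniform background, A-rich sense-TE bodies
    chrom_len = cursor + 1000
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=chrom_len)
    for rep in repeats:
        body_len = rep.interval.length
        a = spec.te_a_fraction
        rest = (1.0 - a) / 3.0
        if rep.interval.strand == "+":
            probs = [a, rest, rest, rest]  # A-rich on the plus strand
        else:
            probs = [rest, rest, rest, a]  # T on plus = A on the TE strand
        seq[rep.interval.start : rep.interval.end] = rng.choice(
            np.frombuffer(b"ACGT", dtype="S1"), size=body_len, p=probs
        )
    genome = AnnotatedGenome(
        genes=genes,
        repeats=repeats,
        sequences={spec.chrom: seq.tobytes().decode()},
    )
    return genome, truth


def _transcription_order(gene: Gene) -> list[int]:
    """Exon indices in transcription direction."""
    order = list(range(len(gene.exons)))
    return order if gene.strand == "+" else order[::-1]


def simulate_counts(
    genome: AnnotatedGenome, truth: GroundTruth, spec: SimulationSpec
) -> tuple[pd.DataFrame, pd.DataFrame, list[Junction]]:
    """NB exon/peak counts and a junction panel with planted effects.

    In exonized genes the intronic peak's mean is multiplied by
    ``peak_share_multiplier`` in treatment samples, exons downstream of
    the peak's intron (transcription direction) by
    ``post_peak_multiplier``, and a novel junction from the upstream
    exon's donor into the peak appears in treatment.

    Returns (exon_counts, peak_counts, junctions); exon ids are
    ``gene:exonK`` with K in genomic order.
    """
    rng = spec.rng(2)
    samples = spec.samples
    n_s = len(samples)
    depth = np.exp(rng.normal(0.0, spec.depth_sigma, size=n_s))
    is_trt = np.array([spec.condition[s] == "treatment" for s in samples])

    peaks_by_gene = {p.host_gene: p for p in truth.peaks}

    exon_rows: dict[str, np.ndarray] = {}
    junctions: list[Junction] = []
    peak_rows: dict[str, np.ndarray] = {}

    for gene_id in sorted(genome.genes):
        gene = genome.genes[gene_id]
        gt = truth.genes[gene_id]
        n_exons = len(gene.exons)
        order = _transcription_order(gene)
        # exons downstream (3') of the peak's intron, in transcription order
        post_set: set[int] = set()
        if gt.exonized and gt.peak_intron_index is not None:
            ii = gt.peak_intron_index
            if gene.strand == "+":
                post_set = set(range(ii + 1, n_exons))
            else:
                post_set = set(range(0, ii + 1))

        for k in range(n_exons):
            mu = spec.nb_mean_exon * np.clip(gene.exons[k].length / 250.0, 0.4, 2.5)
            mu_vec = np.full(n_s, mu)
            if k in post_set:
                mu_vec[is_trt] *= spec.post_peak_multiplier
            exon_rows[f"{gene_id}:exon{k}"] = _nb_draw(
                rng, mu_vec * depth, spec.nb_dispersion
            )

        peak = peaks_by_gene.get(gene_id)
        if peak is not None:
            mu_vec = np.full(n_s, spec.nb_mean_peak)
            if gt.exonized:
                mu_vec[is_trt] *= spec.peak_share_multiplier
            peak_rows[peak.peak_id] = _nb_draw(rng, mu_vec * depth, spec.nb_dispersion)

        # constitutive junctions between consecutive exons (genomic order)
        for k in range(n_exons - 1):
            if gene.strand == "+":
                donor = gene.exons[k].end
                acceptor = gene.exons[k + 1].start - 1
            else:
                donor = gene.exons[k + 1].start - 1
                acceptor = gene.exons[k].end
            mu_vec = np.full(n_s, spec.nb_mean_exon * 0.6)
            counts = _nb_draw(rng, mu_vec * depth, spec.nb_dispersion)
            junctions.append(
                Junction(
                    gene.chrom,
                    donor,
                    acceptor,
                    gene.strand,
                    dict(zip(samples, (int(c) for c in counts))),
                    host_gene=gene_id,
                )
            )

        # novel junction into the peak for exonized genes
        if gt.exonized and peak is not None and gt.peak_intron_index is not None:
            ii = gt.peak_intron_index
            if gene.strand == "+":
                donor = gene.exons[ii].end
                acceptor = peak.interval.start + 10
            else:
                donor = gene.exons[ii + 1].start - 1
                acceptor = peak.interval.end - 11
            mu_vec = np.where(is_trt, spec.nb_mean_exon * 0.3, 0.2)
            counts = _nb_draw(rng, mu_vec * depth, spec.nb_dispersion)
            j = Junction(
                gene.chrom,
                donor,
                acceptor,
                gene.strand,
                dict(zip(samples, (int(c) for c in counts))),
                host_gene=gene_id,
            )
            junctions.append(j)
            gt.novel_junction_id = j.junction_id

    exon_counts = pd.DataFrame.from_dict(exon_rows, orient="index", columns=samples)
    peak_counts = pd.DataFrame.from_dict(peak_rows, orient="index", columns=samples)
    return exon_counts, peak_counts, junctions


def simulate_read_ends(
    genome: AnnotatedGenome, truth: GroundTruth, spec: SimulationSpec
) -> list[ReadEnd]:
    """Long-read 3' ends sampled multinomially around per-gene polyA sites.

    Each gene carries 2-3 polyA positions (the annotated 3' end plus
    internal sites); switched genes move ``apa_switch_pp`` of isoform
    mass from the dominant to the second site in the treatment
    condition.  Ends jitter uniformly within +/- ``apa_jitter`` nt
    (inside the collapse radius).
    """
    rng = spec.rng(3)
    ends: list[ReadEnd] = []
    samples = spec.samples
    per_sample = max(spec.apa_reads_per_gene // len(samples), 1)
    for gene_id in sorted(genome.genes):
        gene = genome.genes[gene_id]
        gt = truth.genes[gene_id]
        order = _transcription_order(gene)
        last = gene.exons[order[-1]]
        term = last.end - 1 if gene.strand == "+" else last.start
        k = int(rng.integers(2, 4))
        positions = [term]
        for j in range(k - 1):
            mid_exon = gene.exons[order[len(order) // 2]]
            offset = 200 * (j + 1)
            pos = (
                mid_exon.end - 1 + offset if gene.strand == "+" else mid_exon.start - offset
            )
            positions.append(max(pos, 0))
        base = rng.dirichlet(np.full(k, 5.0))
        base = np.sort(base)[::-1]
        frac_c = base
        frac_t = base.copy()
        if gt.apa_switched:
            shift = min(spec.apa_switch_pp, frac_t[0] - 0.01)
            frac_t = frac_t.copy()
            frac_t[0] -= shift
            frac_t[1] += shift
        gt.polya_positions = [int(p) for p in positions]
        gt.polya_fractions_control = [float(f) for f in frac_c]
        gt.polya_fractions_treatment = [float(f) for f in frac_t]
        for s in samples:
            frac = frac_t if spec.condition[s] == "treatment" else frac_c
            draws = rng.multinomial(per_sample, frac)
            for pos, n in zip(positions, draws):
                if n == 0:
                    continue
                jit = rng.integers(-spec.apa_jitter, spec.apa_jitter + 1, size=n)
                for j in jit:
                    ends.append(ReadEnd(gene.chrom, max(int(pos + j), 0), gene.strand, s))
    return ends


def simulate_peak_profiles(
    n_clusters: int = 3,
    peaks_per_cluster: int = 200,
    profiles: Sequence[str] | None = None,
    dominant_mean: float = 200.0,
    background_mean: float = 5.0,
    dispersion: float = 0.1,
    shared_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[PeakCountMatrix, np.ndarray]:
    """Peak x profile count matrix with planted cluster signatures.

    Cluster ``k`` peaks load on profile ``k`` (NB mean ``dominant_mean``)
    and weakly on all others; a ``shared_fraction`` of each cluster's
    peaks also loads on the next profile and carries both sources.
    Returns the matrix and the true cluster labels.
    """
    rng = np.random.default_rng([seed, 4])
    if profiles is None:
        profiles = [f"RBP{k}" for k in range(max(n_clusters, 2))]
    profiles = list(profiles)
    if n_clusters < 1 or len(profiles) < n_clusters:
        raise ValueError("need at least one profile per planted cluster")
    peaks: list[Peak] = []
    rows = []
    labels = []
    pos = 0
    for k in range(n_clusters):
        for i in range(peaks_per_cluster):
            mu = np.full(len(profiles), background_mean)
            mu[k] = dominant_mean
            sources = {profiles[k]}
            if rng.random() < shared_fraction:
                other = (k + 1) % len(profiles)
                mu[other] = dominant_mean
                sources.add(profiles[other])
            rows.append(_nb_draw(rng, mu, dispersion))
            peaks.append(
                Peak(
                    GenomicInterval("chrP", pos, pos + 100, "+"),
                    frozenset(sources),
                )
            )
            labels.append(k)
            pos += 200
    counts = np.vstack(rows)
    return PeakCountMatrix(peaks, profiles, counts), np.asarray(labels)


def _largest_remainder(shares: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of ``n`` proportional to ``shares``, summing to n."""
    exact = shares / shares.sum() * n
    base = np.floor(exact).astype(int)
    remainder = n - int(base.sum())
    order = np.argsort(-(exact - base))
    base[order[:remainder]] += 1
    return base


def simulate_enrichment_peaks(
    genome: AnnotatedGenome,
    n_peaks: int = 5000,
    peak_width: int = 50,
    target_family: str | None = None,
    target_multiplier: float = 1.0,
    mode: str = "balanced",
    seed: int = 0,
) -> list[GenomicInterval]:
    """Place peaks on gene bodies, uniformly or with a planted preference.

    Without a target family, peaks are placed uniformly over
    gene-footprint bases.  ``mode="balanced"`` (default) is a
    variance-reduced uniform design: the number of peaks landing in each
    composition class (every family x orientation cell, plus repeat-free
    background) is fixed at its exact base-share by largest-remainder
    allocation, and positions are drawn uniformly within the class, so
    the realized composition tracks the genomic one without Monte-Carlo
    drift while the marginal placement density stays uniform.
    ``mode="iid"`` draws fully independent positions.

    With ``target_family``, a ``min(1, multiplier * f)`` share of peaks
    (f = the family's sense base fraction in gene bodies) is placed
    wholly inside sense instances of that family and the rest wholly
    outside any of them, so the observed/expected ratio is the
    multiplier by construction.
    """
    from .intervals import flatten_gene, reduce_intervals, subtract_intervals

    rng = np.random.default_rng([seed, 5])
    footprints = [flatten_gene(g) for g in genome.genes.values()]
    footprints.sort(key=lambda iv: (iv.chrom, iv.start))

    def stratified_positions(
        segments: list[GenomicInterval], n: int
    ) -> list[tuple[GenomicInterval, int]]:
        lengths = np.array([s.length for s in segments])
        total = int(lengths.sum())
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        u = (np.arange(n) + rng.random(n)) * total / n
        idx = np.searchsorted(offsets, u, side="right") - 1
        return [(segments[i], int(u[j] - offsets[i])) for j, i in enumerate(idx)]

    def clip_peak(seg: GenomicInterval, offset: int, width: int) -> GenomicInterval:
        center = seg.start + offset
        half = width // 2
        lo = max(center - half, seg.start)
        hi = min(lo + width, seg.end)
        lo = max(hi - width, seg.start)
        return GenomicInterval(seg.chrom, lo, hi, seg.strand)

    def family_segments(family: str, sense: bool) -> list[GenomicInterval]:
        segs = []
        for fp in footprints:
            for rep in genome.repeats:
                if rep.family != family or rep.interval.chrom != fp.chrom:
                    continue
                is_sense = rep.interval.strand == fp.strand
                if is_sense != sense:
                    continue
                lo = max(rep.interval.start, fp.start)
                hi = min(rep.interval.end, fp.end)
                if lo < hi:
                    segs.append(GenomicInterval(fp.chrom, lo, hi, fp.strand))
        return reduce_intervals(segs, strand_aware=True)

    if target_family is not None and target_multiplier != 1.0:
        target_segs = family_segments(target_family, sense=True)
        if not target_segs:
            raise ValueError(f"no sense {target_family} content inside genes")
        background_segs = [
            s
            for fp in footprints
            for s in subtract_intervals([fp], target_segs)
            if s.length >= peak_width
        ]
        total_fp = sum(fp.length for fp in footprints)
        f_exp = sum(s.length for s in target_segs) / total_fp
        n_target = int(round(min(1.0, target_multiplier * f_exp) * n_peaks))
        peaks = [
            clip_peak(seg, off, peak_width)
            for seg, off in stratified_positions(target_segs, n_target)
        ]
        peaks += [
            clip_peak(seg, off, peak_width)
            for seg, off in stratified_positions(background_segs, n_peaks - n_target)
        ]
        return peaks

    if mode == "iid":
        lengths = np.array([fp.length for fp in footprints])
        offsets = np.concatenate([[0], np.cumsum(lengths)])
        u = rng.random(n_peaks) * lengths.sum()
        idx = np.searchsorted(offsets, u, side="right") - 1
        return [
            clip_peak(footprints[i], int(u[j] - offsets[i]), peak_width)
            for j, i in enumerate(idx)
        ]
    if mode != "balanced":
        raise ValueError(f"unknown placement mode {mode!r}")

    # balanced: exact per-class allocation, uniform within class
    families = sorted({r.family for r in genome.repeats})
    classes: list[list[GenomicInterval]] = []
    all_rep_segs: list[GenomicInterval] = []
    for family in families:
        for sense in (True, False):
            segs = family_segments(family, sense)
            if segs:
                classes.append(segs)
                all_rep_segs.extend(segs)
    background = [
        s
        for fp in footprints
        for s in subtract_intervals([fp], all_rep_segs)
        if s.length >= 1
    ]
    classes.append(background)
    class_lengths = np.array([sum(s.length for s in segs) for segs in classes], dtype=float)
    alloc = _largest_remainder(class_lengths, n_peaks)
    peaks = []
    for segs, n in zip(classes, alloc):
        peaks.extend(
            clip_peak(seg, off, peak_width)
            for seg, off in stratified_positions(segs, int(n))
        )
    return peaks


def stringent_panel_fixture() -> dict:
    """A constructed tissue panel probing every rule of the stringent filter.

    Exactly 3 junctions satisfy the whole chain; 20 decoys each violate
    exactly one rule (four fail host-gene assignment, four the annotated
    donor requirement, four the acceptor-in-peak requirement, five donor
    multiplicity, two the splicing-index floor and one the per-tissue
    read-support floor).  Returns a dict with junctions, tissue totals,
    genes, annotated donors, intronic peaks and the expected outcome.
    """
    tissues = ["liver", "brain", "lung", "heart"]
    tissue_totals = {t: 2.0e9 for t in tissues}
    tissue_totals["testis_lowdepth"] = 5.0e8  # excluded by the 1e9 floor

    def gene(gid: str, start: int, strand: str = "+") -> Gene:
        exons = [
            GenomicInterval("chrS", start, start + 200, strand),
            GenomicInterval("chrS", start + 5000, start + 5200, strand),
            GenomicInterval("chrS", start + 30000, start + 30200, strand),
        ]
        return Gene(gid, GenomicInterval("chrS", start, start + 30200, strand), exons)

    g_main = gene("GMAIN", 100_000)
    g_ov_a = gene("GOVA", 200_000)
    g_ov_b = gene("GOVB", 201_000)  # overlaps GOVA -> ambiguous hosts
    genes = {g.gene_id: g for g in (g_main, g_ov_a, g_ov_b)}

    def peak(start: int, end: int) -> Peak:
        return Peak(
            GenomicInterval("chrS", start, end, "+"),
            frozenset({"SAFB1"}),
            host_gene="GMAIN",
            intronic=True,
        )

    peaks = [peak(106_000, 106_400), peak(112_000, 112_400), peak(118_000, 118_400)]

    def junc(donor: int, acceptor: int, counts: dict[str, int]) -> Junction:
        return Junction("chrS", donor, acceptor, "+", dict(counts))

    high = {t: 800 for t in tissues}
    low = {t: 3 for t in tissues}

    annotated_donors = set()
    junctions: list[Junction] = []
    expected: dict[str, str] = {}

    # donor group D1: two compliant junctions into two peaks
    d1 = 100_200
    j1 = junc(d1, 106_100, {t: 500 for t in tissues})
    j2 = junc(d1, 112_100, {t: 320 for t in tissues})
    annotated_donors.update([j1.donor_id])
    junctions += [j1, j2]
    expected[j1.junction_id] = "pass"
    expected[j2.junction_id] = "pass"

    # donor group D2: one compliant junction + one SI decoy (0.5% share)
    d2 = 100_260
    j3 = junc(d2, 118_100, {t: 995 for t in tissues})
    j4 = junc(d2, 118_200, {t: 5 for t in tissues})
    annotated_donors.add(j3.donor_id)
    junctions += [j3, j4]
    expected[j3.junction_id] = "pass"
    expected[j4.junction_id] = "splicing_index"

    # donor group D5: SI decoy + read-support decoy (group support 400 < 500)
    d5 = 100_300
    j7 = junc(d5, 106_200, {t: 2 for t in tissues})
    j8 = junc(d5, 112_200, {t: 398 for t in tissues})
    annotated_donors.add(j7.donor_id)
    junctions += [j7, j8]
    expected[j7.junction_id] = "splicing_index"
    expected[j8.junction_id] = "read_support"

    # host-gene decoys: introns inside two overlapping genes
    for i in range(4):
        j = junc(201_200 + 10 * i, 206_100 + 10 * i, dict(high))
        annotated_donors.add(j.donor_id)
        junctions.append(j)
        expected[j.junction_id] = "host_gene"

    # annotated-donor decoys: unique unannotated donors, acceptors in peaks
    for i in range(4):
        j = junc(103_000 + 10 * i, 106_050 + i, dict(high))
        junctions.append(j)
        expected[j.junction_id] = "annotated_donor"

    # acceptor-in-peak decoys: annotated donors, acceptors outside peaks
    for i in range(4):
        j = junc(104_000 + 10 * i, 120_000 + 10 * i, dict(high))
        annotated_donors.add(j.donor_id)
        junctions.append(j)
        expected[j.junction_id] = "acceptor_in_peak"

    # donor-multiplicity decoys: compliant but alone at their donor
    for i in range(5):
        j = junc(105_000 + 10 * i, 106_300 + i, dict(high))
        annotated_donors.add(j.donor_id)
        junctions.append(j)
        expected[j.junction_id] = "multi_event_donor"

    return {
        "junctions": junctions,
        "tissue_totals": tissue_totals,
        "genes": genes,
        "annotated_donors": annotated_donors,
        "intronic_peaks": peaks,
        "expected": expected,
        "n_pass": 3,
    }
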