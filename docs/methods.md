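# Methods

This note documents the models, statistics and numerical choices behind
`te-exonize`, and what the synthetic-data generator does and does not
emulate.

## The biological problem

Intronic transposable elements (TEs) are transcribed with their host
pre-mRNA and normally removed with the intron.  When the splicing
machinery instead activates a cryptic splice acceptor inside a TE, the
element is *exonized*; if the exonized segment also carries a
polyadenylation signal, the host transcript terminates prematurely — the
element acts as a gene trap.  RNA-binding proteins of the SAFB family
bind adenosine-rich, purine-rich sense-strand TE RNA (L1, Tigger and
related families) and suppress these events.  The pipeline quantifies
this suppression from four data modalities: RBP peak sets, short-read
RNA-seq counts (exons, intronic peaks, splice junctions), multi-tissue
junction panels, and long-read 3′-end coordinates.

## Coordinate model and interval algebra

All coordinates are 0-based half-open internally (BED convention); GTF,
repeatMasker `.out` and `SJ.out.tab` inputs (1-based inclusive) are
converted at the I/O boundary.  Merging follows reduce semantics with
zero minimum gap: touching intervals merge.  Priority fragmentation
labels every base of a gene footprint by the highest-priority feature
covering it (e.g. exon > repeat > intron for the fragment-level counting
reference); the correctness contract is per-base equivalence with a
painting oracle, enforced in the acceptance suite on thousands of random
instances.

Genes are flattened exon unions — there is no transcript/isoform model.
Overlapping genes are flattened independently; features contained in
more than one gene footprint are assigned to the gene with the longest
overlap (ties: lexicographically smallest gene id) and flagged
ambiguous, except junctions, which are discarded outright when their
host is ambiguous.

## Peak universe

Per-profile peak sets merge strand-aware; a merged peak keeps the union
of contributing profiles.  "Within-gene" means full containment in a
gene footprint on the same strand (the strict reading; any-overlap is a
flag away).  Intronic peaks are the set difference of within-gene peaks
and all annotated exons on the peak strand: exon-overlapping portions
are masked so exonic reads can never inflate peak counts, and a peak
fully inside exons disappears.

## Differential statistics

The engine targets two-condition designs with small replicate numbers
(default 3 vs 3) and is deliberately compact: no GLM covariates, no
independent-filtering optimization, no posterior effect shrinkage — raw
log2 fold changes are reported and classification thresholds apply to
them.

* **Normalization** — median-of-ratios size factors (median over
  features positive in every sample of count / geometric mean).
* **Expression test** — counts are normalized, shifted by a 0.5
  pseudo-count and log2-transformed; per-feature pooled within-condition
  variances are squeezed toward a cross-feature prior whose strength
  (prior degrees of freedom) is fitted by the closed-form moment match
  on log sample variances; the statistic is a moderated t with
  d0 + n − 2 degrees of freedom.  With a fold-change threshold T the
  composite null |log2FC| ≤ T is tested ((|effect| − T)/se, one tail
  doubled), so only effects beyond T reach small p-values.

  Why moderation: a per-feature plug-in NB dispersion at n = 6 is so
  noisy that the Wald statistic is either anti-conservative (normal
  reference: measured type-I error 0.12 at nominal 0.05) or powerless
  (t with n − 2 df: sensitivity 0.22 for 4-fold effects at padj < 0.05).
  Variance squeezing restores both: measured type-I error ≈ 0.05, null
  p-values uniform (KS p ≈ 0.5), sensitivity ≈ 0.97 under the same
  conditions.  The trade-off is the usual one: the prior assumes
  exchangeable variances across features on the log scale; a constant
  prior (no mean-variance trend) is fitted, adequate for the moderate
  dynamic range of the synthetic substrate but a simplification for
  real data with strong mean-variance trends at low counts.
* **Relative usage test** — a feature's per-sample share of its group
  (gene) is (feature + 0.5)/(group + 1); the moderated test runs on
  log2 shares.  Library size cancels inside the ratio, so the statistic
  is invariant to rescaling any sample up to the pseudo-counts.
* **Multiple testing** — Benjamini–Hochberg; NaN p-values (filtered
  features) are excluded from the family and stay NaN.
* **Association** — Pearson χ² (1 df, no continuity correction by
  default) and the cross-product odds ratio; a zero cell switches the OR
  to the Haldane–Anscombe +0.5 form while the χ² remains valid for
  positive margins.

Features with fewer than 10 raw reads in total are discarded before
testing.

## Exonization / early-termination classification

Every intronic peak is tested for differential usage within its host
gene (group total = summed exon + intronic-peak counts of the gene).
Per gene, the peak with the smallest raw p-value is the reference peak
(ties: leftmost start, then peak id).  Exons wholly 5′ of the reference
peak in transcription direction form the *pre* fragment, exons wholly 3′
the *post* fragment; exons overlapping the peak span belong to neither
(their reads were masked during counting).  Aggregated pre/post counts
are tested for differential expression without a fold-change threshold.
Classification: `upregulated` = peak padj < 0.05 and log2 usage change
> 2; `control` = padj > 0.05 and change strictly inside (−0.5, 0.5);
everything else, including filtered peaks, is `other`.  The thresholds
are log2-scale and configurable.  The gene-trap signature is a flat pre
fragment with a depressed post fragment.

## Junctions

`SJ.out.tab` rows become donor/acceptor positions oriented by strand
(donor = first intronic base in transcription direction).  Filtering
requires a unique host gene and ≥ 10 total reads.  Differential usage
treats junctions as features and host genes as groups.  The splicing
index of a junction at a donor (or acceptor) is its share of all
junction reads using that site, computed on pooled or per-sample counts;
shares at a site sum to 1 by construction.

The stringent multi-tissue chain for novel acceptors applies, in order:
tissue inclusion (≥ 1e9 spliced reads), unique host gene, annotated
donor, acceptor inside a fully intronic peak, donor used by ≥ 2
surviving junctions, splicing index > 1% in ≥ 1 tissue, and donor
support ≥ 500 reads in every included tissue.  Two readings were open:
donor multiplicity is evaluated *after* the earlier filters, and the
500-read support applies to the donor's total junction reads per tissue
(the ubiquitous-usage reading); both are configurable.  The filter
reports a per-junction attrition table naming the first rule each
removed junction failed.

Splice-site strength is surveyed against a pluggable scorer (position →
probability): all AG/GT dinucleotides on the correct strand in a 500 nt
window around a novel site are scored and the novel site is compared to
the best and to a seeded random sample of candidates.  The shipped
hexamer-consensus scorer is a toy for tests and demonstrations, not a
trained splice model.

Nearest-TE distances are computed per repeat family and orientation
(relative to the gene strand) within the flattened host gene; sites
inside a repeat get distance 0, repeats outside genes are dropped, and
absent family/gene combinations are undefined (NaN).

## Alternative polyadenylation

Single-base 3′ read ends are padded ±50 nt and collapsed per chromosome
and strand into disjoint putative polyadenylation regions; collapse is
order-independent and idempotent, and every input end lies in exactly
one region.  Regions map to genes by midpoint containment.  Per gene and
condition, each region's fraction of the gene's reads is computed; a
gene is called differentially polyadenylated iff its total reads
(conditions pooled — the configurable reading of "supported by at least
20 reads") ≥ 20 and some region's fraction shifts by ≥ 20 percentage
points.  Both thresholds are inclusive.  Fractions are raw (no length or
depth normalization).

## Peak-space clustering

The unified peak × profile matrix is column-standardized (population
standard deviation; constant columns become zeros and are flagged).
Embedding and clustering are injected dependencies behind a two-method
interface (matrix → coordinates, matrix → labels); defaults are PCA and
scikit-learn's HDBSCAN (noise label −1), with a UMAP embedder available
when umap-learn is installed.  The scientific outputs are composition
reports, which do not depend on any particular embedding geometry:
per-cluster exclusive source-profile fractions (plus the shared
fraction, reported separately), and per-cluster TE enrichment against
the full peak universe as background.

## Synthetic data

The generator produces one toy chromosome with (by default) 500
non-overlapping genes of 3–8 exons (80–400 nt) and introns of 0.8–3 kb;
each intron hosts a TE insertion with probability 0.7 (families L1 /
Alu / TcMar-Tigger at 0.5/0.3/0.2, lengths 200–900 nt, sense with
probability 0.5), giving gene bodies whose intronic space is roughly
one-fifth TE by length.  Sense-TE bodies are 40% adenosine on their own
strand, emulating the A-rich coding strand of young L1 elements;
background sequence is uniform.  Each TE-bearing gene receives one
intronic peak inside a TE (sense preferred) sourced from a random subset
of three RBP profiles.

Counts are negative binomial (dispersion 0.05, exon mean 150 scaled by
exon length, peak mean 60) with mild lognormal per-sample depth factors,
3+3 replicates.  Planted exonization (10% of peak-bearing genes)
multiplies the peak mean by 8 in the knockdown, downstream-exon means by
0.5, and adds a novel junction into the peak carried almost exclusively
by knockdown samples.  Long-read 3′ ends are multinomial over 2–3 polyA
sites per gene with ±10 nt jitter (inside the ±50 collapse radius);
switched genes (15%) move 30 percentage points of isoform mass in the
knockdown.  The read depth (1000 ends per gene) is chosen so multinomial
sampling error on isoform fractions (≈ ±3 pp) is small against the
20 pp decision threshold, emulating the well-covered genes that dominate
differential calls.  The peak-profile generator plants clusters as
NB blocks with one dominant profile each and a 5% shared-source
fraction.

For enrichment experiments the generator also places peaks on gene
bodies: the uniform null uses a *balanced* design — the number of peaks
in each composition class (family × orientation, plus background) is
fixed at the class's exact base share by largest-remainder allocation,
positions uniform within class — so the realized composition tracks the
genomic one without Monte-Carlo drift while the marginal density stays
uniform; a planted preference places `min(1, m·f)·n` peaks wholly inside
sense instances of the target family, making the observed/expected ratio
equal to the multiplier by construction.  A fully i.i.d. mode exists for
convergence-style checks.

What the generator does **not** emulate: overlapping/nested genes,
transcript isoform structure, fragmented or nested repeat annotations,
mean-variance trends across the dynamic range, multimapping ambiguity,
internal-priming artifacts in 3′ ends, and batch effects.  Passing tests
therefore demonstrate correctness of the algebra and calibration and
power of the statistics under the planted model, not robustness to every
pathology of real libraries.

## Numerical and design choices

* Pseudo-counts: 0.5 on normalized counts before logs; shares use
  (f + 0.5)/(g + 1) so a share never reaches 1.
* Dispersion/variance floors: 1e-12 on moderated variances; the prior
  fit floors sample variances at 1e-12 before taking logs.
* Sentinels: log2 enrichment uses ±inf for one-sided zero fractions and
  NaN for 0/0, always flagged, never silently dropped.
* Tie-breaks are deterministic everywhere (reference peak: smallest p,
  then leftmost start, then id; host gene: longest overlap, then
  smallest id).
* Classification bands are used exactly as printed: strict inequalities
  for the padj and fold-change thresholds, inclusive thresholds for the
  APA support/shift rules ("at least").
* Empirical p-values (k-mer shuffling) use the add-one convention.
* Problem sizes in the test and acceptance suites (500-gene cohorts,
  5,000-feature calibration panels, 5,000-peak placements, 200-gene APA
  cohorts) are the package's standard desk-scale study conditions; all
  generators are seed-deterministic and byte-identical across reruns.

## Known limitations

* The moderated engine assumes exchangeable log-scale variances; there
  is no mean-variance trend fitting and no dispersion outlier handling.
* Usage tests propagate no uncertainty between the feature and its
  group beyond the delta-method/moderation approximation.
* The gene model (flattened exon unions) cannot represent isoform
  switches that do not change exon-level coverage.
* The shipped splice-site scorer is a toy; quantitative splice-strength
  claims require plugging in a trained model.
* The k-mer enrichment null is a mononucleotide shuffle; it preserves
  composition but not dinucleotide structure.
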