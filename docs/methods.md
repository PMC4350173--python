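# Methods

`cytohet` implements two complementary estimators of intra-organismal
genetic heterogeneity for coenocytic (multinucleate) fungi such as the
arbuscular mycorrhizal fungi (AMF), whose hyphae carry thousands of
nuclei in one cytoplasm. Both operate on pyrosequencing-style reads and
are validated end to end against a synthetic-data module with known
ground truth.

## 1. Sequence similarity network

### Model

Whole-genome shotgun reads are clustered without a reference: two reads
are *homologous* when their best local alignment (either strand)
contains at least 75 identical nucleotides, at least 25% identity
relative to the full length of the shorter read, and an e-value of at
most 1e-20. Clusters are the connected components with two or more
members; reads joining no cluster are *singletons*.

Two per-cluster variables summarize the network:

* **PID** — for an aligned pair, 100 × (identical positions) / (length
  of the shorter read); per cluster, the unweighted mean over its
  accepted pairs. Because the denominator is the whole shorter read and
  not the aligned region, partial overlaps score low and only reads
  covering essentially the same locus score above ~95. This makes the
  upper PID band a sensitive probe for *repeated, slightly diverged
  sequence* — the genomic signature of a heterokaryotic nucleus
  population.
* **Clustering coefficient** — accepted pairs divided by the maximum
  possible pairs (graph density, not local transitivity). 1 means every
  read overlaps every other (a "stack"); low values indicate
  contig-like chains.

Distributions of these variables between runs are compared with the
two-sample Kolmogorov–Smirnov test: D is computed by an exact ECDF
sweep over the pooled sample, and the two-sided p-value uses the
asymptotic Kolmogorov distribution with effective sample size
n_a·n_b/(n_a+n_b). (An exact small-sample p is not implemented; for the
cluster counts this package produces, the asymptotic form is adequate
and is what the D-statistic oracle tests pin down.)

### Alignment search

The original workflow used BLAT. Here candidate pairs are proposed by a
shared k-mer index (k = 11 by default, both strands, k-mers occurring
in more than `max_kmer_occ` reads skipped, at least `min_kmer_hits`
shared k-mers required) and verified by optimal local alignment
(Biopython `PairwiseAligner`: match +1, mismatch −2, gap open −3, gap
extend −1). N never counts as an identical position. The e-value is
Karlin–Altschul-style, E = K·m·n·e^(−λS), with λ ≈ 1.33 solved for the
+1/−2 scoring under uniform base composition, K fixed at 0.3, m the
shorter read length and n the total bases in the run. This reproduces
the thresholding contract; it is documented as an approximation, not
claimed identical to BLAT's e-value. Seeding parameters only propose
pairs — they can make the search miss a pair a full all-vs-all scan
would test (the oracle suite bounds this on small instances) but can
never relax the alignment thresholds.

### Minimum genome size

The published analysis summed Newbler contig lengths plus singleton
lengths. Assembly is out of scope here; instead each cluster is laid
out by propagating pairwise alignment offsets from an arbitrary root
along a maximum spanning tree of the cluster (weight = identical
positions, ties toward the lexicographically smaller pair), and the
cluster contributes the span of its placed reads. Total = Σ cluster
spans + Σ singleton lengths. This is validated by recovery on simulated
data (within 10% at deep error-free coverage), not by matching any
published megabase figure, which would require the original read sets.

## 2. Amplicon allele diversity

Reads from amplicon pyrosequencing of a putative single-copy marker
pass four elimination rules (perfect adaptor+primer prefix; no
ambiguous bases; mean quality ≥ 35 in every 50-bp window; no
homopolymer longer than 8 bp, checked after primer trimming). Surviving
reads are preclustered: unique sequences sorted by descending abundance
(ties lexicographic) merge, in a single pass, into the most abundant
earlier representative within 1 edit operation; representatives never
re-merge, so there is no transitive chaining.

The chimera screen replaces ChimeraSlayer with an explicit two-parent
crossover test against a reference allele set: per-position identity
profiles from global alignments give, for every split point, the best
left-prefix parent plus best right-suffix parent (parents distinct). An
allele is flagged when that model gains at least `improvement_min`
identities over the best single parent *and* the single-parent support
(percent identity over the allele) is below `min_support` (default
90%, standing in for the original's 90% bootstrap criterion). Two
consequences are worth knowing. First, the identity mapping makes the
90% gate very permissive: chimeras of parents under ~20% divergence
always exceed it, so against a complete, error-free reference set the
gate should be raised to 100. Second, `improvement_min` should be
`max_diff + 1` of the preclustering step: crossovers within `max_diff`
of a parent are absorbed by preclustering, and a larger threshold
leaves chimeras at exactly `max_diff + 1` differences undetected by
both stages.

Richness is summarized as S_obs, the count of alleles seen at least
twice (the conservative headline count), rarefaction by the exact
hypergeometric expectation E[S_n] = Σ_i (1 − C(N−N_i, n)/C(N, n)), and
the bias-corrected Chao1,

    Chao1 = S_obs + F1(F1−1) / (2(F2+1)),

with Chao's log-normal 95% interval on T = Chao1 − S_obs (collapsing to
[S_obs, S_obs] when F1 = 0). The bias-corrected form is chosen because
it stays finite at F2 = 0; with F1 = 0 it coincides with the classic
estimator, so the degenerate two-allele case (no singletons) gives
Chao1 = 2 with CI [2, 2] under either variant.

## 3. Recombination, reading frames, copy number

* **Rm** (Hudson–Kaplan): sites with exactly two states (columns
  containing gaps excluded; each distinct allele sequence counted once
  regardless of abundance) are tested pairwise; a pair showing all four
  gametes is incompatible. Rm is the maximum number of pairwise
  disjoint incompatible intervals: intervals properly containing
  another are dropped, then a left-to-right greedy scan counts
  disjoint intervals. Intervals sharing only an endpoint site are
  disjoint (events fall strictly between sites).
* **ORF integrity**: in-frame TAA/TAG/TGA before the final codon;
  frameshift = ungapped length differing from the modal ungapped length
  by a non-multiple of 3 (the source analysis counts events without
  defining them; mod-3 against the consensus is this package's
  documented rule).
* **Relative copy number**: Ct regressed on log10 concentration by OLS
  for target and reference dilution series; each target Ct is inverted
  through the reference line and the ratio is the geometric mean of
  effective/actual concentration. Identical curves give exactly 1
  because OLS residuals average to zero. Warnings are emitted for
  non-overlapping concentration ranges and for slopes differing by more
  than 10% (efficiency mismatch).

## 4. Marker screening

A candidate family passes when (1) its copy count is exactly 1 in every
required genome (absence fails), (2) the focal taxa are monophyletic —
some edge bipartition of the unrooted gene tree separates exactly the
focal set — and (3) the tree is compatible with every grouping in a
user-supplied constraint document (the operational meaning given here
to "canonical placement": each grouping, restricted to the tree's
taxa, must not conflict with any tree bipartition in the standard
four-intersection sense). Decisions are bipartition-based and hence
invariant under rerooting; polytomies conflict with nothing they do not
contradict. Alignment, masking and tree inference are upstream tools
whose outputs this module consumes.

## 5. Synthetic data

The generator emulates the study conditions end to end:

* **Genomes** — i.i.d. bases with per-base Bernoulli GC (default 0.28,
  the low GC typical of *Rhizophagus*); optional planted repeat
  families (motif length × copies × divergence) overwritten at
  non-overlapping positions.
* **Nucleus populations** — haplotypes carrying independent per-site
  substitutions at a configured rate relative to the base genome,
  sampled by proportions; a homokaryotic pool is the one-haplotype
  degenerate case.
* **Shotgun reads** — truncated-normal lengths (mean 336 bp, the
  platform's published average; sd 40, range 100–600 as this package's
  choice), uniform starts, random strand, per-base error rate 0.006
  (the 0.6% amplicon-run figure). With probability
  `homopolymer_weight` (default 0.5) an error realizes as a ±1 length
  change of the homopolymer run containing it — *only when the run has
  length ≥ 2*, since flow-space miscalls require an actual run; errors
  at singleton positions realize as substitutions. Qualities are a
  constant offset-33 score derived from the error rate, with an
  explicit `quality_score` override: 454 basecallers score
  homopolymer-dominated errors confidently, so a run can emit q38
  bases while its realized error rate is 0.6% — without the override,
  any error rate above ~3×10⁻⁴ would be self-rejecting under the q35
  window filter, which real data plainly is not.
* **Amplicon pools** — reads drawn from an allele frequency vector; a
  `chimera_rate` fraction formed by a single crossover between two
  distinct parents; primers emitted intact at the ends (errors are
  confined to the marker region so primer screening stays a controlled
  channel).

What the generator does **not** emulate: flowgram (.sff) signal, length
dependent quality decay, PCR-cycle-resolved amplification bias,
chimeras with multiple breakpoints, and real repeat landscapes.
Passing recovery tests therefore demonstrates the pipeline's
correctness under the stated error model, not performance on arbitrary
real 454 data.

## 6. Validation experiments and problem sizes

All validation runs at "desk scale": the published megabase estimates
required the original deposited runs and are out of scope.

* **Genome-size recovery** — 50-kb genome, error-free reads at 30×;
  the layout estimate must land within 10% of truth.
* **Amplicon recovery** — K = 6 alleles (pairwise ~6% divergent,
  200-bp marker), n = 800 reads, e = 0.006, chimera rate 0.03,
  frequencies all well above 5/n; after filter → precluster → chimera
  screen (complete reference set: support gate 100, improvement
  threshold 2 = max_diff+1), the count of alleles seen more than once
  should equal K. Residual failures (measured at ~2/30 seeds) are
  recurrent ±1 miscalls at long homopolymer runs reaching abundance 2 —
  the platform artifact the published analysis also wrestles with.
* **Heterokaryosis contrast** — a pool of two nucleus classes
  differing by 3% (a 150-kb base genome plus one derived haplotype,
  50/50) versus its homokaryotic control: the same base genome alone,
  sequenced with the same read count at 2× coverage, so the only
  difference between the runs is the second nucleus class.
  Per-cluster mean-PID distributions are compared by KS and by the
  count of clusters in the 95–100 PID band. A caution on
  interpretation: with read count and coverage matched exactly, the
  high-PID excess is intrinsically weak — cross-class reads covering a
  common locus score ≈ 95.8 PID (3% divergence plus twice the 0.6%
  error rate), straddling the band's lower edge, and the same-locus
  pair rate is identical between the two runs by construction. The
  dramatic published version of this signature involves comparing runs
  over genomes of *different* sizes (hence different coverage at equal
  read count); the matched design isolates the divergence signal
  itself, which shifts cluster mean PIDs by only ~1.5 points against
  an overlap-geometry spread of tens of points. The acceptance script
  reports the per-seed KS and band tallies so this can be judged
  directly.
* **Calibration** — realigned per-base error of a 0.6% run within 3
  binomial SE; empirical GC of a 100-kb genome within ±0.02 of the
  0.28 target.

## Known limitations

* The e-value model is not BLAT's; the 1e-20 cutoff acts through an
  effective score threshold of ≈ 49 under the documented constants.
* The cluster-span layout underestimates regions where coverage gaps
  split true contigs and cannot resolve repeat-induced cycles beyond
  the spanning-tree approximation.
* The asymptotic KS p-value is anti-conservative below ~25 clusters
  per side; comparisons in that regime should be read qualitatively.
* Chao1 is a minimum-richness estimator: with heavy-tailed allele
  frequency distributions the true richness may exceed the upper CI.
* The four-gamete approach attributes all incompatibilities to
  recombination; recurrent mutation at hypervariable sites inflates Rm.
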