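# Methods

This note records the models, conventions, and numerical choices behind
`kmerphylo`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the design was genuinely open.

## K-mer spectra as dosage proxies

A cell's genome is summarized by the multiset of its length-k read
windows. If a genomic segment is present at higher copy number, reads —
and therefore k-mer occurrences — from that segment arrive proportionally
more often, so after per-cell normalization the *relative abundance* of a
k-mer tracks the fraction of the genome (weighted by dosage) that carries
it. Differences between cells' abundance vectors then approximate
differences in genome copy-number content without any alignment. The
approach deliberately trades positional interpretability (which segment
changed) for robustness to the rearrangements that make tumor-genome
alignment unreliable.

Counting conventions:

* every window over {A,C,G,T} counts once; windows containing any other
  symbol are skipped (the simplest rule, matching common counter
  behavior);
* a k-mer and its reverse complement are distinct keys by default;
  `canonical=True` folds each window to the lexicographically smaller of
  itself and its reverse complement. Because sequencers read either
  strand, non-canonical spectra of the same genome are strand-mixed; all
  downstream statistics are invariant to this, but users comparing
  spectra to a reference sequence directly should either canonicalize or
  check both orientations;
* k-mers are packed into 2-bit integer codes (k ≤ 31) and matrices are
  sparse-first: at k = 15 a 40-cell dataset holds millions of
  sequencing-error singleton rows before filtering.

## Noise model and filtering

Three noise sources are handled explicitly:

1. **Sequencing error** creates low-multiplicity k-mers. The sparse filter
   zeroes per-sample counts below `min_count` (default 2 — one error is
   unlikely to recur identically in the same cell) and drops rows that
   become empty.
2. **WGA unevenness**: whole-genome amplification amplifies regions
   unevenly and cell-specifically, so a k-mer absent in one cell may
   reflect amplification failure rather than deletion. The strict
   presence filter keeps only k-mers observed in every cell; this
   preferentially retains amplifications and sacrifices sensitivity to
   true deletions. For amplification-free protocols,
   `presence_fraction < 1` relaxes the rule.
3. **Depth variation** is removed by Total Sum Scaling. The TSS
   denominator is the post-filter retained k-mer set, i.e. normalization
   happens after both filters; quantile-style global normalization is
   deliberately avoided because tumor cells genuinely differ in genomic
   content and ploidy.

Duplicate cells are detected on *raw* counts with exact equality (a
resequenced library reproduces its counts bit-for-bit; biological near
duplicates do not), and the lexicographically later member of each
duplicate group is dropped.

Filter bookkeeping is an enforced invariant: input k-mers =
sparse-removed + not-ubiquitous + retained, or `FilterReport` refuses to
construct.

## Feature selection

The IQR filter removes k-mers whose interquartile range across samples
lies in the first quartile of all k-mer IQRs — by construction ~25% of
rows when IQRs are distinct. Quantiles use linear interpolation between
order statistics; the Q1 boundary is inclusive (IQR ≤ Q1 is removed); if
every IQR is identical, nothing is removed and a warning is raised.

Differential abundance uses the two-sided Wilcoxon rank-sum test per
k-mer with Bonferroni control: keep raw p ≤ alpha/m, alpha defaulting to
0.001 and m the number of k-mers entering the test. The exact null
distribution is used whenever both groups have fewer than 50 observations
and the pooled values are tie-free (the switching rule of R's
`wilcox.test`); otherwise the tie-corrected normal approximation with
continuity correction. The switch matters: with 20 cells per class the
normal approximation cannot produce p below ~7e-8 and would leave the
Bonferroni-selected set empty for any m beyond ~15,000, while the exact
floor is 2/C(40,20) ≈ 1.5e-11. When the Bonferroni threshold falls below
the attainable exact floor for the given group sizes, the selector warns
that no feature can pass. A Benjamini-Hochberg alternative is available
behind `bonferroni=False`.

## Distances and trees

Euclidean distances on the TSS matrix feed the trees; Bray-Curtis (equal
to half the L1 distance on compositional columns, bounded in [0,1]) is
provided for ordination-style surveys. Distances are computed on the
presence-filtered, normalized matrix *before* differential selection —
selection is supervised by the class labels, and trees built on selected
features would presuppose the structure being tested. A flag enables the
alternative.

Neighbor joining follows the classic Saitou-Nei agglomeration and is
exact on additive matrices (verified to 1e-9 in the test suite).
Q-criterion ties are broken by joining the pair whose sorted node-label
pair is lexicographically smallest, with an internal node inheriting the
smaller label of the pair it replaces — fully deterministic, which
matters because consensus supports can shift at ties. The Q matrix is
evaluated on the upper triangle only, since the two float-summation
orders of Q(i,j) and Q(j,i) can differ in the last bit. Negative branch
lengths on non-additive input are kept and reported via a warning;
`clamp_negative=True` zeroes them and transfers the deficit to the
sibling branch so the joined pair's summed length is preserved.

Bootstrap replicates resample k-mer *features* (rows) with replacement —
the standard character bootstrap for distance trees; read-level
resampling would require re-counting. Row multiplicities are drawn
Multinomial(m, 1/m), and for Euclidean distances the weighted Gram
identity d² = x'Wx + y'Wy − 2 x'Wy turns each replicate into one BLAS
product. The default replicate count is 1,000 at desk scale;
larger counts are a parameter away. The consensus is extended
majority rule: all splits in > 50% of replicates, refined greedily with
compatible minority splits in descending frequency (the behavior of
standard consensus tools); supports are attached as internal node labels
in Newick output, or as bracketed comments on request.

## The separation statistic and its null

For labeled cells the statistic is

    T = mean within-class pairwise distance / mean between-class pairwise distance,

pooled over all classes (so three-stage designs work unchanged). T < 1
indicates class cohesion. The *mean* form is used rather than raw sums:
with unequal class sizes only the mean version is calibrated to 1 under
label exchangeability, which is what makes the permutation-null mean a
useful diagnostic (the sum form is available as `raw_sums=True` for
comparison). The test is one-sided — small T is the alternative — with
p = (1 + #{null ≤ observed}) / (1 + N) over N label permutations
(default 10,000), so p is never 0 and bottoms out at 1/(N+1) ≈ 1e-4.
Only permutations that happen to reproduce the class partition can tie
the observed value, so on genuinely clustered data p sits at that floor.

## Classification harness

Linear-kernel SVM and CART decision tree with library defaults; the
contribution is the feature pipeline and the reporting, not the learners.
Folds are stratified (necessary for imbalanced designs like 3:1
primary:metastatic), assignment is reshuffled each replicate from a
seeded generator, the per-replicate error is the misclassification rate
averaged across held-out folds, and the report stores all per-replicate
errors with min/median/mean/max/sd recomputable from them. Balanced
designs are obtained by uniformly subsampling the majority class without
replacement to the minority size.

## The read simulator

No trusted generative model exists for single-cell WGA sequencing, so the
simulator's distributions are explicit artifact choices:

* **Reference**: uniform-random sequence (default 100 kb) in near-equal
  segments (default 20) — large enough that k ≥ 13 k-mers are mostly
  unique, small enough for minutes-scale tests.
* **Clones**: per-segment non-negative integer copy numbers on a rooted
  clone tree; a cell genome is the concatenation of each segment repeated
  by its copy number.
* **WGA**: each (cell, segment) draws an amplification factor
  exp(Normal(0, wga_sigma)) multiplying that segment's read-sampling
  weight — log-normal for positivity and a heavy upper tail. Default
  wga_sigma = 0.2, i.e. segment amplification swings of roughly ±50% at
  two sigma: material unevenness, chosen so that a 3-fold copy-number
  change remains statistically detectable across 20-cell clones — the
  CNV-signal-dominant regime the method targets. (At 20x coverage,
  Poisson counting noise alone contributes ~0.27 log-CV per feature;
  much larger wga_sigma makes every per-feature test powerless at desk
  scale regardless of method.) Heavier noise is one config field away.
* **Reads**: single-end, fixed length (default 48 bp), count =
  round(coverage × genome length / read length) exactly; starts uniform
  within segment copies (reads never span copy junctions); each base
  substituted to one of the other three with probability `error_rate`
  (default 0.005); each read reverse-complemented with probability 0.5.
  Quality strings are a constant placeholder because no pipeline stage
  consumes them. Fixed seed ⇒ byte-identical output.

What the simulator does *not* model — and hence what passing tests do not
demonstrate about real data: PCR chimeras and adapters, indels and
structural-variant breakpoint reads, quality-score structure, GC bias,
repeat content, or the position-correlated amplification failures of real
WGA chemistry. Results on simulated data validate the pipeline's
statistical machinery, not its robustness to every artifact of real
libraries.

## Desk-scale defaults

Problem sizes used by the test suite and the acceptance script — 100 kb
genomes, 20 cells per clone, 20x coverage, k = 15, 10,000 permutations,
hundreds-to-1,000 bootstrap replicates — are the package's desk-scale
study conditions: big enough that every statistical mechanism (error-tail
filtering, presence filtering, exact-test granularity, bootstrap support)
operates in its intended regime, small enough to run in minutes on one
CPU. Real single-cell datasets (hundreds of cells, ~138x coverage,
gigabase genomes) differ mainly in scale, where the sparse-first matrix
design and the per-sample streaming counter are the relevant provisions.

## Known limitations

* The presence filter discards genuinely deleted regions; the method sees
  amplifications preferentially.
* Compositional closure means a large gain in one region depresses all
  other relative abundances; "differential" k-mers are therefore not all
  located in changed regions.
* Exact duplicate detection will not catch near-duplicate libraries.
* NJ consensus trees carry supports but no meaningful branch lengths.
* With fewer than ~15 cells per class, the exact rank-sum floor exceeds
  any stringent Bonferroni threshold and supervised selection is
  impossible; the selector warns in this situation.
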