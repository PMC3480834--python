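# Methods

## Model and rationale

miRNAs guide the RISC complex to mRNAs through base-pairing of the seed
region (miRNA nucleotides 2–8) with sites in the 3'UTR, and transcript
destabilization is the dominant detectable consequence. The pipeline
therefore treats "down-regulated after miRNA overexpression *and* carries
a seed site" as the operational definition of a candidate target, and
quantifies the global seed-site signal two ways: a set-based contingency
analysis and a set-free ranked-list word analysis.

### Seed sites

For a mature miRNA m (5'→3'), sites are reverse complements of the seed
on the mRNA sense strand:

* 6mer = revcomp(m[2..7]) — the "core"
* 7mer-m8 = revcomp(m[2..8]) = one extra matching base 5' of the core
* 7mer-1A = core + `A` — the A is a literal adenosine opposite miRNA
  position 1, regardless of what position 1 is
* 8mer = revcomp(m[2..8]) + `A`

Every site contains the core, so under mutually exclusive counting each
core occurrence is attributed to the single strongest class whose context
matches at that locus (8mer > 7mer-m8 > 7mer-1A > 6mer). This guarantees
the class counts of a gene sum to its raw core count — an invariant the
tests exploit. Overlapping core occurrences are each one candidate locus
(the simplest convention that a naive oracle can reproduce exactly).
Scanning is sense-strand only; windows containing N match nothing.
Non-canonical pairing (G:U wobble, bulges, 3'-compensatory sites) and
coding-region sites are out of scope.

### Gene sets

Fold changes are base-2 logs throughout. Thresholds are given as linear
fold changes and applied as |logFC| ≥ log2(fc_cutoff); at the default
1.1 that is ≈ 0.1375, inclusive on both sides (inclusivity is arbitrary
but must be fixed for determinism). "No-change" genes are the n nearest
zero in |logFC| among genes in neither tail, ties broken by gene_id; n
defaults to the down-set size so the down-vs-no-change comparison is
size-balanced. The variance filter removes genes whose sample variance
(denominator n−1) of log2 expression across all arrays falls below the
cutoff (default 0.25, absolute); because a "0.25 cutoff" can also denote
a quantile in non-specific-filtering practice, a quantile mode is
available behind a flag.

### Site enrichment

The primary statistic is the fraction of genes per set with ≥ 1 site of a
class (or of the pooled strong classes 7mer-m8 / 7mer-1A / 8mer), tested
with a two-sided Fisher exact test using the minimum-likelihood rule: the
p-value sums hypergeometric point masses ≤ the observed table's mass,
with relative slack 1e-7 on the comparison to absorb floating-point ties
(a χ² with continuity correction is available behind a flag). Two
descriptive modes complement it: mean total occurrences after repeatedly
subsampling every set without replacement to the smallest set's size
(default 1000 resamples, percentile 2.5/97.5 interval, explicit seed),
and occurrences per kb of pooled UTR sequence. The descriptive modes
carry no p-values.

### Word analysis

For word w with per-gene counts x_i and UTR lengths L_i along the list
ranked by ascending logFC (most down-regulated first, ties by gene_id):

    r_i = x_i / L_i,   u_i = r_i − mean(r),   R_j = Σ_{i≤j} u_i

R_n = 0 by construction; the statistic is D = max_j R_j, floored at 0.
Length normalization stops long UTRs from dominating; mean-centering
makes the profile a tied-down walk so a head-of-list excess is the only
way to achieve large D. The null is permutation of the gene order
(default 100 permutations): Z = (D_obs − mean D_perm) / sd(D_perm)
(sd with denominator n−1; Z set to 0 and a degenerate flag raised when
the null is constant, e.g. an absent word), and empirical
p = (1 + #{D_perm ≥ D_obs}) / (n_perm + 1). One permutation set is shared
by all 4^k words per run so ranks are mutually consistent; words are
ranked by descending Z with lexicographic tie-break. D is one-sided by
design — the scientific question is overrepresentation among
down-regulated transcripts — with max |R_j| behind a `two_sided` flag.

This is a self-contained running-sum statistic in the Sylamer/cWords
family, defined here in full rather than copied from any published
scoring; the Z of a max-statistic is *not* standard normal, so the null
tests assert calibration bounds (mean within ±0.2, sd within [0.7, 1.3]),
not distributional claims. BH correction of empirical p-values is left to
`scipy.stats.false_discovery_control` on the output table; the primary
ranking is the Z-score.

The all-words permutation loop is a numba kernel (counts are accumulated
in float64 from a float32 centered-rate matrix); the pure-numpy
single-word path is retained and the tests assert the two paths agree,
alongside an exhaustive-enumeration check of the permutation null at
n = 5 genes.

### Targets and correlation

Candidate targets are down-set genes with ≥ 1 strong site, sorted by
ascending logFC. The strong-site requirement deliberately excludes
6mer-only genes (weak sites are poor predictors individually). Pearson r
uses the exact transform t = r·sqrt(n−2)/sqrt(1−r²) on n−2 df for its
two-sided p (a permutation option exists); inputs are assumed already on
a suitable (e.g. log) scale.

## Synthetic data

The generator emulates exactly the structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| n_genes | 1000 | genes per study |
| utr_length_mean / sd | 800 / 400 nt | log-normal UTR lengths (moment-matched), clamped ≥ word length |
| gc_content | 0.45 | i.i.d. base model, typical mammalian 3'UTR GC |
| carrier_fraction | 0.3 | genes receiving one planted site copy at a uniform offset |
| planted_word | `TCATCTCA` | the miR-143 8mer by default |
| delta | 0.25 | mean extra logFC down-shift of carriers |
| sigma | 0.3 | logFC noise sd |
| n_arrays | 4 | replicate arrays per condition (treated + mock) |
| var_low / var_high / high_var_fraction | 0.05 / 0.6 / 0.3 | per-array noise variance mixture for the filter substrate |
| rho / n_samples | −0.22 / 184 | target correlation and cohort size for the paired vectors |

logFC_i = −delta·carrier_i + N(0, sigma²): the carrier effect is a mean
shift, matching the binary has-site framing (a per-site-count dose model
would be a straightforward extension). Each stage draws from its own
deterministic child of the scenario seed (`SeedSequence.spawn`), so any
stage regenerates independently and scenarios are bit-reproducible.

What the generator does **not** emulate: real UTR composition (Markov
structure, repeats, conservation), correlated co-expression between
genes, probe-level microarray effects, or site-context features (AU-rich
flanks, position within the UTR). Passing the recovery tests therefore
demonstrates that the statistics detect the planted association under the
assumed noise model, not that the pipeline's absolute p-values transfer
to any particular annotation of the human transcriptome — with real data
those depend on the UTR database version and array platform.

## Numerical choices

* Fisher: full-support hypergeometric summation via `scipy.stats.hypergeom`
  pmf (cached per margin set); if the observed table is the mode the
  p-value is returned as exactly 1.0.
* Word analysis: float32 centered rates, float64 accumulation; profiles
  reported by `running_sum_profile` are float64 and end at 0 within 1e-9.
* All thresholds inclusive; all tie-breaks lexicographic by gene_id/word;
  all TSV output deterministic in row and column order.
* Degenerate inputs fail fast with named errors (empty margins, zero
  lengths, < 3 genes for a permutation null, zero-variance correlation
  inputs); an empty down set degrades the pipeline's enrichment/target
  stages to header-only outputs with a warning rather than an error.

## Problem sizes used in the checks

The oracle and calibration tests run at: 1000 random sequences for
scanner/oracle equivalence; every 2×2 table with all margins ≤ 30 for the
Fisher oracle; 500 null studies (δ = 0) for the type-I rate of the
enrichment test and 200 for the word-Z calibration; 100 studies at
δ = 0.4, 30% carriers, k = 7, 100 permutations for planted-word recovery;
100 replicates at n = 184 for correlation recovery. These sizes give
binomial/Monte-Carlo error comfortably inside the asserted bounds while
keeping the default suite fast.

## Known limitations

* Gene-level presence (not occurrence dose) drives the primary
  enrichment statistic; occurrence-weighted alternatives are descriptive
  only.
* The no-change set is a sample of near-zero genes, not a model of the
  null fold-change distribution; with very few unassigned genes it can be
  smaller than requested.
* The permutation Z for extreme words saturates the empirical p at
  1/(n_perm+1); raise n_permutations when tail p-values (rather than
  ranks) matter.
* Identifier mapping between expression platforms and UTR annotations is
  the caller's responsibility; the UTR FASTA is treated as ground truth.
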