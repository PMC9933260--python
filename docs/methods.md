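# Methods

## The statistic: epiallele Jensen-Shannon distance

A sequenced bisulfite read reports the joint methylation state of the CpGs it
covers, so read-level data resolve allelic heterogeneity that per-CpG percent
methylation averages away. We define an epiallele locus as four CpGs within
60 bp of each other covered by at least 40 reads that call all four
positions; each qualifying read is collapsed to its count of methylated CpGs,
ℓ ∈ {0, 1, 2, 3, 4}, giving a 5-category frequency vector per locus per
sample. The 16 binary patterns are retained internally for diagnostics but
carry no statistics.

Disorder is measured against a reference distribution Q, the unweighted mean
of the frequency vectors of reference-age (young, 4-month by default)
samples, by default per tissue. The distance is the Jensen-Shannon distance
with base-2 logarithms:

    JSD(P, Q) = sqrt( (D(P, M) + D(Q, M)) / 2 ),  M = (P + Q)/2,
    D(P, M) = Σ_ℓ P(ℓ) log2(P(ℓ)/M(ℓ)),  with 0·log(0/·) = 0.

The midpoint mixture M guarantees both divergences are finite; JSD is
symmetric, satisfies the triangle inequality, equals 0 iff P = Q and 1 iff
the supports are disjoint. The last two endpoint identities are the
motivation for preferring JSD over Shannon entropy: a locus that is fully
methylated and one that is fully unmethylated both have zero Shannon
entropy, so per-locus entropy alone cannot register a complete,
directional switch; their mutual JSD is 1. Kullback-Leibler divergence
against the raw (non-midpoint) reference was rejected as the distance: it is
infinite whenever the sample occupies a category the reference lacks, which
read-sampling noise makes routine, and it does not satisfy the 0/1 endpoint
behaviour the statistic is meant to have.

Group-level change is summarized as the fold change of the mean JSD over all
(locus, sample) pairs in a group, (mean_old − mean_young)/mean_young, with
the plain ratio mean_old/mean_young emitted alongside since "n-fold" is
ambiguous between the two conventions. Loci missing in a sample contribute
nothing; nothing is imputed. Young samples are compared against a reference
that averages them in, which biases young JSD slightly downward and the fold
change slightly upward uniformly across groups; rankings across groups are
unaffected. Differences in JSD spread between groups are tested with the
Brown-Forsythe (median-centred Levene) statistic — robust to the skewed,
bounded JSD distribution — with a mean-centred option exposed; p-values are
Bonferroni-corrected over the pairs tested.

The turnover analysis correlates per-group fold change with the 30-day
tissue turnover rate, defined as 30 × the average fraction of cells replaced
per day, via Pearson correlation with a two-sided p. At least three shared
tissues are required; zero-variance inputs are an error, not a NaN.

## Per-CpG drift statistics

Sites are filtered to ≥ 20 reads in ≥ 75% of samples (boundary inclusive);
cells below coverage are treated as missing, which is distinct from an
observed (0, 0). Two-condition differential methylation pools counts within
each group and applies a 2×2 chi-square with Yates continuity correction;
multiple testing uses Benjamini-Hochberg (named in output headers), and a
site is called at |Δ| > 5 percentage points and q < 0.05. A config-exposed
variance-inflation factor (default 1 = plain chi-square) crudely accounts
for replicate overdispersion by deflating the statistic; it is an
approximation, not a replicate-level dispersion model.

The all-ages analysis tests each site's Spearman correlation ρ (average
ranks for ties; replicated ages are the expected design) of percent
methylation with age against a permutation null: age labels are shuffled
1000 times, the empirical p-value is p = r/n with r the number of replicates
whose |ρ| reaches the observed |ρ|, and a site is called hyper- or
hypomethylating at |ρ| ≥ 0.5 with p < 0.05. By default one shuffle per
replicate is shared across all sites, preserving inter-site correlation
under the null; per-site independent shuffles are available by flag. Sites
with under 3 distinct ages or constant methylation get ρ undefined, p = 1,
no call.

Compartment enrichment assigns each site exactly one of Promoter-CpGi,
nonPromoter-CpGi, Promoter-nonCpGi, nonPromoter-nonCpGi by point-in-interval
against user-supplied BED region sets (promoter coordinates are always an
input, never inferred), then tests a 2×2 table of in-compartment vs
all-other CpGs × significant vs not with Fisher's exact test. The 95% CI
uses the log-OR normal approximation; a zero cell is flagged and handled
with the Haldane 0.5 correction for the OR and CI only. Expression linkage
bins genes by promoter mean methylation into 0-10, 10-20, 20-50, 50-80,
80-100 percent (left-closed right-open, last bin closed, stated in output
metadata) split by CpG-island overlap, and correlates per-gene methylation
change with expression change within expressed/silenced strata.

## The simulator

The generative model embodies the replication-error hypothesis: methylation
maintenance errs at each division, so disorder accumulates in proportion to
lifetime division count. Each CpG on each allele is an independent two-state
Markov chain: per division an unmethylated CpG gains methylation with
probability ε_gain and a methylated CpG loses it with probability ε_loss. A
tissue's stem cells at age a months have undergone t = round(rate_tissue ×
a) divisions (rounding because Markov steps are integral); differentiated
cells receive `differentiation_divisions` (default 4) further divisions,
reflecting the short division path from stem cell to differentiated
epithelium. Expected per-CpG methylation follows
m_t = m_∞ + (m_0 − m_∞)(1 − ε_g − ε_l)^t, m_∞ = ε_g/(ε_g + ε_l), which the
test suite verifies empirically across parameter grids.

Key parameters, defaults and rationale:

- **ε_gain = ε_loss = 0.001 per CpG per division.** No measured per-division
  error rates are available to this package; 10⁻³ makes a 24-month
  high-turnover tissue (≈ 240 divisions) show clear but unsaturated drift
  (the drift factor 1 − 0.998²⁴⁰ ≈ 0.38) while a quiescent tissue stays
  near baseline. Scalars or per-compartment maps are accepted.
- **divisions_per_month** defaults (colon 10, small_intestine 8, blood 3,
  spleen 2, lung 1, liver 1, kidney 0.3, muscle 0.2, heart 0.1) are
  synthetic values ordered by the qualitative proliferation ranking of these
  tissues — intestinal epithelium fastest, heart/kidney/muscle nearly
  quiescent; they are inputs, not measurements.
- **initial methylation** is a fixed per-CpG genomic property drawn once per
  simulation from compartment-dependent ranges (CpG-island compartments low,
  0-0.15 and 0-0.3; non-island 0.2-0.8 and 0.6-1.0), so all samples of a
  study share each site's baseline, as real samples share a genome.
- **Geometry.** Epiallele loci are 4 CpGs placed inside a 60 bp window, loci
  2 kb apart, so the non-overlapping tiling rule recovers them exactly;
  singleton CpGs for per-site drift statistics sit ≥ 1 kb apart and can
  never form loci.
- **n_cells = 300, coverage_mean = 60** per sample by default; analyses in
  tests scale these up (to 5000 cells for closed-form checks, 400-600 reads
  for concordance) where the check demands tighter sampling error.
- **Pooling.** pool_size > 1 simulates independent mice whose read sets are
  concatenated before analysis, mirroring pooled DNA extraction. Stem and
  nonstem samples of the same (tissue, age) derive from the same simulated
  mice: nonstem pools are differentiated copies of those mice's stem pools,
  as marker-sorted fractions of one animal would be. "whole" samples are
  treated as differentiated bulk.
- **Randomness.** One root seed; per-mouse and per-sample streams are
  derived from it with a stable label hash, so adding samples to a design
  never perturbs existing ones, and identical config + design + seed
  reproduce every output file byte for byte.

Read sampling emulates RRBS shallowly: per-locus read counts are Poisson
with the configured mean, alleles are drawn with replacement, and emitted
per-CpG counts equal the column sums of the emitted reads, so epireads and
coverage files are mutually consistent by construction.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: sequence context and bisulfite conversion errors
(no FASTQ level), CpG-site-specific error rates beyond compartment
uniformity, clonal expansion, niche dynamics or selection among stem cells,
cell-type mixtures within "whole" tissue, batch and mapping artifacts.
Recovery results on synthetic data demonstrate that the statistics measure
what they claim under the stated generative model, not that any particular
tissue obeys that model.

## Window enumeration and other numerical choices

- Epiallele windows tile the sorted distinct CpG positions of a chromosome
  in non-overlapping consecutive groups of four, keeping a group only if its
  span is ≤ 60 bp. Disjoint loci keep per-locus statistics independent;
  whether overlapping windows should also be scanned is a genuinely open
  design point, and the brute-force oracle in the tests applies the same
  rule. Reads must call all four positions to count; partial reads are
  discarded, never imputed.
- Probability vectors are validated to sum to 1 within 1e-6; the computed
  Jensen-Shannon divergence is clamped to [0, 1] before the square root to
  absorb float rounding at the endpoints.
- Degenerate 2×2 tables (a zero margin) score chi-square 0, p 1 rather than
  erroring; degenerate correlation inputs (zero variance, too few points)
  raise typed errors so callers cannot mistake them for findings.
- Bismark-coverage percent columns are never trusted; counts are
  authoritative and percent is recomputed. CpG sites are strand-collapsed
  single 1-based positions; BED inputs are 0-based half-open and converted
  only at the reader boundary.
- The coverage/presence filter marks below-threshold cells absent before
  computing presence, so presence always refers to usable cells.

## Limitations

- The chi-square differential test treats pooled counts as one sample per
  group; between-replicate biological variance enters only through the
  scalar variance-inflation knob.
- The per-tissue young reference averages the young samples themselves, so
  their JSDs (and the fold-change denominator) carry a small self-reference
  bias, uniform across groups.
- Fold change is undefined when the young group's mean JSD is exactly zero
  (only possible with a single young sample identical to the reference);
  designs should include ≥ 2 young replicates per tissue.
- The simulator's division rates and error rates are stipulated, not
  estimated; conclusions about real tissues require real division-rate
  measurements.
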