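# Methods

## Data model

Calls live in a samples × SNPs `int8` array with codes 0 (homozygous
major), 1 (heterozygous), 2 (homozygous minor), −1 (no-call), bound to a
SNP panel (id, chromosome, position, major/minor allele, optional MAF).
Comparison groups come from a study-design table (subject, replicate,
experiment, platform, well). Positions are 1-based and carried as metadata
only; wells record plate layout and play no role in any statistic.

## Synthetic replicate studies

**Truth model.** Per SNP, a minor allele frequency p is drawn uniformly
from a configurable band (default [0.05, 0.5]); per subject and SNP a
genotype is drawn from the Hardy–Weinberg probabilities
((1−p)², 2p(1−p), p²). Subjects are unrelated (no trio structure) and SNPs
are independent (no linkage disequilibrium); a uniform-MAF HWE truth is the
simplest model under which every concordance statistic has a closed form to
calibrate against.

**Replicate error process.** Each designed replicate copies its subject's
truth; independently per call, with probability `nocall_rate` the call
becomes a no-call, otherwise with probability `call_error_rate` (e) it is
reassigned uniformly to one of the two other genotype classes
(`uniform_other`). Two replicates of one subject then agree at a co-called
SNP with probability (1−e)² + e²/2 = 1 − 2e + 1.5e²: both unchanged, or
both flipped to the same class. The default per-experiment error rates in
the pipeline configuration (0.003, no-call 0.005) put intra-group
concordance at ≈99.4%, the regime a modern array operates in. The
`direct_pairwise` scheme applies the same flip rule to a designated
reference call set instead of the truth, so expected concordance against
the reference is exactly 1 − e (every flip changes the class); it is the
natural way to dial a *pairwise* discordance, e.g. 0.012 for a
98.80%-concordant cross-platform pair. Whether real platform errors are
genotype-class flips or allele-level dropout is not identifiable from
concordance summaries; the class-flip scheme was chosen because its
calibration is exact, and an allele-level scheme was deliberately not
implemented. Errors are independent across replicates and SNPs — no batch,
plate or cluster-calling effects are simulated — so passing calibration
tests demonstrates correctness of the statistics, not robustness to
structured artifacts in real data.

**Low-quality arrays.** `inject_low_quality` converts an exact
round(f·n_hom) of one sample's homozygous calls to heterozygous (modeling
contamination/array failure, which pushes intensity clusters toward the
heterozygous cloud) and/or an exact fraction of its calls to no-calls.
Exactly one row changes; everything else is bit-identical.

All generator functions take mandatory integer seeds; there is no global
RNG state, and identical seeds give bit-identical matrices.

## Concordance

`co_called` is the default denominator (SNPs called in both samples);
`strict` divides by all N SNPs, treating a single-sided no-call as
discordant and a double no-call as agreement. Both are first-class and
reported with their denominators. Note that strict ≤ co-called is
guaranteed only when no SNP is no-call in *both* samples; double no-calls
count as strict agreements and can reverse the inequality. Summaries report
per-subject-per-group mean and sample (n−1) standard deviation over member
pairs, plus per-group and grand overall rows computed over all member pairs
(not means of means); SD is defined as 0 for a single pair.

Cross-platform comparisons run only on harmonized shared SNPs: SNPs are
matched by id, allele pairs reconciled as identical, swapped (major/minor
exchanged; homozygote codes remapped), strand-flipped (complemented), or
both; A/T and C/G SNPs are dropped as `strand_ambiguous` (complement and
swap are indistinguishable without frequency evidence), irreconcilable
pairs as `allele_mismatch`. The shared-SNP count is always available next
to the concordance. Harmonization is idempotent: re-harmonizing already
harmonized matrices yields all-identical mappings and unchanged calls.

## Replicate-based QC

Per array: call rate (called/total) and heterozygote rate (HET/called,
undefined at zero called SNPs). Within each (subject, experiment) replicate
group, a sample is flagged `het_outlier` when
|het − median(group)| > max(abs_floor, k·MAD). Defaults: abs_floor 0.02,
k 5, chosen so that (i) the MAD of a clean 4-replicate group at ≥20k SNPs
(binomial noise ~0.002–0.003) never lifts the threshold above the floor,
and (ii) the smallest injected inflation the package advertises as
detectable (5% of homozygous calls, a het-rate shift of ≈0.03 at typical
het rates) clears the floor with margin. Samples below `call_rate_min`
(default 0.95) are flagged `low_call_rate`. Degenerate groups: a singleton
cannot be evaluated (the median is itself; noted in the report); in a pair,
a het gap above the floor flags the replicate farther from the
experiment-wide median, since the within-pair median cannot localize the
outlier. `exclusion_impact` recomputes intra-group concordance with and
without flagged arrays, per group, to show the penalty of retaining them.
Vendor-software quality metrics are out of scope by design — the point of
replicate QC is to catch arrays those metrics pass.

## Odds-ratio simulator

Baselines are deterministic: the minor-allele total m = 2·n·maf must be an
integer (guaranteed on the default grids; otherwise a grid-alignment error),
the heterozygote count is the rounded HWE expectation 2·n·maf·(1−maf)
decremented by one if m−h is odd, and (m−h)/2 minor homozygotes absorb the
remainder. The allele frequency is therefore *exactly* maf in both
populations and the clean allelic OR exactly 1 — a stochastic baseline
would contaminate the error-only OR distribution. Noise at concordance c is
drawn at count level as multinomial transitions (stay c, move (1−c)/2 to
each other class), which conserves population size exactly and is
distributionally equivalent to per-individual Bernoulli perturbation (a
tested property, not an assumption). Noise applies to both populations by
default (`noise_target="both"`); a cases-only variant exists but is off by
default. The odds ratio is the allelic OR from the 2×2 allele table — the
GWAS-standard effect measure under the additive model; genotypic ORs are a
non-goal. A zero cell triggers the Haldane–Anscombe correction (+0.5 to all
four cells) unless disabled, in which case it is an error.

"Top 5%" is the 95th percentile, nearest-rank definition: the ascending
order statistic at index ceil(0.95·R). Each grid cell draws from an RNG
stream keyed on (seed, maf, concordance), so cell values are reproducible
independently of grid layout or evaluation order. Default configuration:
2,000 cases, 3,000 controls, 50,000 repetitions per cell, MAF 0.01–0.40 in
steps of 0.01, concordance 0.940–1.000 in steps of 0.001 (≈4 minutes on one
CPU at full scale). The test suite exercises a reduced surface —
MAF {0.05, 0.10, 0.20} × c {0.94, 0.97, 1.00} at 5,000 repetitions — which
is ample to verify exactness at c = 1, monotone decrease of the percentile
OR in both c and MAF (checked with a 0.005 Monte-Carlo tolerance), and the
strictly smaller inflation of a 5,000/5,000 cohort.

## Numerical and testing choices

- Calibration assertions use 5 Monte-Carlo standard errors of the relevant
  estimator at 10⁵ SNPs. For the 36-pair intra mean the variance is
  (per-pair variance)/12, not /36: pairs sharing a replicate are ≈50%
  correlated under the flip model.
- Pipeline stage seeds derive from the root seed via `SeedSequence.spawn`,
  making reruns byte-identical (checksummed in `manifest.json`).
- Genotype TSV carries no MAF column; panels read back from disk have
  MAF = NaN ("unknown"), which only truth generation requires. PLINK
  `.ped`/`.map` import infers major/minor orientation from observed allele
  frequencies (ties broken alphabetically); a monomorphic SNP's minor
  allele is recorded as "N" with a warning, and such SNPs cannot encode
  heterozygous or minor-homozygous calls on write.
- Figures (heatmaps, surface curves) are conveniences; every plotted number
  is first written as TSV and the TSVs are the tested surface.

## Known limitations

- The error model is exchangeable across SNPs and replicates; real arrays
  fail in structured ways (batch, plate, cluster-calling artifacts) that
  the generator does not emulate.
- Het-outlier detection assumes at least one clean majority within a
  replicate group; two simultaneously inflated replicates in a group of
  three can mask each other.
- Harmonization matches SNPs by id only; positional matching and
  frequency-based strand resolution of palindromic SNPs are not attempted.
- The simulator fixes equal MAF in cases and controls (a pure null); it
  does not model differential error between groups, LD, or significance
  testing of the simulated ORs.
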