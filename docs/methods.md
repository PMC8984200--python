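# Methods

This note documents the models, estimators and numerical choices behind
`keelscan`, what the synthetic-data generators do and do not emulate,
and the design decisions taken where several defensible options existed.

## Pool-Seq F_ST

Input is a biallelic two-pool allele-count table (chrom, 1-based pos,
ref/alt read counts per pool). Per site, frequencies are the raw
read-count ratios pᵢ = altᵢ/depthᵢ; heterozygosities are Hᵢ = 2pᵢ(1−pᵢ),
H_S = (H₁+H₂)/2, H_T = 2p̄(1−p̄) with p̄ the *unweighted* mean of the two
pool frequencies, and F_ST = (H_T−H_S)/H_T. Because 2p(1−p) is concave,
H_T ≥ H_S, so defined values always lie in [0, 1]; the estimator is
symmetric in pools and in allele labels.

Deliberate simplifications, each an extension point rather than an
oversight:

* no pool-size correction (Karlsson- or PoPoolation2-style unbiased
  pooled estimators are not applied): the plain plug-in heterozygosity
  ratio is the estimator of record here;
* equal pool weighting in H_T ("compound population" read as the
  average of the two pools), not depth- or size-weighting;
* no minimum-depth or MAF filter by default;
* sites with H_T = 0 (monomorphic across pools, or a zero-depth pool)
  are *flagged undefined and retained* so window SNP counts stay
  auditable; windows use only defined sites. Zero depth in both pools
  is a hard error.

**Estimator expectation under the simulator.** The generator draws each
population's frequency independently from the Balding–Nichols beta
Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p ~ U[0.05, 0.95],
where F is the per-population divergence. For two demes the
heterozygosity-ratio statistic has expectation ≈ F/(2−F) — about half
of F — because the two-deme "total population" captures only (d−1)/d of
the drift variance; a Weir-style moment estimate from the true
frequencies, which corrects that factor, recovers F itself. Tests and
examples therefore compare the per-SNP mean against F/(2−F), not F.
Binomial read sampling at depths 180x/240x adds a small positive offset
(≈ (1/d₁+1/d₂)/4 ≈ 0.002 at these depths). None of this affects the
window scan, which is a *relative* outlier analysis.

## Window scan and candidate regions

Windows are 50 kb sliding by 25 kb (step must divide the window so the
tiling has no gaps), anchored at coordinate 0 of each chromosome,
0-based half-open; a 1-based site p belongs to every window with
start ≤ p−1 < end, which prevents double counting at boundaries. The
window statistic is the mean per-SNP F_ST over defined sites;
`min_snps` (default 1, since sparse windows are legitimately reported
in this design) filters noisy windows if desired, and window ends are
truncated at the chromosome end when lengths are supplied.

The outlier threshold is the mean of the top ⌈fN⌉ windows by mean F_ST
(f = 1% by default; ties at the cutoff all included; ⌈·⌉ guarantees at
least one window). The alternative reading — the (1−f) quantile
itself — is available as `threshold_mode="quantile"`, and a manual
`threshold=` override supports the common practice of hand-rounding the
empirical value. Windows *strictly above* the threshold are selected
and overlapping or bookended windows merge into maximal candidate
regions carrying the max window value and the number merged; merging is
what turns a set of 50%-overlapping windows into disjoint regions.

## Read filtering

Three whole-read rules, applied in order so every read is tallied in at
most one category: (1) exact substring match of a user-supplied adapter
sequence; (2) N fraction strictly greater than 10%; (3) strictly more
than 50% of bases with Phred quality (offset 33) strictly below 10.
"Strictly" is deliberate throughout: a read at exactly 10% N or exactly
50% low-quality bases is kept. Reads are removed whole, never trimmed,
and the filter is idempotent. Partial/overlap adapter detection of the
fastp kind, quality trimming and paired-end mate handling are out of
scope.

## Animal model and Gibbs sampler

The model is y = Xb + Za + e with cage tier (down/middle/up) as a
one-hot fixed effect (no intercept, hence full rank), breeding values
a ~ N(0, A σ²ₐ) and residuals e ~ N(0, I σ²ₑ). A⁻¹ comes directly from
Henderson's rules; the Mendelian-sampling variance coefficient is 1/2,
3/4 or 1 for two/one/zero known parents, optionally adjusted by
Meuwissen–Luo inbreeding coefficients (off by default: the simulator
ignores inbreeding too, appropriate for an outbred commercial strain, so
the default model matches the data-generating process; the flag exists
for real pedigrees).

Sampling is single-site Gibbs on the mixed-model equations: each fixed
effect and each breeding value is drawn from its univariate normal full
conditional (for breeding value i the precision is nᵢ + λA⁻¹ᵢᵢ with
λ = σ²ₑ/σ²ₐ), then σ²ₐ and σ²ₑ from scaled inverse-chi-square
conditionals. The per-individual sweep is a numba kernel driven by a
pre-drawn vector of standard normals from a single seeded
`numpy.random.Generator`, so chains are bit-reproducible. Priors are
scaled inverse-chi-square with df 4 and scales splitting the observed
phenotypic variance 50/50 — weakly informative, overwhelmed by n in the
thousands. Chain defaults: 20,000 iterations, 5,000 burn-in, thin 10.
Posterior standard deviations are reported in the "SE" slots of the
summary, mirroring how variance-component software prints standard
errors next to estimates.

Two response scales are shipped because the published residual
variances (0.120, 0.201) are incompatible with a threshold model's
fixed unit residual, implying the score was analysed numerically:

* **linear** (default): the 1–4 score, or any continuous column (the
  simulator's `latent` column enables exact parameter-recovery tests),
  treated as Gaussian;
* **threshold**: liabilities sampled from truncated normals between
  fixed probit cutpoints derived from the observed category
  frequencies, σ²ₑ ≡ 1; data with fewer than two observed categories
  are rejected (cutpoints at ±∞ leave the liability unidentified).
  Liability-scale h² from ordinal data is attenuated relative to the
  latent truth when cutpoints are fixed from marginal frequencies; the
  mode is provided as the statistically principled alternative, not as
  the reference estimator.

`em_reml` is an independent dense EM-REML implementation of the same
linear model (MME solve per iteration, σ²ₑ ← y'ê/(n−p),
σ²ₐ ← (â'A⁻¹â + σ²ₑ tr(A⁻¹C^aa))/q), used to cross-validate the
sampler's posterior means; it is O(n³) per iteration and intended for
n up to a few thousand.

## Enrichment

Candidate genes are those with ≥1 bp overlap (0-based half-open; mere
adjacency does not count) with any candidate region, each reported once
with the best overlapping window F_ST. Any-overlap was chosen over
containment as the inclusive, conventional rule. Per gene-set term the
p value is the exact hypergeometric upper tail P[X ≥ k] (identical to
one-sided Fisher on the 2×2 table), with BH step-up adjustment across
terms. The universe defaults to all genes in the supplied annotation;
ortholog conversion is a plain two-column mapping table, never a remote
lookup. Note that the BH adjustment is not a projection: re-adjusting
already-adjusted values inflates them, so adjusted p values are always
computed from raw p values exactly once.

## Phenotype statistics

The cage-tier association is the Pearson chi-square of independence on
the 3×4 tier-by-level table (df 6, no continuity correction, expected
counts reported; zero margins rejected). Production traits use one-way
ANOVA across KB levels with Tukey HSD at α = 0.05 (Bonferroni-corrected
t tests available), summarised by a Piepho-style insert-and-absorb
compact letter display: start from one letter covering all groups,
split any letter containing a significantly different pair, absorb
subsets. Lettering schemes are not unique; this scheme guarantees that
two groups share a letter iff they are not significantly different,
and the sharing structure is invariant to group relabelling. Levels
with fewer than two observations are dropped with a warning; all-equal
trait values raise an error rather than returning an undefined F.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* the analyses
assume, at the study's own design points: pools of 36 and 48 at 5x per
individual (fixed per-pool depths 180x/240x, so depth assertions are
exact; Poisson depths behind a flag), a neutral background F with
localised sweep regions of higher F, variance components
σ²ₐ = 0.043 / σ²ₑ = 0.120 (h² = 0.264), an ordinal 4-level score from a
latent Gaussian with three increasing cutpoints (defaults chosen to
give a realistic severity distribution of roughly 45/35/15/5%), and a
modest bottom-tier cage effect (+0.15 on the latent scale) reflecting
the reported direction of the cage-height association. Pedigrees are
paternal half-sib: 20% of each generation serve as sires, every dam
produces `family_size` offspring by one random sire — a modelling
choice, since the real flock structure of the ~1,600 hens is not
recorded. FASTQ fixtures plant *exact counts* of violating reads so
filter tallies are deterministic rather than binomial.

Not emulated, and therefore not demonstrated by passing tests: linkage
disequilibrium (sites are independent, so the scan's false-positive
clustering behaviour on real, correlated data is untested), sequencing
error and mapping artefacts (counts are clean binomial draws),
inbreeding accumulation, selection over generations, sex chromosomes,
and any realism of read sequences beyond quality strings.

## Problem sizes and numerical notes

Default test/acceptance scales were chosen to exercise the claimed
behaviour at the study's stated conditions while staying desk-sized:
20,000 SNPs / 2,000 windows and 50 replicates for sweep recovery
(250 kb sweep at F = 0.3 on background 0.02 — about 12 of the 20
top-1% windows, which keeps the empirical threshold well below the
sweep windows' means and makes single-region recovery the expected
outcome); ~5,500 individuals and a 20,000-iteration chain for
parameter recovery; ~2,000 individuals for the EM-REML cross-check;
1,000 replicates for test calibration. Random draws everywhere come
from seeded `numpy.random.Generator` instances; fixed seeds give
bit-identical tables, chains and files. Degenerate inputs fail loudly
and specifically: both-pools-zero depth, unsorted site tables,
non-topological pedigrees (which also catches cycles), confounded
fixed-effect levels, single-category ordinal data, empty window tables
and zero-margin contingency tables all raise with messages naming the
offender.

## Known limitations

The F_ST estimator ignores pool sizes, so it does not correct the
finite-pool sampling bias a Karlsson-type estimator would remove; the
sweep scan has no per-window significance (the empirical percentile
threshold is a ranking device, not a test); threshold-model cutpoints
are fixed rather than sampled, attenuating liability-scale h²; EM-REML
is dense and cubic; and the enrichment universe is whatever annotation
the caller supplies, which on real data is a consequential choice.
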