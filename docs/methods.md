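# Methods

`imfnet` reimplements, as a tested pipeline, a common systems-genetics
strategy for finding putative regulators of a quantitative trait
(intramuscular fat, IMF) from an extreme-group RNA-seq design: predict
genomic breeding values for a genotyped population, sequence the transcriptome
of the k highest and k lowest animals, test for differential expression,
build a co-expression network per group, and score transcripts by how their
connectivity and wiring differ between the groups.  Because studies of this
design rarely deposit raw data, the package ships a synthetic-study generator
that emulates the statistical structure of such an experiment, so that every
stage — and the pipeline end to end — is testable without any download.

## Genomic prediction (gblup)

The animal model is `y = Xb + Zu + e` with `Var(u) = G σ²m` and
`Var(e) = I σ²e`.  `G` is VanRaden's genomic relationship matrix
`WW′ / (2 Σ pⱼ(1−pⱼ))`, where `W` holds allele dosages centred at twice the
allele frequency.  Fixed effects default to an intercept, a
contemporary-group class and a (centred) carcass-weight-style covariate.

Variance components are estimated by EM-REML.  Each iteration applies

σ²ᵢ ← σ²ᵢ + (σ⁴ᵢ / n) · (y′PVᵢPy − tr(PVᵢ)),

whose fixed point solves the REML score equations.  All quantities are
evaluated in the eigenbasis of `K = ZGZ′`, computed once, so an iteration
costs O(np) and tens of thousands of iterations are cheap.  Components are
floored at `1e-8·Var(y)`; convergence is declared when the per-iteration
change in both components, scaled by `Var(y)`, falls below `1e-6`.  The
scaled-absolute criterion matters at a zero boundary, where EM steps shrink
geometrically and a component-relative test would never trigger.  At desk
scale (n = 500, m = 2000 independent SNPs) the likelihood carries limited
information about h²: the per-replicate standard error is ≈ 0.1–0.13, so
recovery is assessed on the mean across replicates, which is unbiased to
within ±0.02 except for boundary truncation near h² = 0.1 (≈ +0.02).

GEBVs solve Henderson's mixed-model equations with `λ = σ²e/σ²m` and `G⁻¹λ`
in the random block; marker-based `G` is stabilised by adding 0.01 to its
diagonal before inversion (configurable; an identity relationship is used
as-is so the closed-form shrinkage identity `û = (y−ȳ)/(1+λ)` holds
exactly).  Extreme groups are the k largest and k smallest GEBVs with a
stable (value, id) tie-break; group phenotypes are compared with Welch's
unequal-variance t-test, the R default.

## Differential expression (diffexpr)

Counts are filtered by three rules: drop genes with zero total, with an
average below one read per sample, or expressed (count > 0) in fewer than
three samples.  Size factors are median-of-ratios against the geometric-mean
reference over all-positive genes.  Per-gene NB dispersions
(`Var = μ + αμ²`) come from the method of moments on normalised counts,
pooled across all samples; a trend `α(μ) = a₀ + a₁/μ` is fitted by least
squares over the unfloored gene-wise values.

The test is the conditioned NB exact test on the two group sums: under a
common per-sample null mean `q₀` (the pooled mean of normalised counts),
each group's sum is NB with mean `q₀ΣS` and variance `q₀ΣS + αq₀²ΣS²`; the
two-sided p-value sums the probabilities of all splits of the conditioning
total that are no more likely than the observed one.  Splits are enumerated
directly up to a total of 1e5; above that the enumeration window is set by
far quantiles of both group distributions and the neglected tail mass is
asserted below 1e-10.  Genes with a zero total get p = 1 so the BH input
length is stable; BH adjustment is step-up with a cap at 1, and the DE flag
is `padj ≤ fdr` (default 0.10, with a secondary 0.20 list feeding
enrichment).

Dispersion sharing defaults to the fitted trend ("fit-only").  Gene-wise
moment estimates at 7 + 7 samples are extremely noisy, and taking
`max(gene-wise, trend)` doubles down on that noise in one direction: in
global-null NB simulations at the study's scale it pushes the fraction of
raw p < 0.05 down to ≈ 0.03, while the trend alone keeps the test near its
nominal level (≈ 0.048).  The conservative maximum remains available via
`sharing="maximum"`.

## Co-expression networks (pcit)

Expression is FPKM (`k·10⁹ / (L·N)`), correlated on the `log2(FPKM+1)`
scale by default (`scale="fpkm"` is available; the raw-FPKM scale is
dominated by the most abundant genes).  For every gene trio the three
first-order partial correlations are computed, a local tolerance
`ε = mean(partial/direct)` is formed, and edge (x,y) is eliminated if some z
satisfies `|r_xy| < |ε·r_xz|` and `|r_xy| < |ε·r_yz|`; an edge is significant
if no trio eliminates it.  Direct correlations of exactly zero make the
tolerance undefined, so such trios abstain; |r| is clipped at 0.999999
before denominators.  Group networks keep PCIT-significant pairs with
absolute direct correlation ≥ 0.90.  The trio scan is O(n³) (a compiled
kernel; ~2000 genes per group in under a minute) and a configurable gene
cap (default 5000) guards against accidental genome-scale calls.

One subtlety the tests document: the tolerance is multiplicative, so a
perfectly mediated edge (`r_xy = r_xz·r_yz`) is only eliminated when the
chain is of moderate strength — for an `r_xz = r_yz = c` chain, elimination
requires `c·√(1+c²) < 2/3` (c ≲ 0.61).  Strong cliques survive PCIT intact;
the |r| ≥ 0.90 floor is what keeps such networks sparse.

## Differential hubbing and impact scores (impact)

DH is the difference in a transcript's significant-connection count between
the two group networks, `DH = k_high − k_low` by default (the sign is
configurable since the field's phrasing "between the low and high group" is
used both ways); top-k lists break ties by gene id.  PIF per gene is
`ā·d` with `ā` the average and `d` the difference of group-mean
log2(FPKM+1).  Candidate regulators are all transcripts with at least one
edge in either network.  For candidate i against DE genes j:

RIF1ᵢ = mean over j of PIF_j · (r_ijH − r_ijL)²
RIF2ᵢ = mean over j of (ē_jH·r_ijH)² − (ē_jL·r_ijL)²

with correlations computed within each group and self-pairs excluded (the
mean runs over pairs actually summed).  The cited literature does not print
a single canonical formula — published uses describe the calculation as
modified — so these forms are fixed here as the package's definitions and
unit-tested, including the group-swap antisymmetry of PIF, RIF1 and RIF2
and the location/scale invariance of RIF1 in the candidate's expression.
RIF scores are reported raw and z-scored (sample sd, n−1).

## The synthetic study (simdata)

One integer seed drives a hierarchical `SeedSequence`, so stages are
independently reproducible and the whole bundle is bit-identical across
runs.  Defaults emulate the target design at desk scale: 200 animals × 1000
independent HWE SNPs (maf ~ U(0.05, 0.5)), a trait with h² = 0.29 built from
100 of those SNPs (genetic variance scaled exactly, residual drawn), total
variance 0.686 and mean 3 to echo an IMF-like percentage scale, 7 + 7
extreme-GEBV groups, and 2000 genes with 60 DE (|log2FC| = 2 split evenly
between groups) and two planted regulators with 20-gene modules coupled at
0.9 (high) versus 0.2 (low).

Counts are NB (gamma–Poisson, dispersion α = 0.05; α = 0 is exactly
Poisson) around `2^x · (L/1kb) · depth`, with gene lengths ~ U(0.5, 5) kb
and per-sample depths Poisson around 2e7 reads.  Baseline log2-means are
N(8.5, 1.5), putting the median gene near 10³ reads and ~20 FPKM — the
per-gene depth of a ~40× muscle transcriptome — so the log2(FPKM+1) offset
is negligible for typical genes.  The emitted library sizes are the true
simulated depths and are the intended FPKM denominators: the generator only
emits the analyzed gene subset, and real total-mapped-read counts are
dominated by the rest of the transcriptome, so normalising by subset column
totals would inject a shared factor with no genome-scale analogue (at n = 7
it manufactures pathological hub structure).

The planted wiring works as follows.  Each regulator r has a latent
activity a_rs per sample, standardised within each group so that the
coupling is the realised within-group correlation scale on every draw, not
just in expectation.  A target in group g gets
`signal_sd · (c_g·a_rs + √(1−c_g²)·η)` added to its log2-mean
(signal_sd = 2 log2 units), giving regulator–target correlation ≈ c_g and
target–target correlation ≈ c_g².  The regulator itself is emitted as a
well-expressed transcript (baseline loc + 1.5 sd) whose measured profile is
the activity plus small noise (0.1 log2 units) — a low-abundance regulator
would violate that premise mechanically through Poisson noise and the log
offset.  Regulator targets are drawn from the DE set first
(`de_target_frac`, default 1.0): regulator scoring operates on
regulator–DE correlations, so a generator whose wired modules were disjoint
from its DE genes would carry no recoverable regulator signal at all.  The
DE targets of one regulator share a DE direction, since a mixed-sign module
cancels in PIF-weighted RIF1 by arithmetic rather than biology.  DE/target
overlap and directions are recorded in the emitted ground truth.

What the generator does not emulate: linkage disequilibrium and pedigree
structure among SNPs, read-level sequencing artefacts, compositional
normalisation effects, count outliers, and correlated biological covariates
(batch, breed, diet).  Passing tests therefore demonstrate statistical
correctness of the methods under a clean generative model, not robustness
to real-data pathologies.

## Validation experiments and their limits (validation)

Three canned studies are shared by the test suite and the acceptance
script: REML recovery (50 replicates × h² ∈ {0.1, 0.29, 0.5} at n = 500),
exact-test type-I error (20 global-null replicates × 2000 genes at 7 + 7),
and planted-regulator recovery (20 seeds; 200 genes, one regulator, 20-gene
module coupled 0.9 vs 0.0, 7 + 7 samples; scored by attaining the maximum
DH and ranking in the top 5% by |RIF1 z|).

The recovery experiment deserves a caveat that the package reports rather
than hides.  With coupling 0.9, the regulator–target correlation is 0.9
while target–target correlations are forced to ≈ 0.81 by positive
semidefiniteness — so at the 0.90 edge threshold the regulator's own edges
are roughly coin flips at 7 samples per group, and a lucky module member,
or a background gene whose 7-sample profile happens to align with the
latent activity, overtakes the true hub in a substantial fraction of draws.
An idealised noiseless version of the design (pure Gaussian signals, exact
activity tracking) succeeds in only ~2/3 of draws on each criterion and
about half jointly; the full count-level pipeline achieves somewhat less.
More samples do not rescue the joint score: with 12 + 12 the maximum-DH rate
reaches ~0.9, but background |r| ≥ 0.9 edges vanish, the candidate list
collapses to the module itself, and a top-5% rank among near-identical
scores becomes arbitrary.  This is a statement about the information content
of 7-sample correlation networks, and it is the reason single-study top-DH
and RIF lists should be read as hypothesis generators, not detections.

## Orchestration (pipeline, cli, io)

`run_pipeline` executes simulate → GBLUP + selection → filter + DE →
FPKM + PCIT per group → DH + RIF/PIF → over-representation, writing each
stage's TSV/JSON outputs before the next stage starts and finishing with a
manifest (tool version, config snapshot, seed, output checksums, stage row
counts).  A stage failure aborts with the stage name and preserves earlier
outputs.  When no gene-set file is supplied, the enrichment stage tests the
DE list (FDR ≤ 0.20) against the planted modules plus size-matched random
sets — a built-in positive/negative control.  The `imfnet` command exposes
`simulate`, `gblup`, `de`, `pcit`, `impact`, `enrich` and `pipeline`; all
tabular formats are tab-separated UTF-8 with Unix newlines, and every
writer/reader pair round-trips.
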