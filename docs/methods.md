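# Methods

This note documents the models, conventions, defaults and known
limitations of `dmsallo`. It is written for users who need to know
exactly what each stage computes and why the design is the way it is.

## Selection model and the synthetic-data generator

The simulator (`dmsallo.simulate`) emulates a pooled competition
experiment in a turbidostat: a saturation-mutagenesis library plus the
unmutated reference allele grow exponentially in continuous culture,
samples are drawn at 0, 4, 8, 12, 16, 20 and 24 h in three vials per
illumination condition, and each sample is sequenced to a fixed depth.
For variant *a* with initial abundance `x0_a` and true relative growth
rate `rgr_a` (h⁻¹, reference ≡ 0), the expected population share at
time *t* is

    p_a(t) = x0_a exp(rgr_a t) / Σ_b x0_b exp(rgr_b t)

and observed counts are one multinomial draw of size `depth` from
`p(t)`. Because shares are renormalized, any growth rate common to all
alleles (the dilution-balanced absolute growth of the culture) cancels;
only differences from the reference are identifiable, which is exactly
the quantity the downstream estimator targets.

Defaults encode the study conditions the pipeline is meant for:

| parameter | default | rationale |
| --- | --- | --- |
| timepoints | 0–24 h, step 4 | the assay's sampling schedule |
| replicates | 3 lit + 3 dark | triplicate vials per condition |
| depth | 10⁶ reads/sample | typical HiSeq amplicon allocation; a free parameter of the design |
| μQ | 30 | the quality scale of the error model and read filter |
| rgr mixture | 15.5% neutral (σ 0.01), bulk N(−0.084, 0.04), 22% null at −0.8 h⁻¹ | reproduces the observed fitness spectrum of an unoptimized chimera: a deleterious bulk with median ≈ −0.084 h⁻¹ and ~22% of variants depleted before three timepoints |
| dropout | 7.5% | fraction absent at t = 0 (library construction losses) |
| allosteric fraction / scale | 5%, ±0.03 h⁻¹ | sparse, modest light-dependent effects |
| reference weight | 5% of the t = 0 population | keeps `N_WT` large in every sample |
| abundance log-sd | 0.3 | mild library imbalance |

Allosteric effects are additive in log-growth space
(`rgr_lit = rgr_dark + Δ`), mirroring the statistic the analysis
estimates. One master seed drives everything; each sequencing sample
gets an independent stream derived deterministically from
(seed, condition, replicate, timepoint), so any single sample can be
regenerated without simulating the rest.

Simulated reads are pre-merged single records spanning the amplicon
(read-pair merging is out of scope). Per-base qualities are drawn
around μQ (default σ 3, clipped to [2, 41]) and each base is miscalled
with probability `10^(−q/10)` consistent with its recorded quality,
uniformly to one of the three other bases. The generator does **not**
emulate PCR amplification bias or chimeras, position- or cycle-specific
quality decay, index hopping, strand asymmetries, protein-abundance
artifacts, or coupling between vials. Passing tests therefore show the
estimators are correct under multinomial sampling and Phred-consistent
miscalls — not that they are robust to every artifact of real
libraries.

## Read counting

A read is discarded if any base of the mutagenized coding region falls
below Q30 (the cutoff is configurable; the default matches the
pipeline's quality convention). Kept reads increment the reference
count if they match the reference coding sequence exactly, a
(position, codon) entry if exactly one codon differs, and a separate
multi-mutant tally otherwise; kept + discarded + multi-mutant +
length-rejected always equals total. Coordinates are 0-based half-open
internally and 1-based residue numbers in every report. Because the
library was built with NNS primers (N = A/C/G/T, S = G/C), codons with
A or T in the third position cannot be genuine library members and are
excluded when codons are pooled into amino-acid counts; nonsense codons
pool under `*`.

## Sequencing-error model

The normative correction is the pipeline formula

    N_errant = N_source · (10^(−μQ/10))^HD

for each codon at Hamming distance HD (≤3) from a source codon. This
deliberately omits the binomial factor `C(3,HD)` and the `(1−p)^(3−HD)`
survival term of the exact per-base model, and treats the per-base
error rate as the rate of each specific substitution; the exact
variant is available as `binomial_errant` for comparison, but the
simple formula is what the correction applies. All expected flows are
computed from the raw table and subtracted simultaneously
(order-independent), and negative results are floored at zero since
counts are non-negative by construction.

The reference allele is corrected symmetrically: its count is reduced
by the total expected outflow into the alternative codons of the
table's positions (plus the inflow it received from mutants). Strictly,
the raw reference count never contained the outflow reads — they were
observed in mutant bins — so this overshoots as an estimate of the true
reference abundance. It is retained because it is the correction the
pipeline convention defines, and because it is a constant per-sample
factor on `N_WT` it cancels exactly in the log-ratio normalization
that follows; no downstream slope is affected.

## Growth rates and data categories

Frequencies are normalized as
`f_a(t) = ln(N_a/N_WT)_t − ln(N_a/N_WT)_0`, so `f_a(0) = 0` exactly and
the reference's own trajectory is identically zero. Timepoints where
either count is zero are dropped rather than imputed (the log is
undefined, and depletion is informative). Slopes are ordinary least
squares with intercept, fitted per replicate and then averaged; the
per-replicate layout matches the exported table (three lit columns,
lit mean/sd, three dark columns, dark mean/sd).

Classification is hierarchical: `no_data` if the variant is absent or
has ≤50 reads at t = 0 in any replicate (sentinel −1000), `null_data`
if eligible but lacking three usable timepoints somewhere (sentinel
−999), else `measured`. The three categories partition the designed
library (3021 for the full 159-position scan). Before allostery
analysis, measured variants with mean rgr at or below −0.13 h⁻¹ in
**either** condition are excluded: that empirical cutoff corresponds to
a catalytically crippled active-site control, below which variants are
effectively inactive and their slopes — often fitted from the minimum
three early timepoints of a collapsing trajectory — are the least
reliable in the dataset. The either-condition rule was chosen over
per-condition filtering because an inactive enzyme is inherently
non-allosteric regardless of which condition crossed the threshold.

## Allostery statistics

`Δ = mean(rgr_lit) − mean(rgr_dark)` with `exp(Δ)` as the in-vivo
proxy for the mutant's change in lit/dark velocity ratio, valid in the
log-linear regime of the growth–velocity calibration. Significance is
Welch's unequal-variance t-test (Welch–Satterthwaite degrees of
freedom, two-sided). Degenerate inputs follow a documented convention:
two exactly-constant groups give p = 1 when equal and p = 0 otherwise;
fewer than two finite replicates in a condition excludes the variant.
Note that with triplicate groups the Welch test is conservative under
an equal-variance normal null — the acceptance script measures a
rejection rate of ≈3.5–3.7% at p<0.05 rather than the nominal 5%
(R's `t.test` reproduces the same rate); only the pooled Student's
test is exactly calibrated at this sample size, but the
unequal-variance statistic is the assay's convention and is what the
package implements.

Multiplicity is controlled with the exact binomial SGoF procedure:
with R p-values at or below γ = 0.05 among n tests, the one-sided
binomial meta-test `P(X ≥ R′)`, `X ~ Binomial(n, γ)`, is applied
repeatedly, declaring one more of the smallest p-values significant
and decrementing R′ while it stays below α = 0.05. The binomial
(exact) form was chosen over the chi-square approximation — exact at
any n and identical in the large-n limit. Ties with the largest
declared p-value are declared together (all-or-none, toward
inclusion), so results are deterministic and the declared set is
always the smallest p-values; the effective adjusted threshold p* (the
largest declared p-value) is reported alongside the counts. A relaxed
mode using a fixed raw threshold (default p ≤ 0.05) is available for
sensitivity analyses. SGoF is intentionally insensitive on small
families: with a handful of tests the meta-test essentially never
triggers, so analyses of a few dozen variants should use the raw mode.

## Structural annotation

Solvent accessibility uses the rolling-probe (Shrake–Rupley) surface
with a 1.4 Å probe, computed by biotite's deterministic
Fibonacci-sphere sampling with 960 points per atom by default (the
tests verify ≤5% per-residue change against 10⁴ points, and an
independently hand-rolled implementation agrees on toy systems).
Waters, heteroatoms and hydrogens are stripped first. Relative
accessibility divides by the theoretical residue maxima of the
Gly-X-Gly normalization table (Tien et al. 2013 values; the table is a
configurable input), and "surface" is strictly RSA > 0.25. Sector and
conservation membership are **inputs** (TSV flags from coevolution
analysis), never recomputed.

A surface residue "contacts the sector" when any of its peptide-bond
atoms lies within 1.2× the sum of the two atoms' Pauling radii of any
sector atom. The peptide-bond atom set is interpreted as the residue's
own backbone N, C and O (Cα excluded): the definition is ambiguous
about whether the bond spans two residues, and the single-residue
reading keeps the flag a property of one residue. Distances to the
effector insertion site are Cα–Cα Euclidean distances to residue 121.
Enrichment uses the two-sided Fisher exact test (summing hypergeometric
tables with probability not exceeding the observed — the standard,
deterministic convention), with a Haldane 0.5 correction on the odds
ratio when a cell is zero.

## Enzyme kinetics

Initial velocities are the slope of A340 over the first 15 s divided
by ε·l (ε = 13.2 mM⁻¹cm⁻¹ for NADPH, 1 cm path), sign-flipped because
NADPH is consumed; non-decreasing traces yield 0 with a warning.
Michaelis–Menten fits run in (log kcat, log Km) so positivity needs no
bounds, with deterministic initial guesses (kcat: 1.1× the largest
observed velocity; Km: the substrate concentration at half-max by
interpolation) and standard errors from the Jacobian at the optimum;
enzyme concentration is normalized to one, so kcat absorbs any shared
abundance factor and lit/dark folds are invariant to it. Lit and dark
are fitted independently. The allosteric fold is the ratio of fitted
velocities at a reference substrate concentration (default 25 µM DHF,
the physiological level); when Km is light-insensitive it equals the
kcat ratio at every substrate concentration. Multi-mutant expectations
are log-additive relative to the unmutated construct:
`expected = baseline · Π(single_i / baseline)`. Folds are ratios of
fitted velocities (not of replicate-averaged raw velocities); with
replicates pooled into one fit per condition the two conventions agree
to first order.

## Problem sizes and numerical choices

The test-suite and acceptance script use a ~500-variant library
(27 positions) at depth 10⁶ for recovery properties, a 10-position
library for the log-linear consistency check, 10⁴ draws for Welch
calibration, 20 seeds × 1548 uniform p-values for SGoF null behavior,
100 Monte-Carlo rounds for the error-model bias comparison, and full
enumeration of all 2×2 tables with n ≤ 40 (deduplicated by symmetry)
for the Fisher oracle — sizes chosen so the whole suite completes in
well under a minute per stage while leaving the statistical assertions
comfortable margins. Monte-Carlo calibration tests draw replicate
measurements and miscall counts directly from the generative model's
marginal distributions rather than re-running the read-level pipeline
hundreds of times; the distributions are identical by construction.

## Known limitations

- Growth-rate slopes for variants near the viability boundary are
  fitted from few, early timepoints and are systematically noisy; the
  −0.13 h⁻¹ filter exists precisely to keep them out of the allostery
  statistics, and recovery guarantees are stated for the retained set.
- The error model is per-run (one μQ), not per-position or per-cycle,
  and assumes substitution errors only.
- The simulator's multinomial sampling understates overdispersion from
  PCR jackpotting; real count noise can be larger at the same depth.
- SGoF's adjusted threshold is data-dependent; the package reports p*
  per run and makes no claim that any particular numeric threshold
  generalizes across datasets.
- Reverse-translated reference coding sequences (used when no plasmid
  sequence is supplied) are synthetic conveniences; supply the real
  CDS for real data.
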