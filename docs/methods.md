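# Methods

This note documents the statistical models behind `oncoqc`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions applied throughout.

## Study design being modelled

Four reference samples are assumed: **A**, a pooled cancer-cell-line DNA
sample with a dense catalog of known positives (KPs), each with a
characterized expected VAF, and a catalog of known-negative (KN) positions
defined inside a consensus targeted region (CTR); **B**, a diploid normal
background whose true alleles sit at 50%/100% VAF; **C**, a 1:1 mass
mixture of A and B (A-origin variants at half VAF, B heterozygous/
homozygous alleles at 25%/50%); and a **spike-in** sample (B plus synthetic
hotspot variants at a fixed 5% VAF). Each panel is run in ≥ 3 laboratories
with 4 replicate libraries per sample; sample C is sequenced about twice as
deep as the others. The CTR lies entirely inside the high-confidence
coding region (HC_CR), so each panel target partitions exactly into
CTR / (HC_CR beyond CTR) / rest.

## Conventions

* Regions are 0-based half-open (BED); variant positions are 1-based (VCF)
  and converted exactly once at the call-set boundary. Bookended intervals
  merge during normalization so sizes are unambiguous. Chromosome names
  match as exact strings (an alias map is available at BED read time).
* Variant matching is exact-key on `(chrom, pos, ref, alt)` after
  multiallelic splitting, parsimony trimming and (when a reference fetcher
  is supplied) left alignment. No fuzzy or haplotype-aware matching: the
  estimators are defined at locus level and approximate matching would
  shift every metric silently.
* Region membership of an indel/MNV is decided by its leftmost (anchor)
  reference base — a single unambiguous rule; users can pre-pad regions if
  they need span semantics.
* A "VAF cutoff at x" keeps calls with `vaf ≥ x`. VAF strata are
  half-open `(low, high]`, except the lowest study stratum which is closed
  below — the four strata 1–2.5%, 2.5–5%, 5–10%, 10–20% then partition
  without double counting.
* The `B_low` window [1%, 10%] is inclusive at both ends; "seen in sample B
  above 10%" means strictly greater. `C_only` treats a variant as "called
  in sample A" at any VAF (the VAF floor applies only to the B check).
* `viaKN` counts multiple alternate alleles at one KN position as distinct
  FP calls.
* Phred-scaled reproducibility is −10·log₁₀(1 − r); r = 1 maps to a cap
  (default 60). The transform is the standard error-probability mapping of
  the miss fraction 1 − r.

## Sensitivity

Pooled sensitivity in a stratum is Σ detections / (n_KP × n_libraries),
with truth restricted to the panel's assessed region and stratification by
the *expected* VAF (A: catalog VAF; C: half of it; spike-in: the design
VAF). Pooling across libraries and averaging per-library sensitivities
coincide here because every library is scored on the same KP set; the
pooled form is the default. A stratum with no targeted KPs is flagged
not-assessable rather than reported as zero.

Confidence intervals use a two-stage clustered percentile bootstrap:
laboratories resampled with replacement, then libraries within each
selected laboratory (replicates within a lab are not independent; the
two-stage scheme is the standard conservative choice). Default 1000
resamples, 95% level; the single-lab single-library case degenerates to the
point estimate and is flagged. All stochastic operations accept a seed or
`numpy` Generator.

## False-positive rates

`viaKN`'s denominator is the KN position count (rates per million KN
positions), exactly as the estimator is defined; `B_low` and `C_only` use
the evaluated region size in bases (rates per Mb), the only meaningful
denominator for estimators not tied to a position list. Each method's
blind spots are inherent: `viaKN` exists only inside the CTR; `B_low` can
overcount if rare mosaic alleles drift into the low-VAF window; `C_only`
cannot see systematic (panel-bias) errors because those recur in all three
samples. FP recurrence across replicates is reported as the fraction of
distinct flagged variants seen in ≥ 2 libraries, with the recurring keys
listed for inspection as systematic-error candidates (no automatic
adjudication).

## TMB coefficient of variation

**Technical CV (thinning simulation).** The reference samples are far
denser in low-VAF variants than clinical tissue, which would understate
run-to-run TMB variability (FP calls would be swamped) or overstate it
(through low-VAF detection noise). The simulation therefore (i) removes
B-germline loci and KP loci with sample-A VAF outside [5%, 40%] from the
report region, and (ii) per round retains k% of eligible KPs with VAF in
(10%, 40%] and 0.5·k% of those in [5%, 10%], dropping all calls at
non-retained loci. Reported calls above the VAF cutoff are counted per
replicate; with per-round across-replicate mean and variance averaged over
rounds,

    CV = sqrt(overall average variance) / overall average mean count.

Both removals in (i) are treated as locus exclusions from the report
region. Treating the [5%, 40%] filter as a catalog-only change would leave
high-VAF cell-line variants (mixture VAF > 20%, above any cutoff) in every
report and push the simulated TMB far above the clinical range the
simulation exists to emulate, so the locus-exclusion reading is the only
self-consistent one. Mean TMB is the average count over the average report
region size (region minus excluded loci). Defaults: k ∈ {1, 2, 5, 10, 20},
5000 rounds (tests use 200–500 with fixed seeds; the estimate is already
stable there), cutoffs {2.5%, 5%}. k = 0 rounds, when requested, are
reported separately as an FP floor and excluded from CV estimates, since
their mean count is essentially error calls.

Because a study has a fixed, small set of replicate libraries, thinning
rounds reuse the same library data and are therefore correlated; the
round-averaged CV is an unbiased estimate of the compound
binomial-plus-Poisson CV only in expectation over studies. Validation
against the closed form consequently draws fresh per-round compound counts
through the same CV arithmetic (`cv_from_round_counts`), while the
full-pipeline estimate is checked for the monotone decrease of CV with
mean TMB.

**Intrinsic CV (MSD decomposition and regression).** Given a per-sample
mutation catalog with an exome-scale baseline TMB (mutations per Mb of a
shared region), each panel's projected TMB is the mutation count inside the
panel's covered portion (panel ∩ CTR ∩ CDS) per Mb of that portion; panels
covering < 250 kb are rejected as too small for rate estimation. Samples
with baseline TMB in [5, 40] are sorted by TMB and grouped (default 100 per
group; scaled down in tests). Per group, with population variances:

    MSD   = mean((TMB_ref − TMB_panel)²)
    MSD′  = mean((mean TMB_ref − TMB_panel)²) = bias² + var(TMB_panel)
    adjusted variance = var(TMB_panel) − var(TMB_ref)

MSD ≈ MSD′ − var(TMB_ref) for TMB-homogeneous groups (the residual is
2·(var_ref − cov(ref, panel)), which the tests verify shrinks with group
spread). Samples whose deviation exceeds 5 group standard deviations are
excluded and logged — a per-group generalization of excluding a single
pathological genome. The adjusted variance times panel size squared (count
scale) is regressed through the origin on mean panel TMB times panel size
(mean count), pooling groups from all panels with equal weights (a weight
option is exposed); the through-origin form follows from the target
relation CV(c) = coef/√c, and the free-intercept fit is reported as a
diagnostic. Then coef = √slope and intrinsic CV(c) = coef/√c. A
replication-mode model with coef = 1.15 is available as a named constant;
estimators never use it implicitly.

**Overall CV** combines the components in quadrature,
√(CV_tech² + CV_intr²) — they arise from independent mechanisms
(run-to-run sampling vs genomic subsampling), and quadrature is the
natural combination for independent relative variances.

## Synthetic-data generator

The generator reproduces the statistical structure the estimators assume,
with every parameter recorded for recovery tests.

* **Toy genome**: 3 × 10 Mb chromosomes; HC_CR 4 Mb; CTR 2 Mb inside it;
  one panel target overlapping all three sub-region classes. Desk scale,
  but with non-trivial region structure.
* **Truth**: 4000 KPs uniform over the CTR (≈ 2 per kb, matching the
  reference sample's density) with VAF spectrum 7% in (1%, 2.5%], 18% in
  (2.5%, 5%], 25% in (5%, 10%], 18% in (10%, 20%] and the remainder above
  20%; 1.2% of KPs are small indels/MNVs. One million KN positions (half
  the CTR), disjoint from KPs by construction. 3000 B-germline variants
  over the HC_CR at 50%/100% VAF (they may coincide with KN positions —
  which is exactly why sample C's KN list must be derived by removing
  them); 300 spike-ins at 5% VAF in the panel's CTR portion.
* **Sequencing model**: per library, depth ~ negative binomial around 1500×
  (dispersion 50; sample C at 2×); per expected variant, alternate reads ~
  Binomial(depth, expected VAF); a call is emitted iff observed VAF ≥ the
  panel threshold (default 1%) and alternate reads ≥ 3. The negative-
  binomial depth is a documented stand-in — the emulated studies do not
  publish a depth model — and its exact marginal detection probability is
  exposed (`detection_probability`) so oracles never depend on the choice.
* **Errors**: Poisson per base per library (defaults 4/Mb inside the CTR,
  4× higher outside, matching the observed regime of low single-digit FP/Mb
  inside and multi-fold elevation outside), with VAFs from an exponential
  tail truncated above 10% — the regime where real panels report
  essentially no FPs. Errors are library-specific, so FP recurrence across
  replicates is nearly nil, and `C_only` can recover the rate.
* **Batch effects**: optional per-lab detection multipliers, off by
  default (the emulated studies harmonized protocols across labs, and
  observed intra- and cross-lab reproducibility nearly coincide).
* **Pan-cancer catalog**: per sample, a target TMB uniform in [5, 40] over
  a 22-Mb shared region; mutation events uniform in position, with an event
  being a two-adjacent-base doublet with probability π = (φ−1)/(3−φ).
  Under panel projection this compound process has adjusted count variance
  φ·(1−f) times the mean count for sampling fraction f, independent of TMB
  level, so the fitted intrinsic slope recovers the configured
  overdispersion φ for small panels. The six default panel coverages
  (0.25–0.8 Mb, all above the 250-kb floor) keep f ≤ 4%, making the (1−f)
  shrinkage negligible against the recovery tolerances.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real panels: read-level artifacts and sequence-
context error models (errors are position-uniform), FFPE damage, primer/
capture interference around dense variant clusters (spike-in sensitivity
loss from such interference is out of scope), uncharacterized true
variants, copy-number distortion of VAFs, and vendor pipeline differences.
Tests demonstrate estimator correctness against the stated generative
model, not field performance of any panel.

## Numerical and testing choices

* All randomness flows through `numpy.random.Generator` seeds; identical
  seeds give identical studies.
* Stochastic recovery tests assert within 3 standard errors derived from
  the generative model (binomial/Poisson/delta-method as appropriate).
  Where many cells are asserted jointly (the 10-cell technical-CV check),
  the per-cell threshold is the Bonferroni equivalent of a single 3-SE
  check plus an RMS-z guard, keeping the family-wise strictness unchanged.
* The bootstrap-coverage study uses 6 labs × 4 replicates × 50 KPs with a
  mild per-lab effect around 0.9: more labs than the 3-lab study minimum
  because a cluster bootstrap needs a non-trivial number of clusters to be
  exercised meaningfully.
* Test problem sizes (hundreds of KPs, 200–500 bootstrap/thinning rounds,
  800–2400 catalog samples) were chosen as the smallest sizes at which the
  statistical checks above are decisive; defaults in the library remain at
  the full study scale.

## Known limitations

* Exact-key matching treats complex-representation disagreements between
  callers as mismatches unless inputs are normalized with a reference.
* `fp_b_low`'s sibling exclusion needs ≥ 2 B replicates per site; with
  fewer it degrades (with a warning) to the raw low-VAF rule.
* The MSD decomposition's approximate identity deteriorates for very
  heterogeneous groups; group size trades bias (heterogeneity) against
  variance of the per-group moments.
* The intrinsic-slope recovery carries a deterministic (1−f) shrinkage for
  panel sampling fraction f; it is negligible for the default coverages but
  would matter for panels covering a large share of the shared region.
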