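# Methods

## Gradient profiles and normalization

The atomic input is one protein's quantification across 25 sucrose-gradient
fractions for one condition (control or RNase-treated) and one replicate.
Fractions are 1-based indices 1..25 throughout; fraction position proxies
the apparent molecular weight of the complex the protein migrates in.

Each profile is self-normalized so its 25 values sum to exactly 100; the
analysis therefore works on the *distribution* of a protein across the
gradient, never its abundance. Normalization is idempotent, and all-zero
profiles are flagged not-evaluable rather than divided. Mean profiles are
fraction-wise arithmetic means of the normalized replicates; a protein
needs at least 2 evaluable replicates (configurable; the experiment runs
3) per condition, and a protein missing in one condition entirely is
excluded from shift calling and reported as condition-missing. Per-protein
total amounts (summed raw signal over fractions and replicates, before
normalization) are kept separately for expression comparisons.

## Sum-of-Gaussians decomposition

Each mean profile is modelled as `f(x) = Σ a_j exp(−(x−c_j)²/(2w_j²))` at
x = 1..25, with bounds c ∈ [1, 25], a > 0 and w ∈ [0.5, 5] fractions: a
25-point grid cannot support narrower or wider features. Fitting is
bounded nonlinear least squares (trust-region reflective, analytic
Jacobian) for k = 1..k_max (default 4) components.

Initialization places the k centers on the k highest local maxima of a
3-point moving average of the profile (the smoothing suppresses
single-fraction spikes while moving no maximum by more than one fraction);
ranking ties break toward the lower fraction index for determinism. When
the smoothed profile offers at least k local maxima this initialization is
reliable and a single solve is run; otherwise up to 3 jittered restarts
under a fixed sub-seed guard against poor starting points. The k-sweep
stops early once BIC (n·ln(RSS/n) + 3k·ln n) worsens by more than 10 over
the running best — additional components cannot recover from that deficit.

Model selection takes the smallest k whose BIC lies within 2.0 of the
minimum, a parsimony rule favoring the single- and double-peak fits that
dominate real profiles. Post-selection, components contributing less than
5% of the model area are pruned and components whose centers fall within
1.0 fraction are merged (area-weighted center, summed area), each followed
by a refit. Peak maxima are reported both as continuous centers (for shift
distances) and rounded half-up to integer fractions (for category rules).

On noiseless 1–3 component inputs with >2 fraction separation the fit
recovers the true k with negligible residual, matching a brute-force
grid-search oracle (exhaustive center×width grid with closed-form
amplitudes) to within 1% of the signal energy; the model area conserves the
normalization total within 5%.

## Shift calling

Control and RNase peaks are paired greedily by nearest center: candidate
pairs in order of increasing distance, each peak used once, pairs beyond 20
fractions left unmatched (effectively never, on a 25-fraction gradient).
RNase-only peaks are reported as emergent but never drive the category —
they have no control partner. Greedy pairing is the *defined* matching
rule; it is not guaranteed to minimize total distance for adversarial peak
configurations, but coincides with the optimal assignment on the
well-separated cases the data presents.

For each matched pair, significance is a two-sided Welch t-test on the
per-replicate normalized amounts at the integer fraction of the control
maximum (unequal variances after RNase are expected; optionally both maxima
are tested with a Bonferroni factor of 2). Zero variance in both groups
yields p = 1 for equal means and p = 0 otherwise; fewer than 2 replicate
values on either side makes the pair not-evaluable. Raw p-values at α =
0.05 are the primary per-protein rule, mirroring per-protein screen logic.

A pair is a **shifting peak** iff |distance| > 1.0 fraction (strictly — a
displacement of exactly one fraction is never a shift) AND p < α.
Category precedence: **precipitated** if any shifting peak's RNase integer
maximum exceeds fraction 23; otherwise the sign of the area-weighted mean
signed distance of the shifting peaks gives **left** (negative) or
**right** (positive); no shifting peak means **no shift**. Proteins with
shifting peaks in both directions keep the net-direction category and are
flagged ambivalent.

The **shifting coefficient** is the summed area of control peaks in
shifting pairs over the total control model area: ≥ 0.75 is complete RNA
dependence, strictly between 0 and 0.75 partial, exactly 0 independent.
The 0.75 boundary is configurable; the complete/partial distinction is
verbal in origin and carries no canonical threshold.

## Screen comparison and atlas

Two screens are compared on their common evaluable proteins: the four
shift-behavior classes (both, A-only, B-only, neither) partition that set
exactly; opposite-direction proteins shift in both screens with opposite
net-distance signs. Expression classes use the ratio of summed raw
amounts with a two-fold threshold (sum over replicates; configurable).
Per-screen breakdowns split screen-specific shifters by direction among
commonly detected proteins ("differential") and separately count shifters
among proteins detected in that screen only; direction subcounts always sum
to the differential total.

The atlas intersects a GO-term-defined universe (flat label matching, no
GO-graph traversal) with RNA-linkage evidence: prior-knowledge flags
(RBP2GO-style) unioned with screen shift calls, deduplicated. Precipitated
proteins count as shifted. Percentages round half-up to one decimal.

## IP-MS interactor screen

Log2 iBAQ-like intensities over IgG / bait / bait+RNase × replicates.
Proteins must be detected in ≥ 70% of all samples (e.g. 7 of 9). Missing
values are imputed per sample from a Gaussian centered at the sample median
with width 0.3 × sample SD (seeded); imputed draws above the sample mean
are clipped to it by default — imputed values stand in for undetected,
hence low-abundance, measurements. The outlier-adjustment strategy is a
switch (`clip` | `winsorize` to the observed 5–95 percentile range |
`none`) because no single canonical definition exists; samples with fewer
than 3 observed values refuse imputation. Per-replicate log2 ratios
(bait−IgG; bait−bait+RNase) are tested against zero with a two-sided
one-sample t-test and BH-adjusted across proteins within each contrast.
Interactors need mean enrichment ≥ 1 log2 and adjusted p < 0.05;
RNase-sensitive interactors additionally the same on the RNase contrast.
Co-migration intersects the RNase-sensitive set with screen proteins that
shifted and have a control peak whose integer maximum lies within a
tolerance (default 0) of the bait's fraction.

With 3 replicates the t-test has 2 degrees of freedom, which floors the
attainable p-value; under BH a 4-fold effect at 0.25 log2 replicate SD is
genuinely marginal at adjusted p < 0.05. The synthetic-screen recovery
test therefore asserts the empirically measured rate (~62% of ≥4-fold
enriched, ≥4-fold sensitive proteins at the fixed seed) rather than a
hypothetical near-perfect one; false interactor calls among true nulls stay
at zero to a few percent.

## iCLIP summaries

Sites are 7-nt windows with a PureCLIP-style score, gene, gene-type and
transcript-region assignment taken as given from upstream site calling;
sequences are handled in the RNA alphabet with T mapped to U on input.
Score-tail trimming removes sites scoring strictly below the 5% quantile or
strictly above the 95% quantile; sites tied with a boundary value are
retained, so an all-equal score table is untouched while distinct scores
lose exactly 10%. Region statistics report counts, proportions (summing
to 1) and per-nucleotide enrichment (count / summed region length). The
pentamer contrast takes the strongest and weakest 20% of sites by score
(stable order on ties), counts each site's 3 overlapping pentamers and
normalizes within group over all 4^5 pentamers.

## Synthetic data

The generators are first-class, tested code and define the conditions all
recovery claims refer to. Gradient profiles are the generating Gaussian
mixtures evaluated at integer fractions, scaled to a per-phase total
amount, with multiplicative log-normal per-fraction noise of mean 1 and
configurable CV (default 0.1 — fraction-level MS intensity noise is
heteroscedastic); 3 replicates per condition by default. Ground truth is
computed from the generating peaks with the same moved-peak definition the
analysis estimates (matched displacement > 1 fraction), so the true
shifting coefficient is the analytic ratio of generating-peak areas.
Precipitation is generated as an RNase peak at fraction 24–25. The default
random population holds 60% non-shifters, 20% left, 12% right and 8%
precipitated, with 2–10 fraction displacements and occasional stationary
second peaks (partial dependence).

IP-MS tables are Gaussian in log2 around a base level shifted by the true
folds (0.25 log2 replicate SD), with Bernoulli missingness per sample; the
default population makes 55% of quantified proteins genuine interactors
(4–64× enrichment), 30% of those RNase-sensitive (4–64× drop), background
missing more often than interactors. iCLIP sites draw regions
proportionally to region length (the uniform-binding null), gene types from
a stated mix, scores log-normally; an optional uridine bias raises the
per-position U probability in the weakest 20% of sites, mirroring the
U-rich character of low-score CLIP background.

What the generators do *not* emulate: peptide-level quantification and
protein inference, ragged missingness structure of real MS (intensity-
dependent), inter-protein correlation within complexes, chromatographic
artifacts, and genomic sequence context around CLIP sites. Passing
recovery tests therefore demonstrates correctness of the analysis rules
under the stated statistical structure, not performance on real deposited
data — screen-level published counts (thousands of proteins, specific hit
numbers) are properties of the deposited measurements and are out of reach
at desk scale.

## Problem sizes and numerics

The test suite and the acceptance script use 200-protein screens for
recovery, 20 × 25-protein null screens for error control, 500-protein IP
tables and 2000–8000-site CLIP tables — sizes at which every statistic is
stable while the full suite completes in a few minutes. All randomness is
seeded; identical inputs give bit-identical outputs. Degenerate inputs
(all-zero profiles, zero-variance tests, empty universes, all-equal
scores) resolve by rule rather than by exception wherever a rule is
defined above.
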