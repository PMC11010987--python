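# Methods

## The assay, in brief

Tumour-derived cfDNA carries hypermethylated promoter CpGs (here
RASSF1A, MIR129-2, NRIP3, SOX8, with CCDC181 carried through
quantification but dropped from scoring) against a vast background of
unmethylated blood-cell DNA. Bisulphite conversion encodes methylation
state into sequence; a deliberately biased preamplification then
amplifies the methylated (converted-CpG-retaining) template far more
efficiently than the unmethylated one, and droplet digital PCR counts
the resulting molecules in ~20,000 partitions per well. Copies/mL of
methylated marker DNA, total cfDNA, patient age and (for the
PSA-dependent scores) the free-to-total PSA ratio QfPSA feed integer
composite risk scores whose cutoffs are calibrated to keep sensitivity
for clinically significant cancer at 100%.

## Preamplification model

Each condition is reduced to per-cycle duplication probabilities
`(E_m, E_u) ∈ [0,1]²`; annealing temperature and Mg²⁺ concentration are
carried as metadata only, because no functional form links them to
efficiency — condition grids are expected to come with measured or
assumed efficiencies. Deterministically, `N = N0·(1+E)^c`; the
stochastic variant is a Galton–Watson branching process
(`N ← N + Binomial(N, E)` per cycle) whose mean reproduces the
deterministic law. PCR bias is `B = 100·N_m/(N_m+N_u)` and is
undefined (an error) without template. All bias computations default
to `c = 12` cycles, the cycle count at which the feasibility criteria
are defined; the thermal-cycling programme may run more cycles, but
the bias definition is the quantity under test. Feasibility screening
accepts conditions with `B > 90`, at least 500 surviving unmethylated
copies (the internal control against false positives from purely
methylation-specific amplification) and amplitude proxies above a
configurable floor (default 0, i.e. inactive, since signal amplitude
is qualitative).

## Droplet measurement model and quantification

`simulate_well` partitions integer molecule counts into droplets
multinomially (conserving molecules exactly), gives occupied droplets
amplitudes from the positive fluorescence cluster
(default 5000 ± 100 RFU) and empty ones from the negative cluster
(1000 ± 100 RFU), and shifts each channel by a per-well baseline
offset (uniform ±150 RFU). `rain_fraction` optionally re-draws a share
of *positive* droplets uniformly between the clusters, emulating
delayed-onset amplification; its default is 0 because an optimised
assay produces clean clusters and any between-cluster population
biases threshold classification by construction — it is a stress
parameter, not a baseline condition.

Quantification normalises each channel to its negative-cluster centre.
The baseline estimator is deliberately not a fixed low quantile: at
high occupancy (λ ≈ 3, > 95% positives) any fixed-percentile rule
tracks the positive cluster. Instead an exact 1-D two-means split
(sorted prefix sums; deterministic, no seeding) locates the two
cluster centres, the baseline is the median of droplets below the
midpoint, and the classification threshold defaults to the midpoint of
the normalised centres. Wells whose centres are closer than a minimum
separation (default 1000 RFU) are treated as single-cluster and
classified all-negative — correct for empty wells; a fully saturated
well is unresolvable anyway and raises a saturation error instructing
dilution (the pipeline glue retries at 10×/100×/1000× dilution and
multiplies back).

Occupancy inverts through `λ = −ln(1 − k/n)`; copies per reaction are
`λ·n`. Copies/mL plasma scale reaction copies by the eluate-to-well
loading ratio (12 µL eluate, 4 µL per well), divide by the net
preamplification gain and refer to the plasma volume. The default gain
is 1: quantified copies/mL are reported on the template (pre-gain)
scale, the convention under which the simulator's configured copies/mL
round-trip through measurement unchanged. A sample × marker is called
positive only when at least two replicate wells each contain more than
5 positive droplets — the stringency compensates the very strong
amplification of trace methylated template.

## Synthetic cohort generator

The generator emulates a four-group study: 90 young healthy controls,
40 BPH, 7 indolent and 32 clinically significant cancer patients
(indolent defined clinically as Gleason 6, tPSA < 10 ng/mL, T1/T2a).
Group marginals follow the published summaries where printed — age
(67.4 ± 10.5 BPH vs 71.8 ± 9.7 PCa, truncated to [40, 95]; controls
24 ± 3 in [18, 30]), cfDNA/mL (22.0 ± 17.7 / 47.4 ± 84.0 /
75.0 ± 135.6 ng/mL), MIR129-2 (107.7 ± 151.1 BPH, 172.0 ± 206.4
cs-PCa) and CCDC181 (128.6 ± 529.9 BPH, 108.5 ± 399.7 cs-PCa,
deliberately non-discriminating). Marker levels and cfDNA are
zero-inflated log-normals: the printed standard deviations exceed the
means, ruling out normal marginals, and the zero mass models samples
in which a marker is genuinely absent (zero fractions 0.50 / 0.25 /
0.20 / 0.05 from controls to significant cancer). The (mean, sd)
parameters describe the *mixture including zeros* — the non-zero
component is rescaled accordingly — so cohort-level sample moments
converge to the configured values.

Unprinted quantities were fixed once to reproduce the published cohort
behaviour: RASSF1A/NRIP3/SOX8 group means rise control < BPH < cancer
with per-marker benign-vs-cancer AUCs around 0.75–0.8; QfPSA is
truncated normal with ~40% of BPH above and ~12% of significant
cancers above the 20% cutoff (matching the published single-marker
operating point); tPSA is uniform on each group's clinical range, so
it carries no discriminative signal inside the grey zone — as
observed. Markers and cfDNA share an exchangeable Gaussian copula
(ρ = 0.3) representing a common tumour-DNA shedding factor; with
independent markers the calibrated composite scores become markedly
*more* specific than the published ladder (mean specificities
64/73/68/84% vs the published 47.5/57.5/52.5/70%), while ρ = 0.3
reproduces that ladder closely (43/60/53/71%). The correlation was
chosen once from this design study and is configurable. QfPSA, age and
tPSA are sampled independently of the copula block.

What the generator does **not** emulate: inter-marker correlation
structure beyond a single exchangeable factor, age–marker coupling,
assay batch effects, bisulphite-conversion sequence errors, or
serum-vs-plasma matrix differences. Extraction and conversion losses
exist as binomial thinning parameters but default to 1 because the
configured copies/mL represent measured (post-workflow) levels.
Passing tests therefore show the *pipeline* is correct and the
qualitative study pattern is reproducible — not that real cohorts
would yield these exact specificities.

## Marker selection

Candidate probes must be significantly hypermethylated in tumour
tissue against healthy prostate, bladder, kidney, liver and lung
(raw p < 0.001 each, Welch's t; an exact-style permutation test on the
mean difference replaces it when a group has fewer than 5 samples),
with per-contrast effect Δβ > 0.2 and background means (white blood
cells, healthy serum) ≤ 0.10 — the background bound sits above the
published healthy ranges (1.8–6.0% serum, 3.1–9.3% WBC). No
multiple-testing correction is applied by default (the criterion is a
raw per-contrast threshold); a Bonferroni option exists. An
`allowed_exceptions` list records deliberate keeps of probes elevated
in one off-target tissue (the NRIP3-in-liver situation) rather than
guessing a rule. Ranking is by worst-case Δβ across contrasts,
descending, ties broken by probe id; missing betas are dropped
pairwise, never imputed. Degenerate contrasts are conventioned:
identical constant groups give p = 1, zero-variance groups with
different means give p = 0.

## Risk scores and calibration

The published scores print integer decision thresholds ("cutoff < 3"
for 6 components, "< 4" for 7), consistent with a count-of-exceedances
score; that additive form is implemented as a documented
reconstruction (the original functional form is not public). Risk
directions: markers, cfDNA and age score above their cutoffs, QfPSA
below (a low free fraction indicates cancer); exceedance is strict, so
a value exactly at its cutoff never scores. Components use measured
copies/mL by default; the binary positive-call rule remains available
on the records.

Calibration fixes cutoffs by grid search over midpoints between
observed component values plus the two flag-everyone/flag-no-one
extremes — the optimum of a step function always lies on this grid.
Feasibility is guaranteed (the all-flagging assignment satisfies any
τ ≤ k), so the 100%-sensitivity constraint on the target groups
(significant + indolent cancer for variant 1, significant only for
variant 2) always holds at the optimum and is asserted on return.
Small grids (≤ 2·10⁷ combination-patient evaluations, covering
few-patient cohorts) are enumerated exactly; cohort-scale problems use
coordinate-wise sweeps from the all-flagging start with a pairwise
refinement pass, since single-coordinate moves alone can stall in
two-component local optima. Ties prefer the more conservative cutoff
(fewer patients flagged), then earlier components by sweep order —
making the fit invariant to patient ordering. Indolent patients never
enter the specificity objective; they are reported separately.

## Evaluation layer

The group-difference gate applies Shapiro–Wilk per group (standard
practice; a pooled test would conflate location shifts with
non-normality) and classical Levene (mean-centred). Non-normal data
route to Kruskal–Wallis + Conover regardless of variance — the
conservative completion of a routing table that only enumerates three
combinations. Conover's all-pairs comparison is computed from pooled
tie-corrected ranks with the `(N−1−H)/(N−k)` variance deflation and
Student-t reference on `N−k` degrees of freedom. Post hoc tests run
only below the 0.05 omnibus gate; significance tiers are
0.05/0.01/0.001. No cross-marker multiplicity correction is applied,
matching per-marker reporting. ROC curves sweep unique score values
(integer composite scores give coarse stepwise curves — their AUCs
should not be over-interpreted) and AUC is trapezoidal, equal to the
concordant-pair fraction by the Mann–Whitney identity, which the test
suite verifies exhaustively at small n.

## Numerical and testing choices

Problem sizes were picked to keep the full suite fast while leaving
estimates stable: estimator-recovery checks use 200 replicate wells of
20,000 droplets per occupancy in {0.01, 0.1, 0.5, 1, 3} against 99%
binomial bands (≥ 95% coverage required); branching-process means use
1,000 realisations at 2% tolerance; monotonicity and screening checks
use 1,000 and 100 random draws; calibration constraints are verified
over 50 seeded cohorts, and the end-to-end pattern (marker gradient
plus composite-beats-QfPSA specificity) over 50 seeds with an 80%
pass requirement. All randomness flows through seeded
`numpy.random.Generator` instances; fixed seeds give bit-identical
cohorts and wells.

## Known limitations

- A fully positive well cannot be distinguished from a fully negative
  one after baseline normalisation; it is unreachable below λ ≈ 10
  and the dilution-retry policy handles realistic saturation.
- The coordinate-wise calibration is heuristic at cohort scale; it
  matches exhaustive search on small cohorts but carries no global
  optimality guarantee beyond them.
- The copula correlation and the unprinted marker means are simulator
  design choices calibrated to published summary behaviour, not
  patient-level data; absolute specificities on real cohorts will
  differ.
- QuantaSoft-style droplet exports are supported via column mapping
  only; proprietary gating, plate QC and EPIC-array normalisation are
  out of scope.
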