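# Methods

## The model of the workflow

`epimark` treats biomarker discovery as a two-arm process. The *discovery
arm* screens a two-condition methylation array for probes whose methylation
drops when a transcription factor is depleted, then demands regulatory
corroboration: the differential probe must sit at a promoter CpG island
that also has a nearby TF-bound enhancer. The *validation arm* quantifies
the nominated locus across a disease-progression cohort by bisulphite
pyrosequencing and evaluates a binary serum MSP call as a diagnostic.

### β-values and differential selection

A probe's methylation is β = M/(U + M + 100); the +100 offset regularises
low-intensity probes and bounds β strictly below 1 (at the simulator's
fixed total intensity M + U = 1000, the ceiling is 1000/1100 ≈ 0.909).
Replicates are combined by the arithmetic mean of β within each condition
before differencing — the convention is not forced by the data model, but
one β per condition per probe is what downstream ranking consumes.
Selection is on Δβ with an inclusive threshold (default 0.25) and a
direction flag; discovery defaults to `hypo` because depleting a silencing
TF should *lower* target methylation. No detection-p or QC filtering is
applied; an optional minimum-total-intensity floor (default off) marks
degenerate probes as missing.

### Interval integration

Coordinates are 0-based half-open throughout (BED convention) and overlap
means at least one shared base; adjacency ([10,20) vs [20,30)) is not
overlap. Enhancers are the base-wise intersection of H3K4me1 and H3K27Ac
peaks — the stricter of the plausible readings (the alternative, requiring
only that both marks overlap the peak somewhere, would admit more genes).
The promoter window is ±2 000 bp around the TSS, symmetric so that strand
can be ignored; the enhancer-to-island flank defaults to 5 000 bp, because
a regulatory site "a few kb" from the promoter island should still count.
Both are configurable. The differential probe may lie inside the island or
within the same flank of it (the promoter-region reading); setting
`flank=0` recovers the strict island-only reading. Candidates are ranked
by their most negative probe Δβ, ties broken by gene id for determinism.
Set operations on intervals delegate to pyranges; tests check every
operation against a per-base boolean-scan oracle on a 100 kb toy genome.

### Pyrosequencing

Site methylation is 100·C/(C+T). Sites with total signal below a floor
(default 10 fluorescence units) are flagged missing rather than silently
reported as 0 % or 100 %; a sample with no defined site is an error, not a
0. The per-sample summary is the unweighted mean over defined sites —
sites are a priori exchangeable and no weighting rule is implied by the
data model.

### Statistics

The Mann-Whitney U uses the mid-rank tie convention
(U = #{x>y} + ½#{x=y}). Exact mode enumerates all C(n_x+n_y, n_x)
labelings — feasible through n = 12 total, 924 labelings at worst — and
reports the two-sided p as the null probability of a U at least as far
from n_x·n_y/2 as observed (the null is symmetric under label exchange, so
this equals the doubled smaller tail). Approximate mode is the
tie-corrected normal approximation with continuity correction
(scipy). `auto` picks exact whenever feasible. Unpaired t-tests (Student
or Welch) delegate to scipy, with explicit handling of the zero-variance
degenerate cases (equal means → t = 0, p = 1; unequal → p = 0, flagged).
Tests are two-sided; α = 0.05 is reporting-only and no multiplicity
correction is applied.

### Diagnostics

MSP positivity is the presence of the methylated band regardless of the
unmethylated band — the standard reading of a two-lane MSP gel. Metrics
are computed with exact rational arithmetic (`Fraction`), so the
formatting mode, not binary floating point, decides the printed digit.
Truncation to one decimal is the default because published diagnostic
tables of this kind are only reproducible under truncation
(47/53 = 88.679 → 88.6; 47/52 = 90.38 → 90.3; 15/22 = 68.18 → 68.1),
while round-half-up is exposed for comparison and raw precision is always
retained internally. A zero denominator yields an undefined metric (None),
never 0. The two-block report (cancer-only vs cancer-or-IM positives)
shares one negative set — serum samples from groups in neither definition
— so IM serum samples are excluded from, not counted against, the
cancer-only block. Group sizes always come from the input cohort.

### qPCR

Relative expression is the within-sample ΔCt form 2^−(Ct_target −
Ct_reference); a ΔΔCt variant against a calibrator ΔCt is available.
Technical replicates are averaged on the Ct scale (averaging after the
exponential transform would bias the estimate). The 2-fold re-expression
threshold is a free parameter; zero untreated expression yields an
infinite fold change with a warning rather than an error.

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
tested. Genes occupy non-overlapping 20 kb slots so one gene's evidence
cannot fall within the default flank of a neighbour's island; probes are
placed uniformly in the ±2 kb promoter window. Noise is Gaussian on the β
scale (not the intensity scale), clipped to the representable range and
back-converted to (M, U) at fixed total intensity 1000 — this keeps a
planted Δβ exact at zero noise and the +100 offset observable. Planted
targets carry Δβ = −0.35 from a control β of 0.70; decoy genes carry the
same Δβ but one broken evidence link per class (`no_cgi`,
`peak_no_enhancer`, `enhancer_no_peak`), plus a `no_delta` class with full
evidence and no methylation change, so every arm of the candidate filter
is exercised. Default array noise in tests is sd 0.03 with 3 replicates.

The cohort emulates the progression design: group sizes default to
34/33/53 (gastritis/IM/cancer), tissue methylation is Normal(group mean,
6 %) clipped to [0,100] with means 5/15/25 % for gastritis/IM/cancer
(4 % normal, 10 % adjacent-normal) — chosen once as representative of a
low→intermediate→moderate promoter-methylation progression, since no
tabulated per-group values exist to calibrate against. Pyro signals per
site are the sample's tissue % plus site-level Normal(0, 2 %) noise at a
fixed 100-unit total signal. Serum MSP positivity defaults to 47/53 for
cancer, 2/3 for IM and 1/4 for non-cancer groups — the rates implied by
the published marginal counts — with serum available for all cancer
samples, 3 IM samples and 20 non-cancer controls. One integer seed drives
each generator through a single RNG with a documented draw order, and
identical inputs produce byte-identical artifacts.

What the simulator does *not* emulate: raw IDAT intensities and their
scanner noise, probe cross-hybridisation, bisulphite-conversion failure,
batch effects, correlated probes within an island, PCR chemistry, or
realistic genome annotation density. Passing tests therefore demonstrate
the correctness of the computation and the discriminative power of the
evidence filter under planted truth — not the pipeline's operating
characteristics on real arrays.

## Problem sizes and numerical choices

The standard test genome is 10 chromosomes × 1 Mb with 200 genes × 3
probes (5 targets, 10 decoys); recovery under noise is measured over 100
intensity seeds, interval-oracle agreement over 500 random track pairs on
a 100 kb genome, and the progression trend over 200 cohort seeds — sizes
at which every Monte-Carlo estimate is stable to a few percent while the
whole suite runs in a couple of minutes. Exact Mann-Whitney U values are
compared with a half-unit-safe tolerance (1e-9) to guard float equality of
tied mid-rank sums. Diagnostic percentages use exact rationals end to
end.

## Known limitations

* The candidate filter is binary evidence logic; no scoring or FDR control
  across probes is attempted (none is part of the workflow being modelled).
* Exact Mann-Whitney is limited to n ≤ 12 total by design; beyond that the
  tie-corrected normal approximation is used (agreement within 0.02 for
  n ≥ 20 per group without ties, checked at the feasibility boundary in
  tests).
* The generator's group means and noise levels are stylised; conclusions
  about real-cohort effect sizes cannot be read off the synthetic defaults.
* MSP calls are simulated as independent Bernoulli draws per group — no
  dependence between tissue methylation and the same sample's serum call.
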