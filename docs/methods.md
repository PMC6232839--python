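# Methods

This note records the models the package implements, the conventions and
defaults chosen where the design was open, and what the synthetic-data
generators do and do not emulate.

## Marker quality control

Genotypes are dominant presence/absence calls (DArT-style), so all
frequency arithmetic is on the presence frequency f and "minor allele
frequency" means min(f, 1−f). The cascade applies, in order: duplicated
call patterns (exact vector equality with missing as a distinct symbol;
an `ignore_missing` mode matches on shared non-missing calls instead),
missingness strictly greater than 0.20, MAF strictly below 0.05 computed
over non-missing calls, and removal of markers absent from the genetic
map. The order matters only for the per-filter counts; when the failure
categories are disjoint the final retained set is order-free, and the
report exposes both the sequential counts and the union. Markers with no
non-missing calls are reported under a separate reason code rather than
as low-MAF. No imputation is attempted, and no Hardy–Weinberg test is
run (not meaningful for dominant markers).

## Phenotype model for the augmented design

Plot values for one trait and year follow

y = μ + check effects (fixed) + cultivar + row + column + e,

with cultivar, row and column random. Test entries are unreplicated
within a year, so the residual variance is identified by the replicated
checks; check cultivars are fixed effects and carry no random cultivar
term. The model is fitted by REML through statsmodels MixedLM with
variance components supplied as explicit dummy design matrices (zero rows
for check plots in the cultivar factor). Two optimizers (L-BFGS, then
Powell) are run and the fit with the higher restricted likelihood kept —
L-BFGS can stall when a component sits on the zero boundary. Variance
estimates are floored at zero. The across-years fit adds year as a fixed
effect and nests row/column within year.

The combined ANOVA operates on one value per cultivar-year (BLUPs plus
the year mean), because plot-level replication of non-checks does not
exist in this design. It is a two-way year x cultivar decomposition with
the interaction as the error term; the cultivar SS splits exactly into
between-subpopulation and within-subpopulation parts, and admixed
accessions are excluded before the decomposition. Only cultivars observed
in every year enter, keeping the layout balanced. SS percentages are
reported against both the total SS and the model (year + cultivar) SS,
since either normalisation is defensible and they answer slightly
different questions.

Tukey comparisons use the studentized range with the harmonic-mean group
size for unbalanced groups, and build the compact letter display by
insert-and-absorb: start from one class of all groups, split any class
containing a significantly different pair, then drop classes contained in
others. SI is the plain quotient GS/GPC. The EU quality index is
implemented as the weighted percentage of per-trait check means
(GPC 0.40, GS 0.30, YI 0.20, TW 0.10); the exact normalisation used in
regulatory practice is not specified formulaically anywhere accessible,
so the check-mean-percentage convention is explicit and the weights and
check set are arguments.

## Association scan (K+Q)

Kinship is allele sharing: the fraction of pairwise non-missing markers
with identical calls, symmetrised and bent to positive semi-definiteness
by an eigenvalue shift when needed; the diagonal is 1. The scan fits the
null mixed model y = Xβ + u + e, cov(u) = σ²_g K once per
trait-environment by REML, profiling the variance ratio on the spectral
decomposition of K (bounded scalar search on log₁₀ λ in [−5, 5]). The
fitted ratio then whitens the model and every marker is tested by an
F-statistic for its fixed effect given the intercept and Q — the
"population parameters previously determined" shortcut, which at n ≈ 165
is indistinguishable from per-marker refits and orders of magnitude
faster. No compression of individuals into groups is applied: compression
is a runtime device, not a statistical requirement, at this scale.

Q enters with one column dropped against the intercept. Markers with
within-sample MAF below the threshold or collinear with the fixed part
(residual norm ≈ 0 after projection) are skipped with a reason. Marker R²
is the marker's incremental SS over the total SS of the whitened model —
a definition choice, stated here because the quantity has no canonical
definition in a mixed model. Missing genotype calls are mean-imputed for
testing only.

The Q-Q threshold rule: sort observed −log10(p) against (k−0.5)/n uniform
quantiles and take the observed value at the smallest rank from which
observed − expected > δ holds through the top of the distribution;
δ defaults to 0.1 −log10 units and the threshold never drops below 2.0.
The deviation criterion in the original workflow was visual; δ is the
explicit, reported knob standing in for that judgment.

## MTA-QTL regions and allele analytics

Associations within a gap (default 10 cM) on the same linkage group chain
into one region by single linkage over sorted positions; linkage groups
of one chromosome (1A.1 vs 1A.2) are never merged, and region ids number
consecutively per base chromosome in map order. The 10 cM default is the
upper end of the field's 5–10 cM windowing convention given LD decay up
to ~8 cM; it is a parameter because no single threshold reproduces every
published grouping (published region tables on 3B imply a threshold below
9.1 cM while 2B implies one of at least 9.5 cM — the original grouping
involved judgment). Environment counts treat each year and "across" as a
distinct label.

Carrier frequencies are per-subpopulation fractions among non-missing
calls. Carrier-effect comparisons use Welch's t at α = 0.05 with
letter-style reporting and the relative effect
100·(mean_present − mean_absent)/mean_absent. Decile analyses rank by
BLUP and take ⌈0.1·n⌉ accessions per tail, widening across ties at the
cut and reporting the realised tail size.

## QTL meta-analysis

Confidence intervals reported by a source study take precedence; missing
ones are estimated as 163/(N·R²) for RIL and 530/(N·R²) for DH, BC and F2
progenies, interpreted as 95% widths centered on the position. The
precedence is configurable since collected literature mixes both cases.
A 95% width maps to a Gaussian sd by division by 3.92 (2 × 1.96); the
Gaussian reading is the standard meta-analysis assumption, not something
the CI itself guarantees.

Projection is piecewise linear through the positions of markers common to
the study and consensus maps: within a common interval,
c = c_a + (p − s_a)(c_b − c_a)/(s_b − s_a); beyond the common span the
nearest interval's scale is used anchored at the nearest common marker,
flagged as extrapolated, and downgraded to unprojectable beyond 20 cM of
extrapolation. Fewer than two common markers on the chromosome means the
QTL cannot be projected. Inverted marker order between maps is projected
with |scale| under a warning. CI endpoints ride the same transform.

Clustering maximises Σ_i log Σ_j w_j φ(x_i; μ_j, sd_i²) by EM with known
per-observation variances; means update as precision-weighted averages of
responsibilities. Initialisation is deterministic at the k-quantiles of
the positions; chromosomes at or above the method-switch size (default
10 QTLs) add seeded random restarts — both branches run the same
estimator, preserving the historical workflow's shape (different software
below and above 10 QTLs) as configuration rather than as two algorithms.
EM stops at |ΔlogL| < 1e-8 (log-likelihood non-decreasing by
construction); an emptied component triggers a refit at k−1. Model choice
minimises AIC with 2k−1 free parameters (k means, k−1 weights), ties
toward smaller k; BIC and AICc are selectable.

Assignment and exclusion rules: QTLs with LOD < 2.0 or CI > 100 cM are
excluded before clustering (the named rules come without published
values; both are flags and appear in the report). Each remaining QTL goes
to its maximum-posterior component unless that posterior falls below the
ambiguity cutoff 0.6 (the membership-coefficient rule), in which case it
is excluded as overlapping several clusters. One-member components are
singletons, not meta-QTLs. Every input QTL lands in exactly one of
members/singletons/excluded/unprojectable — a conservation invariant the
tests enforce.

## Gene anchoring

Physical coordinates follow GFF3 1-based inclusive input, treated
internally as half-open [start, end+1); an interval [lo, hi) includes a
gene iff the spans intersect, so a gene starting exactly at hi is out.
The Mb/cM ratio is computed per marker from the nearest commonly-placed
pair spanning it (nearest pair with an extrapolation flag otherwise). LD
blocks grow outward from the focal marker along the map while the
entering marker keeps presence/absence r² at or above the threshold
(default 0.5) with every block member; monomorphic or undefined pairs
count as below threshold. r² on presence/absence codes is a composite-LD
surrogate — the price of dominant markers. A marker without a physical
anchor requires an explicitly supplied proxy marker at the same genetic
position; substitution is never silent. Note one arithmetic convention:
±window at ratio r gives exactly 2·window·r Mb, with no rounding-up of
the window.

## Synthetic data: what it emulates, what it does not

The generators reproduce the study's shape: ~165 accessions in five
subpopulations (≈10% admixed), ~1100 dominant markers on 14 chromosomes,
three year-environments, planted marker effects of a few percent of the
trait mean, and a literature of RIL/DH/BC/F2 studies with N in 60–300 and
R² right-skewed in [0.01, 0.55] (Beta(1.6, 5) rescaled — mean ≈ 0.14 with
roughly four fifths of values below 0.20, matching the reported PVE
distribution; the implied formula CIs average near 18 cM). Structure is
Balding–Nichols: subpopulation presence frequencies are Beta-perturbed
around an ancestral U(0.1, 0.9) frequency with F = divergence
(default 0.15, a typical between-subpopulation differentiation for
structured durum germplasm).

Field layout: entries in seeded order with one replicated check after
every 10th test plot (three checks cycling), rows of 20 plots; the
original design names the augmented layout but not its geometry, so this
is a documented convention, not a reconstruction. The polygenic term is a
multivariate normal draw with covariance proportional to the
marker-sharing kinship after removing its constant off-diagonal baseline,
so the `genotype` variance parameter is the variance of independent
deviations and kinship contributes correlation only. Year effects are
additive; genotype-by-year interaction and epistasis are deliberately not
simulated, so tests passing on this generator say nothing about those
features of real data, nor about spatial trends beyond random row/column
effects.

The QTL-literature generator gives each study an affine per-chromosome
coordinate system sharing (by default) four markers with the consensus
map, inverse-projects each QTL's true position into it, and adds
positional noise proportional to the study's own precision
(sd_i = CI_i/3.92), rescaled so the root-mean-square scatter around each
true meta-QTL equals that meta-QTL's `spread` parameter (spread 0 means
no noise). This keeps the noise consistent with each study's N, R² and
cross type while making `spread` directly interpretable in cM. A
configurable fraction of studies shares no markers with the consensus, to
exercise projection failure.

## Problem sizes and numerical settings

Simulation-based checks run at the sizes a laptop handles in seconds:
meta-QTL recovery uses 50 seeds at 30 QTLs (selection) and 90 QTLs
(position accuracy, 30 per cluster); the null calibration of the scan
uses 20 seeds × 1000 markers at n = 165; power checks use 25 seeds at
n = 300; REML recovery uses 20 seeds at n = 200. EM tolerance 1e-8, cap
2000 iterations; REML ratio search tolerance 1e-6 on log₁₀ λ; variance
floors at 0; kinship bending threshold 0 with a 1e-8 shift.

## Known limitations

The published MTA-region table cannot be regenerated row-for-row by any
single chaining threshold (see above); only the 2B chromosome is asserted
against it. The count of markers involved in two or more associations is
computed per trait-marker pair and yields 13, where the original text
says twelve — the text is internally inconsistent with its own
association table on one marker, and the computed count is reported as
is. The across-study supplementary material (per-QTL CI and PVE
distributions of the collected literature) is not distributed with the
package, so those distributions are emulated by the generator defaults
rather than checked against a file. The historical two-software
meta-analysis is deliberately replaced by one estimator with a
configurable branch point; exact numeric replication of that software is
out of scope.
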