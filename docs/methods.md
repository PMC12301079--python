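# Methods

`psqa` implements the statistical machinery of pre-treatment patient-specific
quality assurance (PSQA) for SBRT/VMAT plans: gamma analysis of measured
against calculated dose distributions, ROC-based selection of gamma
passing-rate (GPR) thresholds using absolute isocenter-dose agreement as the
ground truth, aperture-complexity metrics of the MLC sequence, and plan
quality indices. Because real QA measurements require a linac and detector
hardware, the package ships a synthetic-data generator that reproduces the
*statistical structure* such a study assumes, with known ground truth, so the
whole analysis chain is testable end to end.

## Gamma analysis

For a reference (measured) point at position `r_m` with dose `D_m`, the gamma
index against the evaluated (calculated) grid `D_c` is

    gamma(r_m) = min over r_c of sqrt( |r_c - r_m|^2 / DTA^2
                                     + (D_c(r_c) - D_m)^2 / dD^2 )

with `dD = DD/100 * D_norm` under global normalization (default; `D_norm` is
the evaluated-grid maximum when set to `auto`) or `DD/100 * D_m` under local
normalization. Points with `D_m` below the low-dose threshold (default 10% of
`D_norm`) are excluded from both numerator and denominator of the GPR; a
gamma of exactly 1 counts as a pass. The default criteria set is the six
DD/DTA pairs at and below the universal IMRT/VMAT tolerance: 3%/2mm, 2%/2mm,
1%/2mm, 3%/1mm, 2%/1mm, 1%/1mm.

Conventions that the gamma literature leaves open and we fix here:

* the *measured* point set is the reference and the *calculated* grid is the
  searched (evaluated) distribution;
* normalization dose `auto` = maximum of the evaluated calculated grid
  (measured maxima are noise-sensitive);
* cylindrical detector arrays are analysed in their unwrapped 2D manifold
  (arc-length x axial mm); the evaluated grid must be supplied in the same
  manifold.

**Search.** The minimization is exhaustive and deterministic: a cubic lattice
of displacements of step `DTA/step_divisor` (default `DTA/10`) within radius
`search_factor * DTA` (default 3x) on a multilinear interpolation of the
grid, followed by branch-and-bound sub-step refinement. For each coarse
candidate a lower bound on the gamma attainable inside its lattice cell is
computed from the cell half-diagonal and a per-cell bound on the dose
gradient (finite differences of the grid, max-dilated by one cell); every
cell whose bound undercuts the incumbent is refined by local lattice descent
(9x9, re-centering at each scale while it improves, shrinking 4x down to
1e-5 mm), in ascending bound order, until the bound exceeds the incumbent.
The gradient-aware bound matters: with a steep penumbra and a tight DD, the
dose-agreement valley is narrower than the coarse step, and its coarse
samples can rank far from the top — a best-candidates-only refinement
silently returns gammas that are too large there. The result converges to
the continuous minimum of the interpolated field (verified in the tests
against an independently coded dense-search oracle to 1e-3 per point on 20
synthetic cases). Speed was deliberately traded for verifiability — the
worst case remains exhaustive. Cohort-scale simulations
use a documented fast preset (`step_divisor=5`, no refinement): only the
pass/fail count at gamma = 1 matters there, and candidate doses are cached
across measurement realizations because the detector positions and the
calculated grid are fixed.

Degenerate inputs: a reference point outside the grid inflated by the search
radius raises `OutOfBoundsError`; a zero normalization dose raises
`NormalizationError`; a cohort in which no point survives the threshold
raises `EmptyAnalysisError` (distinct from GPR = 0).

## Ground truth and ROC analysis

A unit (plan, or arc in field-by-field mode) carries the TPS-calculated and
the measured absolute isocenter dose. Its signed deviation is
`delta = 100 * (D_meas - D_calc) / D_calc` (the TPS value is the reference
the QA interrogates). At agreement level `L` (1-5% by default), the unit
*fails* the ground truth iff `|delta| > L`; the boundary counts as a pass.

The positive class is ground-truth **fail**, and a unit is test-positive at
threshold `t` when its GPR is strictly below `t`. Sweeping `t` over 0, every
observed GPR, 100 and a final flag-everything point yields the exact step
ROC from (0,0) to (1,1). The AUC is the trapezoidal area, which equals the
normalized Mann-Whitney statistic `U/(n_fail * n_pass)` with ties counted
one half — an identity the test suite checks exactly on random data.

The optimal threshold (OPTh) is the curve point minimizing the Euclidean
distance to the upper-left corner (0,1). Ties are broken toward higher
specificity (fewer false alarms in QA), then toward the lower threshold.
Because any threshold in the interval between two adjacent observed GPRs
classifies identically, the OPTh is reported as the midpoint of the optimal
point's equivalence interval (lower bound 0 below the smallest observed GPR;
the interval above the largest observed GPR is capped at 100). This is why
reported OPThs generally fall *between* observed GPRs.

AUC significance against the random-guess null (AUC = 0.5) uses the
two-sided two-sample Mann-Whitney U test on the pass/fail GPR distributions:
exact enumeration when `n_fail * n_pass <= 400` and the data are tie-free,
otherwise the tie-corrected normal approximation with continuity correction.
A known limitation worth stating: at cohort sizes of tens of units this test
cannot produce p-values many orders of magnitude below ~1e-12; published QA
tables sometimes print far smaller values, which cannot arise from the
standard two-sample test at those sample sizes and are not reproduced here.

`ROCStudy` / `ROCStudyResults` wrap the full (mode x criteria x level) grid
the way statsmodels wraps a model and its fit: rows with degenerate labels
(all pass or all fail) are reported as undefined rather than dropped, and
the per-mode percentage of significant AUCs is exposed as a summary.

## Spearman permutation correlation

Cross-device GPR agreement and complexity-vs-deviation relationships are
assessed with the Spearman coefficient (Pearson correlation of mid-ranks)
and a two-sided permutation p-value: `p = (1 + #{|r_perm| >= |r_obs|}) /
(n_perm + 1)` over `n_perm = 10000` seeded random shuffles of one rank
vector. For n <= 7 all `n!` permutations are enumerated and the p-value is
exact. Constant inputs raise `UndefinedCorrelationError`.

## Aperture complexity and quality indices

Per control point, with leaf-pair widths `w_i` and pair openings `g_i`:

* area `A = sum over open pairs of w_i * g_i`;
* perimeter `P` = exact rectilinear boundary length of the union of the
  open-pair rectangles: each open pair contributes its two leaf-tip edges
  (2 `w_i`), and each interface between vertically adjacent pairs
  contributes `|da| + |db|` when the two openings overlap in the leaf-travel
  direction, or both full openings when they are disjoint; boundary pairs
  expose their full opening. The per-leaf first-difference formulation of
  the perimeter leaves the boundary terms and disjoint-row case undefined;
  the union-of-rectangles reading resolves both, reproduces the 4A/P square
  limit, and is checked against a polygon-union oracle (shapely) on random
  apertures to 1e-6 mm.
* equivalent field size `EFS = 4A/P` (undefined — flagged, not zero — for a
  closed aperture).

A pair counts as open when its gap exceeds `gap_tol` (default 0.5 mm; smaller
gaps are closed-leaf leakage positions). Per plan or arc, `MEFS = mean(EFS)`
and `MSRA = mean(sqrt(A))`, unweighted means (no MU weighting) over the
control points with an open aperture; fully closed CPs are excluded and
their count reported.

Quality indices from a plan dose/volume summary: homogeneity
`HI = (D2% - D98%)/D50%` and conformity (inverse Paddick)
`CI = V_PTV * V_PIV / V_overlap^2`. Both are reported rounded half-up to two
decimals when regression against printed tables is wanted. The packaged
20-plan reference cohort reproduces 39 of its 40 published two-decimal
index values exactly; the one exception (patient 18's HI: recomputed 0.12 vs
published 0.11 from the row's own printed inputs, a one-ulp rounding
inconsistency of the published table, whose indices were evidently computed
from unrounded doses) is asserted as such in the regression test rather than
tolerated silently. Note the table legitimately contains a row with
D2 < D98; the summary type records it as-is.

## Synthetic-data generator

The generator is first-class, tested code: it defines the study conditions
under which every statistical claim of this package is exercised.

* **Field** (`simulate_field`): analytic 2D dose distribution, flat core
  with separable logistic penumbra; `penumbra_mm` is the 80-20 distance and
  the dose on the geometric field edge is half-maximum. Defaults: 30 mm
  field (SBRT-scale), 5 mm penumbra, 10 Gy maximum, 1 mm grid. The default
  field is deterministic; the seed argument exists for interface symmetry.
* **Detectors**: planar 2.5 mm-pitch square grid (high-resolution
  stereotactic array-like) and 10 mm-pitch unwrapped-cylinder grid (helical
  array-like), the resolution contrast being the study's central variable.
* **Measurement** (`simulate_measurement`): delivered dose = truth grid
  rigidly shifted and globally scaled, sampled at the diode positions with
  independent multiplicative Gaussian noise per diode.
* **Cohort** (`simulate_cohort`): per unit, a half-normal delivery-error
  magnitude `e` drives shift (`shift_sd * e`, random direction) and scale
  (`scale_sd * e`, random sign); GPRs for all six criteria are computed by
  the gamma engine. The isocenter deviation magnitude is coupled to `e`
  through a Gaussian copula with coupling `kappa` (fraction of variance on
  the Gaussian-score scale): `kappa = 0` gives an independent half-normal
  deviation, `kappa = 1` with zero noise gives `|delta| = delta_sd * e`
  exactly. Defaults: n = 20 units, shift_sd = 1 mm, scale_sd = 2%,
  noise_sd = 1%, kappa = 0.8, delta_sd = 2.5% — error scales at the edge of
  clinical action levels, chosen so the GPR distribution spans its dynamic
  range rather than saturating at 100%. Unit-level randomness comes from
  per-unit child seeds, so cohorts differing only in detector share their
  error realizations (two devices measuring the same deliveries), which is
  what makes cross-device correlation analyses meaningful.

What the generator does *not* emulate: MLC-resolved delivery errors, TPS
dose-engine artefacts, detector spectral/field-size response, angular
dependence, setup rotations. Consequences: passing tests demonstrate the
statistical machinery (threshold selection, significance, coupling
recovery) under a controlled error model, not the clinical GPR values or
AUCs of any real device pair, which depend on those unmodelled physics.

## Validation-study problem sizes and design choices

The statistical validation tests run: null cohorts (kappa = 0) of n = 200
units across 100 seeds on the coarse cylindrical layout (a ties-robust
property, and the cheaper geometry); the coupling sweep kappa in
{0, 0.4, 0.8} at n = 200 and the perfect-coupling check (kappa = 1, zero
noise, n = 50) on the high-resolution planar layout — exact AUC = 1.0
requires GPR to rank units strictly by error magnitude, and a 36-diode
layout quantizes GPR into ties, which is precisely the resolution effect
the two-detector comparison is about. Oracle-equivalence cases use grids of
at most 50 x 50 samples so the dense reference search stays exhaustive.

Numerical conventions collected in one place: gamma pass at `gamma <= 1`
exactly; ground-truth pass at `|delta| <= level` exactly; round-half-up for
printed-table regression; OPTh tie-breaks as above; permutation p-values
include the identity permutation (so `p >= 1/(n_perm+1)`); all randomness
flows through explicitly seeded `numpy` generators and every simulated
artefact records its seed.

## Known limitations

* The gamma search is exhaustive-plus-refinement, O(points x lattice); it is
  built for auditability at QA problem sizes, not for 3D dose cubes at
  sub-millimetre steps.
* The Mann-Whitney approximation inherits its usual small-sample behaviour
  under heavy ties (the exact path switches off when ties appear).
* Synthetic cohorts use one shared field model per cohort; real cohorts mix
  plan geometries, which adds between-unit GPR variance the generator does
  not model.
* DICOM RT Dose/Plan import is intentionally out of the core: the documented
  text/JSON formats keep the pipeline testable offline, and an adapter can
  sit on top of the same types.
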