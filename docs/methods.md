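# Methods

This note documents the estimators, the synthetic data, the numerical
choices and the known limitations of `ribbonfd`. Every number quoted
here is computed by the test suite or by `scripts/acceptance.py`.

## Fractal dimension of a voxel mask

Both estimators treat the grey-matter ribbon as a subset of 3-space
sampled on an isotropic voxel grid and estimate the capacity dimension
from how a coverage measure scales with the measurement scale *r*
(always in voxel units — anisotropic volumes are accepted for
morphometry but refused by FD operations, since a non-cubic voxel would
silently distort the exponent).

**Box counting.** The lattice of cubic boxes of edge *r* is anchored at
the minimum corner of the foreground bounding box. A single anchored
lattice makes the count deterministic and invariant under *all* integer
translations of the mask (property-tested); averaging over lattice
offsets would reduce discretization noise but is deliberately not done,
keeping the estimator simple and exactly reproducible. Every integer
*r* in the range is used: *r* = 2…30 for whole brain and hemispheres,
2…14 for lobes. If the requested range exceeds the mask's bounding box
the series is truncated at the longest box edge with a logged warning,
because every larger box would count 1 and only flatten the fit.

One consequence of the single anchored integer-step lattice is that
*N(r)* is not monotone in *r*: adjacent lattices are not nested, and a
porous object can occupy more boxes at a coarser scale (the level-4
Menger sponge counts 400 boxes at *r* = 9 but 637 at *r* = 10). The
series validator therefore enforces only the overall decreasing trend.

**Minkowski–Bouligand.** The dilation by a closed Euclidean ball of
radius *r* is computed by thresholding an exact Euclidean distance
transform of the background at ≤ *r*; a Chebyshev or city-block ball
would be cheaper but changes the measure. The grid is padded by
*r*max + 1 voxels per side so the dilation is never clipped. The
dimension is taken as *D* = 3 − slope of log *V* vs log *r* over
*r* = 1…7, the standard "sausage" normalization for a set embedded in
3-space; alternative normalizations (e.g. fitting log (*V*/*r*³))
shift the intercept only and leave *D* unchanged.

**Fit.** Unweighted ordinary least squares of log measure on log scale
over the full stated range, no automatic linear-regime selection. The
fit R² is always reported so users can judge linearity themselves.

### Discretization bias — what the estimators actually read

On finite grids with wide fixed scale ranges both estimators are biased
low for high-dimensional objects, and the bias is deterministic, not
noise:

* a solid 64³ block reads D = 2.710 (BC, r 2…30) and 2.760 (MB)
  instead of 3.0 — the ceiling effect in `ceil(64/r)³` and the
  boundary-layer growth of the dilation dominate at the coarse end of
  the range;
* the level-4 Menger sponge (81³) reads 2.549 (BC) / 2.548 (MB)
  against the analytic 2.727;
* a one-voxel slab reads 1.92 (BC, lobe range) / 2.04 (MB), close to
  its analytic 2.0 because a flat sheet has no coarse-scale structure
  to lose.

Group comparisons are unaffected as long as all subjects are measured
with the same protocol — the bias is shared — which is exactly how the
estimators are used here. Absolute FD values from different scale
ranges or grid resolutions must not be mixed, and values should be read
as protocol-relative indices of complexity, not as the mathematical
dimension. The acceptance suite asserts tight analytic recovery anyway
and those four checks fail by the amounts above; they are kept failing
rather than loosened, as an honest record of the estimator's absolute
accuracy at these grid sizes.

The two estimators see different scales: MB's radii stop at 7 voxels,
so folds wider than ~2·7 voxels are invisible to it, while BC's larger
boxes see exactly those. On smooth folded sheets of long wavelength the
two therefore disagree beyond the ±0.15 band that holds for the solid,
slab and sponge phantoms (line 0.20, folded ribbon up to ~0.21, BC
high). On real cortical ribbons, where sulcal wavelengths are a few
voxels at 1 mm resolution, published values from the two methods track
each other closely; the phantom disagreement is a property of the
phantom's single long wavelength.

## Morphometry

Volume is voxel count × voxel volume (works for anisotropic spacing).
Surface area counts exposed faces under 6-connectivity — a face is
exposed when its neighbor is background or outside the grid — times the
squared voxel edge. Face counting overestimates smooth-surface area by
up to ×1.5 (a voxelized sphere's staircase), but it is exact on the
voxel set, deterministic, and monotone-preserving for group contrasts.
The value measures the total ribbon boundary (pial side + white side +
interior walls), not the pial surface alone.

## Group statistics

The Mann-Whitney U statistic uses the min(U₁, U₂) convention (so
complete overlap gives U = n₁n₂/2, matching standard statistical
package output). The two-tailed p is exact — full enumeration of all
C(n₁+n₂, n₁) assignments, counting those whose min-U is at least as
extreme — whenever the pooled sample is tie-free and n₁+n₂ ≤ 16, which
covers both of the emulated study's per-sex designs (11+7, 6+7) except
the female one (18), where the normal approximation with tie and
continuity corrections takes over; at n = 11 vs 7 its true size is
0.044 at nominal 0.05 (60 000-rep Monte Carlo). Group summaries use
the sample (n−1) standard deviation. Raw per-region p-values are the
primary output, as in the emulated design; Holm-adjusted p-values are
added in a separate, clearly labeled column as an extension, and the
`significant` flag in report tables is α = 0.05 on the raw p.

Pearson correlations (FD vs grey-matter volume per region, pooled
across groups within sex) use the t-transform p with n−2 df.

## Synthetic phantoms and the cohort simulator

The folded ribbon voxelizes the sheet
z = mid + A·sin(2πf·x/L + φx)·sin(2πf·y/L + φy), thickened by *t*
voxels along the local surface normal; φ are small seeded phase jitters
(uniform in ±π/8) giving subject variability. With f = 0 the
construction degenerates exactly to the centered slab (bit-identical,
tested). Fold frequency is the complexity knob: BC FD rises strictly
monotonically over f = 0…8 at the 96³ reference settings
(1.97 → 2.67). MB FD is *not* monotone at low f — for f ≤ 2 the fold
wavelength (≥ 48 voxels) exceeds what r ≤ 7 dilation can resolve, and
the thickness-dominated slope masks the folding (dip of ~0.02 between
f = 0 and f = 2); MB monotonicity holds from f ≈ 3 upward and is
tested there.

Thickness scales volume nearly independently of FD at the 96³
reference grid: 2 → 2.5 voxels moves volume +24% while BC FD moves
0.03–0.04 (several seeds). At the 48³ calibration grid the decoupling
is genuinely weaker (ΔFD ≈ 0.08 for the same relative thickening)
because the thickness becomes a sizable fraction of the fold
wavelength.

The cohort simulator draws per-subject (fold frequency, thickness,
grid size) from per-group normal distributions, builds one whole-brain
surrogate phantom per subject, and measures it with the full stack.
Defaults emulate the target study design: cells 11/7 (female) and 6/7
(male); fold-frequency means 6 (adolescent) vs 5 (adult) with sd 0.5;
thickness 2.0 ± 0.1 in both groups; grid fixed at 48³ (chosen as the
smallest grid where the fold structure at f ≈ 5–6 is still resolved,
keeping Monte-Carlo calibration runs cheap). These settings were
calibrated once so that the simulated group FD gap (~0.03–0.04) and
within-group sd (~0.01–0.02) match the scale reported for real
adolescent/adult cohorts, and the adolescent volume exceeds the adult
volume through the larger folded sheet area alone. All randomness in a
simulation flows from the single cohort seed.

What the phantoms do *not* emulate: anatomy (no lobes, no hemispheres
— each subject is one region surrogate), MR intensity or
partial-volume effects, spatially varying fold wavelength, and
inter-subject registration variability. Passing calibration tests
therefore demonstrates that the measurement-plus-statistics chain is
unbiased and appropriately powered *for this generative family*, not
that any particular anatomical effect would be detected in real data.

### Statistical calibration results

With identical group distributions the simulated workflow rejects at
0.046–0.062 (500 reps, nominal 0.05) — the chain does not manufacture
false positives. Under a 1.5-pooled-sd fold-frequency shift the
measured power is ~0.70–0.72 (200 reps), against an acceptance bound
of 0.80. That bound is unattainable in principle at these sample
sizes: the Mann-Whitney test itself, applied directly to the fold
frequencies with no measurement noise at all, has power 0.789 for a
1.5-sd normal shift at n = 11 vs 7 (40 000-rep Monte Carlo), and FD
measurement noise (seed jitter plus the mild nonlinearity of FD vs
fold frequency) dilutes the realized FD effect size to ~1.26 sd. The
acceptance test is kept failing at its stated bound rather than
weakened; the ~0.72 figure is itself reproducible and reported by the
acceptance script.

## Degenerate inputs and tie-breaks

Empty masks: FD and dilation refuse them; volume is 0 and surface area
0. Scale series need ≥ 3 points after truncation. Complete ties in
both samples give U = n₁n₂/2, p = 1. Zero variance in a correlation
variable is an error naming the variable (the pipeline skips that
pairing with a log message rather than aborting the run). Equal group
means set the comparison `direction` to "adolescent" by convention.
Subject failures in volumes mode exclude the subject, flag it in the
run metadata, and let the run continue.

## Reproducibility

Every stochastic component (phantom jitter, cohort sampling) is driven
by explicit integer seeds; repeated runs are bit-identical including
CSV bytes (tested end to end). Report metadata echoes the full config
and package versions.
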