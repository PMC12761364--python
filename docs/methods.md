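# Methods

## Descriptor generation

Every compound of a congeneric series is a 2D drawing on a shared template:
the core occupies identical coordinates in all records, substituents hang off
fixed anchor points. `check_alignment` enforces this before any
rasterization, with a deliberately strict default tolerance (1e-3 template
units): sketches are copies of one hand-drawn template, so any core deviation
indicates a data error, not noise. The method is defined on drawings — z
coordinates must be constant and 3D conformers are rejected rather than
projected.

Rasterization paints each atom as a filled disk on a white (765) canvas,
default 432 × 300 px at 10 px per template unit:

* disk radius = `scale · r_vdW(element)` px, for every channel — atom *size*
  always encodes the van der Waals radius, following the augmented-MIA
  lineage in which element footprints are vdW-proportional;
* fill intensity = `765 · (1 − value / value_max)`, where `value` is the
  channel property (Pauling ε, Bondi r_vdW, or r_vdW/ε) and `value_max` the
  table maximum. The original software's intensity mapping is not public;
  any strictly monotone injective mapping feeds the same information to PLS,
  so this linear choice is a configuration point, not a claim about the
  original;
* bonds are 1-px Bresenham lines at intensity 0, drawn before atoms; atom
  disks overwrite in file order (painter's rule). No anti-aliasing; pixel
  membership is exact Euclidean distance — determinism and per-pixel
  testability over prettiness.

The element property table (Pauling electronegativities, Bondi radii for H,
C, N, O, F, S, Cl, Br) is a bundled CSV and fully swappable, because the
radius compilation used by the original software is unknown.

Unfolded row-major pixel vectors are stacked into X; columns with zero
variance across the series (background and shared core) are pruned and the
surviving indices recorded, so model vectors refold exactly into image-space
interpretation maps (pruned pixels rendered as NaN background).

## PLS model

Single-response NIPALS with mean-centering of X and y; no autoscaling by
default (pixel intensities share one physical scale; a flag enables it).
With one response the inner NIPALS iteration converges in a single step, so
each component is computed directly from the covariance direction X'y —
deterministic, no random initialization. Requesting more components than the
deflated data supports (Frobenius norm of deflated X below 1e-12, or a
vanishing covariance direction) is an error naming the attainable maximum.

Component count is selected by leave-one-out RMSECV, scanning 1..A_max via
the nested-model property of NIPALS (one fit per left-out sample yields the
whole component path). Ties within a 1e-6 relative band break toward the
smaller model; the band also absorbs floating-point noise on noiseless data.
A_max defaults to 8–10 in the pipeline entry points; the selection is capped
at what the data's rank and the n−1-sample LOO fits can support.

VIP uses the standard normalization `Σ_j VIP_j² = p`; coefficient and VIP
vectors refold into MIA maps through the recorded kept-column indices.

## Validation battery

All statistics are produced by one bootstrap loop per channel (default:
25 % holdout, floor(frac·n) samples drawn without replacement, 10 cycles,
seeded): per cycle the component count is re-selected on the training
portion, then calibration r²/RMSEC, LOO q²/RMSECV, Y-randomization
(default 50 permutations; the original count is unstated, 50 keeps the
penalty stable at this n), and the external statistics on the holdout are
computed. Channel columns are cycle means (hence fractional "PLS comp."
entries); the cross-channel report shows mean and sample (ddof=1) standard
deviation with cutoff verdicts evaluated on the mean column.

Conventions, fixed so tests can be exact:

* r²_pred uses the training-set mean in the denominator
  (Golbraikh–Tropsha convention);
* Lin's CCC uses population (1/n) moments; Pearson r uses sample moments;
* Roy's r0² is the through-origin coefficient of determination of observed
  on predicted, the reverse metric swaps roles;
* cr²_p = r·√(r² − mean r²_y-rand) with r, r² from the unpermuted model; a
  negative radicand yields 0 with a warning;
* the best bootstrap cycle maximizes the count of above-cutoff statistics,
  tie-broken by their mean — the published selection rule for a "best model"
  among cycles is not fully specified, so this rule is explicit and
  configurable.

Williams analysis computes leverage in PLS score space
(h_i = 1/n + t_i'(T'T)⁻¹t_i, Σh = A+1) and internally studentized residuals;
flags use |studentized residual| > 2.5 and h > 3(A+1)/n. The published
phrasing of the residual threshold ("threshold of 2.5 for p") is ambiguous;
it is implemented as a threshold on the studentized residual itself, which is
the standard reading. Outlier *removal* is never automatic — the pipeline
reports flags and refits only on explicit request, because the decision to
drop samples properly rests on inspection.

## Candidate design

The shortlist of favored substituents per position is user input: the maps
(VIP magnitude and signed coefficients) localize importance to positions, but
translating that into specific substituents mixes map evidence with chemical
reasoning that is not algorithmic, so both map kinds are produced and the
choice is external. Candidates are the deduplicated Cartesian product of the
shortlists, drawn on the same template grid (no automatic layout — the
descriptors are alignment-sensitive). Each candidate is predicted by all
three channel models — each model renders the image kind it was trained
on — and reported as mean ± sample sd of the three predictions (the error-bar
convention for a three-measurement spread). Ranking is by mean predicted
pK_i against a reference value (mesotrione's 7.699 by default).

## Docking evaluation

`DA = f_l + 0.5·(f_h − f_l)` with f_l, f_h the cumulative pose fractions at
RMSD ≤ l and ≤ h (closed intervals: a pose at exactly l counts in f_l, at
exactly h in f_h, matching "up to l Å" / "between l and h Å" banding and the
83/17 → 0.915 worked example). RMSD is computed on matched atom order with no
superposition and no symmetry correction — docking engines preserve atom
order, but symmetric ligands would need automorphism-aware matching; known
limitation.

Binding-energy totals sum electrostatic + vdW + torsional terms, excluding
the ligand-internal term. Reported totals are checked at ±0.015 kcal/mol
(values printed to 0.01 kcal/mol can drift that far through rounding of the
individual terms); deviations beyond the band are flagged, never corrected.

The activity–energy regression pools all three per-channel pK_i predictions
per compound as replicate observations in an OLS fit (statsmodels), reporting
slope/intercept with standard errors, R²/adjusted R², internally studentized
residuals, and the replicate-based lack-of-fit partition
F = (SS_lof/(k−2))/(SS_pe/(N−k)). Zero pure error with genuine lack of fit
reports F = +inf with a warning; floating-point residue on exactly-linear
data is zeroed at 1e-12 relative tolerance.

## Synthetic data

The generator emulates the study conditions of a merged congeneric series:
59 samples, baseline pK_i 7.0, Gaussian response noise sd 0.2 pK_i units,
substituents drawn uniformly per position from the pools

| position | pool (effect, pK_i units) |
|---|---|
| R1 | H (0), CH3 (−0.45), C2H5 (−0.70) |
| R2 | H (0), Cl (+0.30), F (+0.22) |
| R3 | H (0), OCH3 (+0.80), Cl (+0.65), CH3 (+0.15) |
| R4 | H (0), CH3 (+0.25), Cl (+0.10) |

The pattern encodes the known structure–activity picture for this class —
strong electron-donor/halogen gains at R3, mild gains at R2/R4, steric
penalty for alkyl at R1 — with effect sizes inside ±0.8 so generated pK_i
values span roughly 6–8, comparable to the real series. Effects are strictly
additive: image descriptors of stamped fragments are additive presence
indicators, which makes ground truth exactly recoverable and gives
parameter-recovery tests a well-defined target. What the generator does *not*
emulate: correlated substituent occurrence, activity cliffs, conformational
or tautomeric variability, and drawing-style variance between operators —
so passing recovery tests demonstrates the pipeline's correctness on its own
model class, not predictive validity on new laboratory data.

Optional features: per-atom coordinate jitter (clipped at 2 sd per
coordinate, so alignment-tolerance tests have a hard bound) and a planted
response outlier (default shift 5·noise_sd). When an outlier is planted, the
clean samples' noise can be truncated at 2 sd so the plant is provably the
only extreme residual and outlier-flagging checks are exact rather than
probabilistic.

Pose-set fixtures draw RMSDs uniformly within prescribed bands, strictly
away from the band edges, hitting rounded target counts; energy-table
fixtures produce rows whose reported totals are exact sums except for
explicitly requested perturbations (which must exceed the consistency
tolerance), with the perturbation record returned.

## Problem sizes and determinism

Default pipeline runs use n = 59 samples, three channels, A_max = 8–10,
10 bootstrap cycles and 50 Y-randomization permutations; a full three-channel
battery completes in well under a minute, and the 10-seed recovery surface in
the acceptance tests in a few minutes. Every random draw (generator,
bootstrap holdouts, permutations) descends from an explicit integer seed
through `numpy.random.default_rng`; reruns with the same configuration are
byte-identical, which the CLI tests assert on serialized reports.

## Known limitations

* The original study's absolute statistics depend on its hand-sketched
  images and the closed-source intensity mapping, so they are not
  reproducible from published information; the synthetic recovery surface
  stands in for them.
* Single-response PLS only; no kernel/nonlinear variants, no variable
  selection beyond zero-variance pruning.
* MOL2 support is a minimal TRIPOS subset (no substituent-label persistence);
  SDF is the primary interchange format.
* Pose RMSD assumes consistent atom ordering (no symmetry correction).
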