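# Methods

This note records the models, defaults and design choices behind
`dotgrid`, and what the synthetic fixtures do and do not establish about
real imagery.

## Color model and cube quantization

Pixels are integer triples in `[0, 255]^3` under RGB or HSV; HSV channels
are rescaled from their conventional ranges onto `[0, 255]` and rounded,
so both models share one lattice.  Scale-`n` cubes are
`floor(channel / n)` bins with `ceil(256/n)` cubes per axis, so the last
cube per axis may be thinner (n=10 gives a 26×26×26 grid).  The
color-complexity of a pixel multiset is `#occupied cubes / ceil(256/n)^3`;
each occupied cube is represented by the center of mass of its pixels.

Hue is binned linearly.  Hue is circular, so a red hue near 255 and one
near 0 land in distant cubes; for yellow/purple cards no mass sits near
the wrap point and the approximation is immaterial, but it is a known
caveat for targets near red.

## Segmentation

Two branches run independently and are fused at the end:

| branch | training (row HC) | recovery (reference cubes) |
|--------|-------------------|----------------------------|
| RGB    | scale 10          | scale 1                    |
| HSV    | scale 10          | scale 10                   |

Training always happens on the coarse scale, where rows have tens of
occupied cubes and the two color families form well-separated
representative clouds; recovery in RGB drops to unit cubes to sharpen
within-cube color uniformness.  Per focal row (default 39 rows × 10
squares), the cube representatives are clustered agglomeratively (Ward by
default; single/complete/average selectable) and cut at the root; the
smaller branch is purple.  Three guards make this safe on degenerate rows:

- a row with one occupied cube is purple-free;
- if the two root branches' mean representatives are closer than
  `sep_threshold` (default 30 channel units — comfortably above the
  within-family spread at noise σ≈4 and far below the ~190-unit
  yellow–purple separation), the row is declared purple-free;
- an exact branch-size tie labels purple the branch whose mean
  representative lies farther from the row's modal (most occupied) cube.

Validation projects each square's purple and yellow pixels onto the focal
area's global discriminant axis (difference of class mean colors) and
computes a rank AUC; squares with AUC < 0.95 or purple fraction > 0.8 are
reassigned wholly yellow.  The AUC rule catches mislabelled squares whose
"purple" is colorimetrically yellow; the fraction rule catches rows that
split a purple-free shaded region into two yellow tones.  These two rules
are this package's operationalization of a validation step whose exact
statistic is not standardized; both thresholds are configurable.

Reference cubes take majority vote in mixed cubes (ties to yellow), and
nearest-center classification breaks exact distance ties to yellow —
specificity is preferred throughout, since cleaning errs toward the
background class.  A branch that finds no purple in the focal area (e.g. a
dot-free card) contributes an all-yellow mask with a warning rather than
failing.  The focal area defaults to a centered rectangle covering 60% of
the paper area (each dimension scaled by √0.6); it should be placed so
that every shading level present on the card crosses at least some rows —
the row-wise divide-and-conquer can only learn shading it has seen.

## Dots and size laws

Connected purple components use 8-connectivity by default (4 selectable).
Pixels are lattice-center points: a singleton dot has radius 0 and two
edge-adjacent pixels radius 1/2.  The smallest enclosing circle is exact:
convex-hull reduction followed by the deterministic incremental
(Welzl-style) construction, verified against an O(n³) brute force in the
tests.  Size classes (small/medium/large) come from a 1-D Ward 3-cut on
the radii by default, with fixed thresholds as the alternative; fewer than
three distinct radii fall back to all-small with a warning.  The class
mean radii become the feature weights downstream.

`λ̂_P` is the mean pixel count (Poisson MLE); `λ̂_E` is the reciprocal
mean of the strictly positive radii (Exponential MLE — zero-radius
singletons carry no information about a continuous size law and are
excluded).  The KS test plugs in the fitted rate without a Lilliefors
correction, mirroring the plain procedure; this is anti-conservative when
the rate is estimated from the same data, and the tests therefore
calibrate it against the *true* rate.

## Grid categorization

Default 20×20 tiling (the rectangle count is configurable; aspect-driven
counts like 479 or 488 on non-square cards are supported by choosing rows
and cols).  Integer tiling gives every cell the floor share with the
trailing row/column absorbing the remainder.  Dots are assigned by
centroid membership.  The category ladder is applied in order R1 → R2 →
R3 → R4, which makes the qualitative rules mutually exclusive and
exhaustive (property-tested over all count vectors in `[0,5]^3`).  The
weighted distance `sqrt(Σ (w_i Δcount_i)^2)` with class-mean-radius
weights, and the HC tree it induces over the 400 feature vectors, are
provided as the diagnostic that motivates the ladder.

## Spatial-uniformness test

Cell coordinates are (row, col) in grid units and inter-cell distance is
plain Euclidean distance between cell centers.  The null resamples `k`
*distinct* cells uniformly (sampling without replacement — cells are
distinct rectangles).  MSTs are built by Prim's algorithm with
deterministic lowest-index tie-breaking; every MST of a graph shares the
same edge-weight multiset, so all downstream statistics are tie-invariant.

The pooled `B+1` edge-length multisets are binned into 10 equal-width bins
over the pooled range (rightmost bin closed; every row sums to `k−1`); a
zero-range pool degenerates to one bin with a warning.  Ward linkage over
the raw count rows builds the tree (configurable and recorded in the
report — the p-value can depend on the linkage).  Each leaf's PO
multiplies, along its root path, the size of the branch containing the
leaf over the size of the sibling branch; the descent ends at the
singleton leaf.  This telescoped form is algebraically identical to the
coded per-step odds formulation (asserted to 1e-12 on 1,000 random trees)
and is orientation-invariant: swapping left/right children changes the
binary codes but not PO, hence not p.

`p = #{b : PO_b < PO_obs} / B` with strict inequality; ties count as
not-less, which can only make the test conservative.  Under the null the
observed row is exchangeable with the B null rows, so p is approximately
Uniform(0,1); the suite verifies a rejection rate at α=0.05 within
[0.02, 0.09] over 200 replicates.  The ROC AUC ensemble is computed in the
Mann–Whitney form `P(obs > null) + ½P(=)`: AUC < 0.5 means observed
distances are stochastically smaller (clustering).  AUC orientation is a
convention; it is fixed and documented here because either direction
appears in visual presentations of such curves.

## Synthetic fixtures

`generate_card` stamps purple disks (default Poisson(200) dots, radii
Exp(scale 3) clipped to [1, 15]) on a yellow base (default yellow
(225, 215, 70), purple (110, 60, 150) — plausible stand-ins, as no
numeric card colors are standardized), applies multiplicative shading per
declared region, then adds Gaussian channel noise (σ=4).  The default
card is 1000×600 px, large enough for a 39-row focal area yet cheap to
segment.  The shading scenario used in the recovery tests places
horizontal bands (0.85 above, 0.7 below) across the focal area, matching
the method's assumption that the focal rows see every shading level.

What the card generator does *not* emulate: pigment diffusion and
irregular stain outlines, overlapping-droplet coalescence physics,
perspective distortion and curved papers, global illumination gradients,
JPEG artifacts.  Passing the recovery tests therefore shows the algorithm
is correct under its stated model (two color families, local multiplicative
shading, sensor noise), not that it conquers arbitrary field photographs.

`generate_uniform_field` draws i.i.d. categories with default proportions
(0.0625, 0.0625, 0.125, 0.75), chosen so a 400-cell grid expects 25 R1
cells — the sparsity regime of a well-behaved card.  The clustered
generator seeds R1 blocks at the grid center (3×3) and bottom (3×5) and
propagates R2/R3/R4 to unlabelled 8-neighbors with probabilities
0.4/0.5/0.6; unreached cells stay unlabelled and never enter a testing
scale.

## Problem sizes and numerical choices

Tests and the acceptance script use B=500 null MSTs, 200 replicates for
distributional checks, 10⁴ draws for MLE recovery, and 1000×600 cards —
sizes at which every stochastic assertion sits several standard errors
from its bound.  Floating-point tolerances: enclosing-circle containment
1e-9; odds identities 1e-12 (pure products of small integers); all other
stochastic bounds are 3σ bands stated in the tests.

## Known limitations

- Linear hue binning (above).
- The row bipartition assumes exactly two color families per row; a third
  prominent family (e.g. heavy soiling) would need a deeper cut.
- The square-validation thresholds are heuristics; on cards whose shading
  splits rows into tones more separated than the target color, the purple
  fraction rule is the operative guard.
- The KS plug-in test is anti-conservative under estimated rates.
- p-values have resolution 1/B and a point mass at the floor; with B=500
  the smallest reportable nonzero p is 0.002.
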