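# Methods

## Model

The package studies the gray-level co-occurrence matrix (GLCM) of images
containing a single periodic linear gradient.  A phantom with `ng` gray
levels and gradient `grad` (integer levels/pixel) is the column-replicated
ramp

```
I(y, x) = (y mod P) * grad,     P = 1 + floor((ng - 1) / grad)
```

where `P` (written `n_tilde` in the code) is both the spatial period of
the ramp and the number of distinct levels it visits.  The ramp restarts
at zero as soon as the next step would reach `ng`, so it never leaves
`[0, ng - 1]`.  A formulation of the ramp as `(y mod ng) * grad` appears
in parts of the literature; it produces out-of-range values for
`grad > 1` and contradicts the worked pair counts that the closed forms
rest on, so the restart-at-zero ramp is implemented instead — it
reproduces every downstream quantity (entry counts, wrap pairings,
marginals) self-consistently.

At a vertical displacement of magnitude `d < P` the non-symmetrized GLCM
of one ramp period has exactly `P` nonzero cells of equal weight on two
lines parallel to the main diagonal: `m1 = P - d` cells with
`j - i = d*grad` and `m2 = d` wrap cells with `j - i = -m1*grad`.  All
closed forms follow from this support:

* sum average `f6 = (P - 1) * grad`, independent of `d`;
* sum variance `f7 = grad^2 (P^2/3 - P d + d^2 - 1/3)`;
* difference average (signed) `= 0`;
* difference variance `f10 = grad^2 d (P - d)`;
* joint entropy `f9 = log2(P)` bits (non-symmetrized GLCM).

The published final simplification of the difference variance,
`grad^2 d (P + 1 - d)`, is inconsistent with the two-line second moment
`(m1 (d*grad)^2 + m2 (m1*grad)^2) / P` it is derived from; the latter
reduces algebraically to `grad^2 d (P - d)`, agrees with brute-force GLCM
computation for every parameter triple tested, and is what the package
implements.  Similarly the wrap line is `j - i = -m1*grad` (not
`-(1 + m1)*grad`, a variant label that appears once in the source
derivations and fails enumeration).

Dropping the integer part gives the asymptotics `f6 ≈ ng - 1`,
`f7 ≈ (ng-1)^2/3 - (ng-1) d grad + d^2 grad^2 - grad^2/3`,
`f10 ≈ grad d (ng - 1) + (1 - d) grad^2` (coarsely `grad d ng`), hence
the scaling laws `f6 ∝ ng`, `f7 ∝ ng^2`, `f10 ∝ ng d grad`,
`f9 ∝ log ng`, and the quantization-invariant normalizations
`f6/ng`, `f7/ng^2`, `f10/ng`, `f9/log ng`.

All closed forms are restricted to `1 <= d < P`; for `d >= P` the
displacement exceeds the gradient period, the two-line structure breaks
down, and the functions raise instead of extrapolating.

## Conventions

**Coordinates and displacement.** The origin is the upper-left corner,
`x` runs rightward along columns, `y` downward along rows; `dx` is the
column offset and `dy` the row offset of the displacement.  Pair counting
never wraps around the image border — periodicity lives in the pattern,
not in the counter — so an `Nx x Ny` image yields exactly
`(Nx - |dx|)(Ny - |dy|)` ordered pairs.  An opt-in periodic counting mode
exists for experiments.  Negative offsets are allowed;
`count_pairs(-d)` is the transpose of `count_pairs(d)` (tested, not
assumed).

**Symmetrization.** `symmetrize` adds the transposed counts (the
classical definition) and refuses double application.  After
normalization, all features built on the sum marginal or the absolute
difference marginal (`f6, f7, f8, f11`) are exactly invariant under
symmetrization for *any* image.  Under the signed difference-average
convention the identity `f10_sym = f10_nonsym + da_nonsym^2` holds; on
gradient phantoms `da = 0`, so `f10` and `da` are invariant there too.
The joint entropy is the one feature symmetrization moves: it rises by
exactly 1 bit whenever the support is not transpose-closed, which for
gradients means whenever `P != 2d`.  The default is `symmetric=True`
(the convention of standard texture pipelines); the entropy closed form
`log2(P)` refers to the non-symmetrized GLCM, and the +1-bit shift is
handled — and reported — at the numeric feature layer.

**Difference average.** The signed mean `sum_k k * p(j - i = k)` is used
(it is what makes the gradient difference-variance derivation close);
many radiomics toolkits instead average `|i - j|`.  Both marginals are
materialized on `DiffMarginal` so either convention can be computed.

**Entropy.** Default `epsilon = 0` with `0*log 0 = 0`, log base 2
(bits), switchable to natural log.  A positive `epsilon` reproduces
legacy implementations that evaluate `log(p + epsilon)` to guard the
logarithm; this biases every entropy downward and is one of two
mechanisms (the other being the symmetrization bit) that offset numeric
entropies from `log2(P)`.  Both mechanisms are exposed rather than
conflated; no default `epsilon` other than zero is assumed since legacy
values vary by toolkit.

**Gray levels.** `ng` is image metadata, never inferred from the pixel
maximum, and no rebinning is performed.

## Phantom sizing

The generator defaults to 1024 x 1024 pixels, the size used in the
numerical experiments the theory was validated against; at fixed sizes
the trailing partial period introduces a small boundary deviation that
the sweep harness reports without correcting.  With
`exact_period_for=d` the height is trimmed to the largest `H` with
`H - d` divisible by `P`, which makes every nonzero GLCM cell receive the
identical count `width * (H - d) / P`; on such images numeric features
equal the closed forms to floating point, and this mode is the assertion
surface of the test suite.  Tests and the acceptance script use minimal
exact-period phantoms (`H = P + d`, width 3–8) — the uniform-count
property makes the features independent of how many periods are stacked,
so small images carry the full content of the check.

## Scaling-exponent fits

`fit_scaling_exponent` is a least-squares slope of `log(value)` against
`log(variable)` over at least three grid points.  Two measurement
subtleties:

* The sum variance rides on a displacement-free pedestal
  `grad^2 (P^2 - 1)/3` of order `ng^2`, from which the
  displacement-sensitive component `−grad^2 d (P − d)` (a *decrement*,
  equal in magnitude to `f10`) is subtracted before fitting against
  `|d|`; `sv_baseline` supplies the pedestal.  A raw log-log fit of `f7`
  against `|d|` would measure the pedestal, not the law.
* Flatness of `f6` and `f9` in `|d|` is checked as exact equality of the
  recorded values across displacements, which holds on exact-period
  phantoms because the per-cell probabilities are exact dyadic rationals
  at `grad = 1`.

The sweep harness also reports the relative error of the sum-variance
asymptotics under two period conventions (`P` and `P - 1`): the
worst-case error quoted for dense grids differs by about a percentage
point depending on the convention, and neither is singled out.

## What the phantoms do and do not show

The generator emulates exactly the idealized conditions of the theory:
noise-free, integer-step, one-dimensional periodic gradients.  Passing
tests therefore demonstrate that the engine and the closed forms agree on
their common domain — they say nothing about natural images, where
gradients are non-integer, two-dimensional, noisy and aperiodic, where
the GLCM support is not two-line and the closed forms do not apply.  The
numeric GLCM/feature path accepts arbitrary grayscale images, but no
analytic prediction is offered for them.  Out of scope by design:
simultaneous two-dimensional gradient vectors, noise models, gray-level
requantization of arbitrary images, closed forms for the remaining
Haralick features (`f1–f5`, `f12–f14`; sum and difference entropy `f8`,
`f11` are computed numerically and, in tests, from the two-point closed
marginal, but no closed form is exported for them).

## Problem sizes

The test suite validates the closed forms over the full study grid
(`ng` in 8–256, `grad` 1–8, `|d|` 1–8, valid combinations only, roughly
380 triples) on minimal exact-period phantoms, and recovers the scaling
exponents on `ng` in 32–256 and `|d|` 1–8 grids; the whole suite runs in
a few seconds.  The 1024 x 1024 default is exercised through the
generator's sizing logic rather than in bulk sweeps, a package choice
that keeps the checks exact while staying lightweight.
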