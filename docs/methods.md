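# Methods

This note records the models implemented in `helixtps`, their assumptions,
the defaults that matter, and what the synthetic data do and do not
emulate.

## Synthetic crystals

### A-form duplex generator

`build_aform_duplex` constructs an idealized duplex from a reduced
per-residue template in helix-local cylindrical coordinates: the six
backbone sites P, O5′, C5′, C4′, C3′, O3′ plus C1′, the glycosidic
nitrogen, and three base-ring pseudo-atoms marching toward the axis whose
weights carry the base-specific ring electrons (A 58 e⁻, G 66 e⁻, C 46 e⁻,
U 47 e⁻, after subtracting the explicitly placed nitrogen).  The
diagnostics this package computes depend on helical repetition, not on
chemistry, so no attempt is made at stereochemical realism; a full-atom
template would change none of the TPS statistics after E normalization.

Base pair *j* sits at height *j*·rise rotated by *j*·twist
(defaults: twist = 360°/11; rise = 266.94/99 Å ≈ 2.697 Å, i.e. one ninth
of c/3 of the reference cell spread over 11 bp, so three turns of the
32-bp duplex span one third of the 266.94 Å cell).  The true fiber rise
is exposed as a parameter rather than fixed, because the turn length is
known only to the ~29–29.7 Å level; all downstream period predictions are
derived from the cell and turn length actually used.  The second strand
is the exact dyad image of the first about the cartesian x axis — the
duplex is two copies of one self-pairing strand (10 A–U + 6 G–U pairs by
default), which is what allows a crystallographic two-fold to generate
the mate from a one-strand asymmetric unit in R32:H.  Strand-2 atoms are
annotated with their *spatial* base-pair index (pair n−1−j), so turn
annotations partition the duplex by height: 11/11/10 bp for 32 bp at
11 bp/turn.

The dsRNA-like preset places the duplex axis parallel to **c** at
fractional (0.25, 0, 0): on the two-fold axis along **a** (so one strand
is the asymmetric unit) but off the three-fold (which would superpose
rotational copies).  The R centering then stacks duplexes every c/3, and
the three turns per duplex complete the 9-fold c pseudo-repeat.  The
hairpin-like preset is a one-turn (11-bp) duplex tilted onto the a×b
diagonal of a 36 × 36 × 60 Å P4₃ cell at a general position — a special
position such as (½, ½) would let the 4₃ screw manufacture an artificial
c/2 pseudo-repeat, which is exactly what the control must not have.

### Imperfection model

`perturb_turns` degrades the pseudosymmetry along the two classical axes.
*Displacive*: each (strand, turn) block receives an independent rigid
translation jitter, and each atom an independent isotropic displacement,
both Gaussian with total expected displacement σ (component standard
deviation σ/√3).  Two independently jittered turns then differ by
√2·σ r.m.s.d. after translation-only superposition, which is how σ maps
onto the observable.  *Replacive*: a chosen fraction of base pairs is
re-typed to a different base — ring pseudo-atom weights change, backbone
positions do not.  A single integer seed makes every perturbation
bit-reproducible.

Known limitation: because turn jitters are independent, all turn pairs
are statistically equidistant (≈ √2·σ).  Real helices bend progressively,
so turns 1–3 of a deposited structure can be farther apart (≈ 1.7 Å) than
adjacent turns (≈ 1.3 Å); the generator reproduces the adjacent-turn
magnitude (σ = 0.9 Å gives ≈ 1.27 Å) but not the accumulation.

### Structure factors

`calc_structure_factors` performs direct summation over symmetry-expanded
atoms, F(h) = Σⱼ wⱼ·occⱼ·exp(−Bⱼs²/4)·exp(2πi h·xⱼ), with
constant per-element scattering weights (P 15, O 8, N 7, C 6 electrons)
and the form-factor falloff folded into B (default 10 Å²).  Wilson/TPS
statistics are invariant to this simplification once intensities are
normalized per resolution shell.  Unique indices are generated from the
full triclinic reciprocal metric, reduced under the point group plus
Friedel symmetry (cross-checked against gemmi's asymmetric unit), and
systematic absences are removed.  Synthetic sigmas follow
σ(F) = 0.02·|F| + shell-median floor (10 equal-count shells) — they exist
only so that F/σ profiles are computable, and model a detector whose
relative error saturates for strong reflections.

## Reciprocal-space diagnostics

**Normalization.**  E² = I/(ε·⟨I/ε⟩_shell) over equal-count shells
(default 20, ≥ 50 reflections each), with the shell-mean curve linearly
interpolated in s² between shell centres and then pinned so each shell's
mean Z is exactly 1.  Epsilon factors and centric flags are derived from
the operator set; distribution statistics use acentric reflections only
by default.  Negative input intensities are clamped to zero and counted
(no Bayesian intensity-to-amplitude conversion is in scope).

**Z-cdf comparison.**  The empirical cdf of Z is compared with the Wilson
acentric law 1 − e⁻ᶻ and with the perfect-TPS mixture law for *m*
translational copies ((m−1)/m extinct, 1/m exponential with mean m; mean
Z = 1 for every m).  The Kolmogorov distance honours the mixture law's
point mass at zero by comparing the empirical lower step against the
law's left limit; Z below 10⁻⁶ is treated as exact extinction so that
numerically zero structure factors land on the point mass.

**l-profiles.**  Mean F/σ per l Miller index over all h, k.  The dominant
period comes from the discrete autocorrelation of the mean-centred,
variance-normalized profile: the candidate is the smallest lag within 90%
of the autocorrelation maximum (so harmonics at 2×, 3× the period do not
masquerade as the answer), scored in units of the white-noise standard
error 1/√(n−k) of a sample autocorrelation.  The default acceptance
threshold is 3; flat or aperiodic profiles return no period.  The score
is scale-invariant by construction.

**Scattering power.**  Cumulative fraction of Σ|F|² in descending-
amplitude order (F000 absent throughout), plus top-N deletion with an
exact removal manifest — the removed power fraction satisfies
1 − ΣF²(kept)/ΣF²(all) identically.

## Patterson analysis

Maps are synthesized by FFT with |F|² coefficients (E² sharpening by
flag), Friedel-completed and expanded to P1 under the point-group
rotations, F000 omitted so the map mean is zero.  Default grid spacing is
d_min/3 with FFT-friendly dimensions; map σ excludes a 5 Å origin
sphere.  Peak search takes 3³-neighbourhood local maxima above a σ
threshold, refines positions by separable quadratic interpolation,
greedily enforces a minimum separation, and excludes the origin together
with the pure centering translations — in R32:H the vectors (⅓ ⅔ ⅔) and
(⅔ ⅓ ⅓) carry full origin height and no TPS information.  The TPS
verdict declares detection when the strongest remaining peak reaches 20%
of the origin height (configurable; the deposited-data regime sits near
57%, well above, while imperfection pushes synthetic peaks down toward
it).

The delete-turn check recomputes calculated Pattersons with one annotated
turn removed: deleting the middle turn of three removes the one-turn-
length peak (both surviving pairs are two turns apart); deleting an end
turn removes the two-turn peak.  Peak presence means ≥ 5σ within two grid
steps of the expected distance.

## Model-level TPS

`translation_rmsd` superposes two turns by pure translation (difference
of paired-atom centroids), pairing residues by offset within the turn and
atoms by name; the r.m.s.d. after translation measures how far the turns
are from ideal pseudosymmetry.  Rotation is deliberately excluded — the
quantity of interest is the quality of the *translation* relating the
turns — though the backbone subset is a flag ("backbone" = P, OP1, OP2,
O5′, C5′, C4′, C3′, O3′; sugar ring excluded) because conventions differ.
Fractional coordinates are unwrapped about their per-axis circular mean
before orthogonalization, so a molecule wrapped across the cell boundary
is reassembled correctly provided it spans less than half the cell.

`predicted_period` counts repeats per cell: duplexes stacked along c
(three, from the R centering) times turns per duplex (round(c/3 / turn
length)) — 9 for the reference geometry, 1 for a single-turn cell.

## Phasing-trial statistics

Each phasing experiment is modelled as independent Bernoulli trials with
per-trial success probability p, capped at 600 trials (the batch-queue
limit the experimental protocol used); the observable is the number of
failures before the first success, right-censored at the cap.  The
maximum-likelihood estimate under censoring is
p̂ = S / (Σ_successes (xᵢ + 1) + Σ_censored cap), with a standard error
from the observed Fisher information.  Geometric probability plots use
plotting positions (i − ½)/n against the fitted quantiles; heavy
censoring shows up as flattened upper-tail outliers and a degraded
correlation.

The k-sample Anderson–Darling test is implemented in the tie-aware
(midrank) form with its exact null variance and a p-value interpolated
from the published critical-value coefficients (quadratic in log-
significance inside the tabulated 0.25–0.001 range, monotone log-linear
extrapolation outside it).  A seeded permutation p-value is available and
becomes the default whenever any sample has fewer than five
observations.  The statistic is rank-based and therefore invariant under
any common strictly monotone transform; calibration checks in the test
suite verify ≈ 5% type-I error at α = 0.05 and essentially full power
separating the hard (p ≈ 0.004) and easy (p ≈ 0.023) phasing regimes at
their observed sample sizes.

## Phase-set figures of merit

The global trial score combines correlation components defined on the
normalized structure factors: CC_all between observed and calculated E;
CC_large over the 70% largest observed E; CC_weak over the 30% smallest;
CC_w,E between the large observed E and their statistical weights (the
calculated E serve as the weight proxy when none are supplied); and
RAT = ⟨E²_calc⟩_weak / ⟨E²_calc⟩_all, which falls well below 1 when the
trial map correctly leaves weak reflections weak.  The combination

    ffom2 = CC_all + CC_large + CC_w,E + 1/RAT   (RAT floored at 0.1)

is this package's own rendering, chosen so that a random map scores ≈ 1,
a correct map ≈ 5, and the conventional success threshold of 3.0
separates them; the components are computed and tested independently of
the combination, so any alternative assembly can be formed from the
report fields.

Phase-set agreement is measured by the weighted mean absolute circular
phase difference (wMPE; 90° for unrelated sets) and a map correlation
evaluated in reciprocal space via Parseval, with the weights doubling as
Fourier amplitudes.  Origin and enantiomorph ambiguity is *not* searched:
callers must pre-align phase sets, and the implementation asserts
invariance only under identical shifts applied to both sets.

## Problem sizes and numerical choices

The test suite and the acceptance script generate data at working
resolutions of 1.6–3.0 Å rather than the 1.05 Å of the reference
experiment: every diagnostic here (Patterson turn peaks at 29.7/59.3 Å,
l-period 9, Z-law distances, power curves) is fully resolved at those
spacings, and the direct-summation structure factors scale linearly in
reflections × atoms.  The full 1.05 Å reference cell (≈ 45k unique
reflections) remains the CLI default for the presets.  Ties in peak
search are broken toward the lexicographically lowest fractional
position; quadratic refinement clamps vertex offsets to half a grid
step; degenerate inputs (empty peak lists, all-censored experiment sets,
all-identical samples, single-reflection cdfs) return explicit flags or
errors rather than silent numbers.

## What the synthetic data do not show

The generator reproduces the geometry of helical-repeat TPS and its
reciprocal-space consequences, but not: solvent contribution or bulk-
solvent modulation; anisotropic displacement; realistic measurement-error
correlations (sigmas follow the simple saturating model above);
progressive helix bending (see the imperfection model); or the internals
of any direct-methods program — per-trial figure-of-merit trajectories,
tangent-formula refinement and origin-fixing procedures are out of scope,
so the deposited experiment's headline values (mean failed trials, the
winning trial's combined score and phase error) are not reproduced here,
only the statistical machinery for analysing such experiments.
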