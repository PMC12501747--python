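# Methods

## Signal model

A WASABI acquisition saturates with a single rectangular pulse of duration
t_p and samples the normalized water signal at offsets Δω around the water
resonance.  The signed model per voxel is

    Z(Δω; c, d, δω, B1) = c − d · A(Δω) · sin²(π t_p √((γ̄B1)² + D²)),
    A(Δω) = (γ̄B1)² / ((γ̄B1)² + D²),   D = (Δω − δω)·ω0  [Hz]

with offsets and δω in ppm, ω0 the reference frequency in MHz (so ppm·MHz =
Hz), B1 in μT and γ̄ = 42.577 MHz/T (so γ̄B1 is in Hz).  A(Δω) is the
amplitude envelope sin²(atan(γ̄B1/D)) written rationally; its on-resonance
limit is 1.  c and d are surrogates for relaxation and incomplete recovery;
reconstructed magnitude images reflect negative lobes across the x-axis, so
fitted templates use |Z| while the signed model is kept for simulation.

The maxima flanking δω are the first Rabi nulls, at integer phase
n = ⌈γ̄·B1·t_p⌉.  Their separation x (ppm) inverts to

    B1 = (1/γ̄) √((n/t_p)² − (x·ω0)²/4),   n = 1 if x ≤ 2/(ω0·t_p), else 2,

and their midpoint is δω.  The threshold 2/(ω0·t_p) (≈1.34 ppm at 7 T with
t_p = 5 ms) is both the branch switch and the point of maximal dB1/dx.
Above B1 = √3/(γ̄t_p) (≈8.1 μT here, 2.2× the nominal power) the branch-2
distance falls back below the threshold and becomes degenerate with a
low-power branch-1 alias; no rule based on x alone can separate the two, and
the inversion returns the alias.  The admissible-B1 bound (1.5× nominal)
keeps the search far from this regime.

## The voxel fit

1. **Smoothing.**  A cubic smoothing spline of the Reinsch (curvature-
   penalized) type is fitted to the sampled spectrum.  The penalty weight is
   chosen by bisection as the largest value whose summed squared residual
   stays within a budget ε + 0.5·N·σ̂², where ε = 3·10⁻⁴ is the smoothing
   tolerance and σ̂ a robust noise estimate from fourth differences
   (median(|Δ⁴y|)/(0.6745·√70); fourth differences annihilate cubics, so
   smooth spectral structure leaks little).  On noiseless input the budget
   reduces to ε and the spline nearly interpolates; on noisy input roughly
   half the noise energy is absorbed.  The penalized form matters: a
   knot-minimal spline with the same budget concentrates its error on the
   weakest features and erases the ~1%-deep sidebands of low-B1 spectra.
2. **Maxima.**  The spline is evaluated on a 10⁻³-ppm grid; strict interior
   grid maxima (plateaus contribute their leftmost point) are polished to
   the nearest sign change of the spline derivative.  Boundary points are
   never maxima.
3. **Case enumeration.**  For ordered maxima M₁..M_m, Case 1 pairs (M_i,
   M_{i+1}) with d = 1; Case 2 pairs (M_i, M_{i+2}) with d = 1.5 (the
   on-resonance lobe reflected in magnitude); Case 3 pairs (M_i, M_{i+4})
   with d = 2 — at most 3m − 7 hypotheses.  Each pair gives x, δω =
   midpoint, and B1 by the inversion above; hypotheses outside δω ∈
   [−0.6, 0.6] ppm or B1 ∈ (0, 1.5×nominal], or with impossible distances,
   are dropped.
4. **Multi-scale pooling.**  Steps 1–3 run at three smoothing scales (the
   default budget, ×10⁻², and ×10⁻⁴ floored near interpolation) and the
   hypotheses are pooled.  The coarse scale suppresses noise; the fine
   scales recover structure the default tolerance cannot — weak-B1
   sidebands below ε, and near-threshold distances where a small
   measurement error would otherwise drop the only correct hypothesis.
   Since every hypothesis is scored against the raw data, pooling adds
   candidates without biasing the choice.
5. **Selection.**  Each hypothesis is rendered as a magnitude template with
   c = 1 and scored by ‖y′ − Z′‖₁, the L1 distance of first derivatives
   (central differences; one-sided at the endpoints; index spacing — on a
   uniform grid this equals the physical derivative up to a global factor
   that cannot change the ranking).  The derivative cancels any constant
   baseline, removing c from the search.  Ties break deterministically by
   lower case id, then |δω|, then anchor index.
6. **Refinement.**  B1 alone is re-optimized over the interval
   [B1(x + l₁·δΔω), B1(x − l₂·δΔω)] (l₁ = 1.5, l₂ = 2.5, δΔω the offset
   step), evaluated on the *candidate's* branch — re-deciding the branch
   from the perturbed distance collapses the interval exactly near the
   threshold where refinement matters most.  Because the objective gains or
   loses whole Rabi periods across the interval it is multimodal, so a
   64-point scan brackets the minimum before a bounded polish to 10⁻⁴ μT.
   The refined score is never accepted if worse.
7. **Volume driver.**  Spectra are normalized by the M0 reference image
   (voxels with non-positive M0 are invalidated), fitted independently
   voxel by voxel (visit order cannot affect results), and assembled into
   δω / B1 / relative-B1 maps with a validity mask and failure-reason
   counts.  The default mask keeps voxels whose M0 exceeds 5% of its 99.5th
   percentile.

Failures are encoded, not raised: too-few-maxima, no-candidate-in-bounds,
non-finite-input, non-positive-m0; invalid voxels carry NaN.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| ε | 3·10⁻⁴ | — | spline residual budget (summed squared residual) |
| B1 range | (0, 1.5×nominal] | μT | admissible-power filter for hypotheses |
| δω range | [−0.6, 0.6] | ppm | admissible-shift filter |
| l₁, l₂ | 1.5, 2.5 | offset steps | refinement interval half-widths in distance |
| grid resolution | 10⁻³ | ppm | maxima search grid |

Defaults correspond to a 7 T protocol: 49 offsets over ±1.5 ppm, t_p = 5 ms,
nominal B1 = 3.7 μT.

## Baselines

The least-squares baseline reproduces the classic pipeline: a template
dictionary (default 20 δω × 20 B1 × 4 d × 3 c ≈ 4 800 curves over the
admissible box) supplies the starting point with the smallest sum-of-squares
distance; damped nonlinear least squares (scipy's trust-region reflective)
then fits {c, d, δω, B1} of the magnitude model inside box bounds.  The
WASSR reference fitter minimizes a reverse-Lorentzian dip model
z = p₃ − p₁/((Δω − δω)² + p₂), initialized at the spectrum minimum; only the
center δω is consumed downstream, which is invariant to the sign
parameterization of the dip.

## Synthetic phantom

The generator emulates a shimmed head at 7 T: smooth seeded Gaussian random
fields scaled to δω ∈ ±0.5 ppm and relative B1 ∈ 0.4–1.2 on an ellipsoidal
support, with the relative-B1 field pulled toward its low end in the extreme
slices (the way 3-D readouts degrade superior/inferior slices); a smooth M0
intensity field; voxelwise signed-model spectra (c = d = 1) scaled by M0
with additive Gaussian noise (σ = 0.02 of the normalized signal) and
magnitude detection; and two small spherical patches whose spectra receive a
one-sided amplitude asymmetry (magnitude 0.25) as a motion/imaging-artifact
surrogate.  Corruption operators for single spectra: one-sided asymmetry
taper, single-offset spike, and a subtract-and-reflect lobe reproducing
depolarized magnitude troughs.  All generators are pure functions of
(specification, seed).

What the phantom does *not* emulate: anatomy and tissue contrast, Rician
noise statistics (Gaussian noise on a signal of order 0.3–1 is a close
approximation; magnitude detection is applied), k-space/readout artifacts,
relaxation beyond the c, d surrogates, and motion beyond the surrogate
patches.  Passing phantom tests therefore demonstrates correctness of the
estimator under the stated model, not in-vivo performance.

Default phantom size is 24×24×6 voxels (~1 300 masked voxels), chosen so
whole-volume comparisons of both fitters complete in minutes on one CPU;
the per-voxel fitter itself runs at ~10 ms/voxel.

## Map comparison and CEST correction

Voxels whose δω deviates from a reference map by more than 0.15 ppm (about
two offset steps of the standard protocol), or that are invalid in either
map, count as ill-estimated; the percentage is reported over the mask.
Bland–Altman agreement reports bias = mean(a−b) and limits of agreement
bias ± 1.96·SD.  CEST B0 correction resamples each voxel's spectrum at
(offsets + δω) by linear interpolation, flagging samples outside the
acquired range; two-point B1 correction interpolates contrast linearly in
the actual local B1 (relative B1 × nominal level) between two acquisitions
and evaluates at the target nominal level.

## Numerical notes and limitations

* δω and offsets are kept in ppm throughout; Hz conversion happens exactly
  once, inside the forward model (and at reporting time where Hz are
  wanted).
* The σ = 0.02 noise level of the default phantom is twice the sideband
  depth of a 0.5 μT spectrum; no estimator recovers such voxels, and they
  dominate the error tail of the noise Monte-Carlo.  In-range powers
  (≥1.5 μT) are robust.
* The peak-distance inversion is undefined above 2/(γ̄t_p) and degenerate
  above √3/(γ̄t_p) (see Signal model); both regimes are excluded by the
  admissible-B1 bound and reported as errors by the low-level functions.
* Derivative scores use index spacing; on strongly non-uniform offset grids
  the score is rescaled relative to the physical-spacing derivative, which
  can in principle change rankings.  The standard protocols use uniform
  grids.
* NIfTI affines are passed through untouched; all computation is in voxel
  space.  No re-gridding of reference maps is provided.
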