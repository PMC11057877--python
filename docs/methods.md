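# Methods

## The visual model

The package models colour discrimination in a tetrachromatic reef fish
with one UV-sensitive single cone (U) and three double-cone members
(M1, M2, L). Photoreceptor spectral sensitivities are Govardovskii
(2000) A1 or A2 rhodopsin templates — the α band
S(x) = 1/(exp[A(a−x)] + exp[B(b−x)] + exp[C(c−x)] + D), x = λmax/λ, plus
the Gaussian β band — multiplied by ocular lens transmission and
renormalised to peak 1. The templates are valid for λmax in 330–600 nm;
A2 curves are broader than A1 at the same λmax, which is what the
automatic chromophore choice exploits (lower full-curve residual sum of
squares wins).

Receptor quantum catches are computed against the adapting background
(the display screen) with von Kries normalisation:

    q_i = ∫ S(λ) R_i(λ) dλ / ∫ S_b(λ) R_i(λ) dλ,     f_i = ln q_i

so the background itself always maps to q = 1 in every channel.
Integration is trapezoidal on a 300–700 nm grid at 1 nm; 1 nm resolves
every LED and template feature, and the trapezoid rule agrees with fine
quadrature (0.01 nm) to better than 0.1% on the smooth spectra involved.
Spectra are linearly interpolated onto the grid; out-of-range
extrapolation is an error unless zero-fill is requested, because silent
extrapolation hides calibration mistakes.

Discriminability follows the log-form receptor-noise-limited model.
Per-channel noise is e_i = σ_i/√η_i, with σ the single-cell Weber
fraction numerator and η the relative cone abundance (1:2:1:1 for
U:M1:M2:L, from the one-single-four-double retinal mosaic). The
chromatic distance between two stimuli is implemented as the
noise-weighted norm of the component of Δf orthogonal to the achromatic
(uniform) direction:

    ΔS² = Σ w_i Δf_i² − (Σ w_i Δf_i)² / Σ w_i,   w_i = 1/e_i²

which is algebraically identical to the published Vorobyev–Osorio closed
forms for 2, 3 and 4 receptors (the test suite verifies all three to
1e-10 or better). Pure intensity shifts give ΔS = 0 by construction.

## Colour space geometry

For a tetrachromat the chromatic signals span a 3-D subspace. Working in
whitened coordinates u_i = f_i/e_i, ΔS is the Euclidean distance after
projecting out the achromatic direction v_i = 1/e_i. `noise_corrected_xyz`
builds an orthonormal basis of that subspace, so the embedding is an
exact isometry (pairwise Euclidean distance = ΔS, tolerance 1e-9 in the
tests). The basis orientation is a convention fixed so the three
opponent contrasts have positive projections: L−(M1+M2) on +x,
M1−(M2+L) on +y, U−(M1+M2+L) on +z. Any rotation of the chromatic
subspace would preserve distances; pinning the rotation makes hue angles
reproducible.

Hue angles are spherical coordinates of a chromatic vector: elevation
Θ ∈ [−90°, 90°] (signed angle to the xy plane, positive for net UV-cone
excitation, computed from the dot product with the vector's planar
projection) and azimuth φ ∈ [0°, 360°) measured from +x through +y,
with negatives corrected by +360°. At the poles (x = y = 0) the azimuth
is undefined and reported as NaN. Colour sets whose azimuths differ by
180° ± 15° are flagged as candidate complementary pairs; the 15° default
covers the pairs reported in practice (10° from exact polarity) while
excluding unrelated sets, since no numeric cutoff is established in the
literature. A stimulus is classified non-spectral when some intermediate
receptor (in λmax order) is excited strictly less than receptors on both
sides — such colours cannot be matched by any monochromatic light.

## Pigment and lens fitting

λmax estimation follows standard microspectrophotometry practice:
normalise the scan to peak 1 (an optional 5 nm boxcar smooth is off by
default — smoothing is never applied silently); keep wavelengths beyond
the argmax; regress normalised absorbance on wavelength over the points
in [0.3, 0.7]; read λ50 where the regression line crosses 0.5; and invert
the template's long-limb half-maximum numerically (bisection to 0.01 nm)
to get λmax. The long limb is used because it is steep and monotone, so
the 50% crossing is the most noise-robust landmark. Errors are raised
for fewer than 3 band points, a non-descending limb, or an
un-bracketable λ50.

Scans are grouped by single-linkage chaining of λmax values with gaps
≤ 10 nm; bin means are renormalised and refitted. Single linkage is the
minimal reading of a pairwise "within 10 nm" rule; a chain
{500, 509, 518} therefore merges even though its extremes differ by
18 nm. Rod scans are processed identically but excluded from the
colour-vision receptor set.

Lens T50 is the longest-wavelength upward crossing of 0.5 on a
transmission curve normalised at 700 nm, linearly interpolated between
bracketing samples; multiple crossings indicate a noisy curve and only
the longest-wavelength one is used.

## Stimulus design

The display model is five radiance channels plus an always-present
screen background; mixtures are linear in the channel weights, so
quantum catches are affine in weights — the weight solvers exploit this
with a precomputed catch matrix instead of re-integrating spectra.

Colour lines place n targets on a ray from the achromatic point at
equally spaced ΔS levels up to a per-line maximum, by bounded least
squares on the five weights (residual tolerance 0.02 ΔS, warm-started
level to level with deterministic fallback starts). Because three
chromatic constraints leave two degrees of freedom, a soft preference
pins target intensity near the middle of the grey range; near the gamut
boundary the preference is dropped rather than sacrificing chromatic
accuracy.

Grey distractors must satisfy a genuinely tight packing: 13 points
within 1 ΔS of grey with all 78 pairwise distances in [0.3, 0.8] ΔS
(maximum possible diameter 0.8). Rejection sampling alone reliably
stalls at 11–12 points, so the sampler proposes a seeded random rotation
of a jittered icosahedral shell (circumradius ≈ 0.34 ΔS, edge ≈ 0.36)
plus a near-centre point — a configuration that satisfies the
constraints by construction — solves each locus to weights, and
re-verifies every constraint through the full model. Greys span a
brightness range (mean log catch 0.9–3.3) so that for any target a 6–10
grey subset exists whose per-receptor catches strictly bracket the
target's — the anti-achromatic-cue control. Subset search is exhaustive
over sizes 6–10 with ties broken toward greys closest to the target in
ΔS.

## Psychometric fitting and model comparison

Choice data are Bernoulli trials; the fit maximises the binomial
likelihood of P(correct|ΔS) = γ + (1−γ−λ)·F((ΔS−m)/s) with logistic F by
default (cumulative normal available). The sigmoid family is a
convention: with a guess rate of zero — justified because fish never
pecked the zero-contrast control, and 1-in-38 spatial guessing is
negligible — the threshold at P = 0.5 is insensitive to the choice.
Lapse is fixed at 0 by default; a free-lapse mode is capped at 0.5 to
keep the 0.5 crossing identifiable. Optimisation uses L-BFGS-B with the
analytic gradient and five deterministic quantile starts; fits flagged
`boundary` (all-correct, all-incorrect, or peak performance below 0.5)
report no threshold rather than an extrapolated one. The threshold
solves P(ΔS) = 0.5 by bracketed bisection to 1e-6. Confidence intervals
are percentile bootstrap (500 seeded resamples of per-level binomial
counts).

Model comparison rescales the world, not the data: for each candidate
visual model (full tetrachromat or drop-one trichromat; σ_single and
σ_double scanned independently over 0.05–0.15 in 0.01 steps, 121 cells
per variant) every target's ΔS is recomputed from stored quantum
catches, every psychometric curve is refitted on the rescaled axis
(warm-started from the neighbouring grid cell), and the model is scored
by the mean absolute deviation of per-set mean thresholds from 1 ΔS —
the value the RNL model predicts if its noise parameters are right.
Deviation uses the absolute value since a signed mean could cancel
opposite errors and make "smallest" meaningless. Dropped-receptor
variants keep the remaining cone ratios unchanged so each surviving
class retains its noise level. Variants that collapse a colour set's ΔS
axis (zero spread) are flagged and skipped, not fatal.

## The synthetic study

The generator reproduces the study conditions with known ground truth:

- **Display**: Gaussian LED channels (FWHM 20 nm) at 367/395/466/526/629
  nm over a flat background. True LED line shapes and screen radiance
  were never published; Gaussians keep catches smooth and the gamut
  realistic. Peak radiance 400× the background level makes all nine
  colour lines feasible to their design depth.
- **Visual system**: A1 templates at 386/497/515/535 nm behind a
  logistic lens (T50 334 nm, slope 0.1 nm⁻¹), σ = 0.11 (single) / 0.14
  (double), ratio 1:2:1:1, giving e = (0.110, 0.099, 0.140, 0.140).
- **Colour lines**: nine sets with the measured threshold elevations and
  the two measured complementary azimuth pairs (UV 127°/green 297°,
  purple 128°/violet-green 298°). The remaining azimuths are design
  choices spread across the double-cone plane — UV-blue sits at
  (10°, 105°), near the M1-opponent bearing where tri- and tetrachromat
  predictions differ most; that bearing is gamut-shallow, so the UV-blue
  line is capped at 1.2 ΔS. Violet-green uses elevation 65° (its printed
  azimuth kept) because the printed 53° is not reachable at depth in
  this synthetic gamut. Line target counts (6–11) match the behavioural
  sets.
- **Behaviour**: per-set planted thresholds equal the nine reported set
  means (0.4–1.6 ΔS) with steeper spreads for the sets reported as
  steep; 5 fish per set, 10 trials per level, γ = λ = 0, plus
  zero-contrast control trials. Model-recovery experiments instead plant
  every threshold at 1 ΔS so the generating σ pair is the metric's
  optimum.

Every generator is a pure function of (config, seed). What the synthetic
data do **not** emulate: spatial search over the 38-pixel board,
learning and motivation dynamics, fish-to-fish threshold differences
beyond binomial sampling, latencies, and the spiky fluorescent component
of real aquarium lighting. Passing tests therefore demonstrate that the
analysis recovers what the model family plants at realistic sample
sizes — not that real fish behave this way.

## Numerical choices and limitations

- Problem sizes: recovery checks use 100 replicate scans per cone class,
  200 simulated psychometric experiments, and a full 605-cell model
  scan; these sizes give stable medians while keeping a complete run in
  minutes on one core.
- The icosahedral grey proposal supports n ≤ 13; larger sets fall back
  to greedy rejection sampling, which may legitimately fail — the
  constraints can be jointly infeasible.
- The weight solvers are local least squares with deterministic
  multi-starts; a direction reported unreachable is unreachable up to
  those starts.
- Hue angles degrade numerically only at the poles, where azimuth is
  undefined by geometry, not by implementation.
- `bin_scans` refits bin means with the chromophore of the first member
  rather than re-running auto selection; mixed-chromophore bins are not
  expected in practice.
- The model scan assumes the stimulus catches stored at design time
  remain valid under every variant — true here because variants differ
  only in receptor complement and noise, not in sensitivities.
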