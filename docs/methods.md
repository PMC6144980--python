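# Methods

## The shared model pipeline

All implemented models assume (a) color vision is chromatic only — the
achromatic/brightness channel is out of scope; (b) all photoreceptor
outputs are opposed against each other with equal weight, the exact
opponent wiring being unknown for most species; and (c) receptors adapt
to the background (von Kries), so the background maps to relative catch
`q = 1` in every receptor and to the origin of the chromaticity diagram.

Quantum catches are trapezoidal integrals of reflectance × illuminant ×
sensitivity on the working grid. Trapezoidal quadrature is exact for the
piecewise-linear representation produced by the resampler, so resampling
then integrating introduces no additional quadrature error. Sensitivity
curves need no normalization: because ΔS depends only on `q = Q/Q_B`,
rescaling any receptor's sensitivity (or the illuminant) cancels — this
invariance is asserted by a test.

## Chromaticity-space construction

For `i` receptors the diagram has `n = i − 1` dimensions and `i`
equal-length vectors at pairwise angle `arccos(−1/n)` summing to zero.
The basis matrix is built from a generator vector `v` computed back to
front (`v[n] = −1/n`; earlier components absorb the remaining unit
length), with row `k` of **V** being `(v_k × k, −k·v_k, 0, …)`. The
construction is deterministic, so loci are reproducible run to run; its
orientation is one of infinitely many valid rotations and differs from
published hexagon figures by a rigid rotation only, which leaves every
distance unchanged (also asserted by a test). Three invariants are
verified on every construction, at 1e−10: equal column lengths, pairwise
dot products `−length²/n`, zero column sum. The generator vector itself
is checked at 1e−12. These tolerances reflect pure double-precision
linear algebra.

Two scalings are exposed. `vector_length` fixes each receptor vector's
length (1 for the hexagon model, 0.75 for Endler–Mielke — the EM
convention is applied at every dimensionality, since only a global scale
factor is at stake). `vertex_distance` fixes the distance between
diagram vertices; for unit columns that distance is `sqrt(2i/(i−1))`.
With the edge held at `sqrt(2)` the center-to-vertex distance is
`sqrt((i−1)/i)`: 0.816 for a trichromat, 0.866 for a tetrachromat. Note
this fixed-edge trade-off is often quoted against an "edge of 2"; the
quoted distances correspond to a *squared* edge of 2, i.e. edge
`sqrt(2)`, which is the reading implemented and tested here. The edge
length itself is a free parameter, so either convention is available.

## Receptor-noise-limited distances

The closed forms for 2–4 receptors follow the classical formulation:
opponent differences `Δf` weighted by channel Weber fractions, e.g. the
trichromat

    ΔS² = (e₁²(Δf₃−Δf₂)² + e₂²(Δf₃−Δf₁)² + e₃²(Δf₂−Δf₁)²)
          / ((e₁e₂)² + (e₁e₃)² + (e₂e₃)²)

The generic route maps a locus into noise units, `s = (V R Vᵀ)^(−1/2) x`
with `R = diag(e_i²)`: `V R Vᵀ` is the receptor-noise covariance
expressed in diagram coordinates, and whitening by its inverse symmetric
square root (computed by eigendecomposition; the matrix is symmetric
positive definite for any positive noise) yields coordinates whose
Euclidean norm equals the closed-form ΔS. The square root — rather than
the inverse covariance itself — is what makes `|s|` a distance rather
than a squared distance. Agreement between the two routes is the
module's core test: 200 randomized inputs per receptor count at 1e−9.
Because `V` appears on both sides, the basis scale cancels; the
transform is valid for any `i ≥ 2`, which is how pentachromatic and
higher systems are supported.

The linear-RNL transform is the identity on `q`; the model is calibrated
for similar colors near the adaptation point, and no similarity check is
enforced — exercising it far out of range is itself informative and is
done deliberately in the harnesses. Channel noise may optionally be
derived from relative receptor abundances as `e_i = ν/√η_i`, following
the standard pooling argument from the receptor-noise literature;
nothing uses this by default.

## Spurious regimes are data, not errors

Models that log-transform and sum-normalize outputs blow up when the
stimulus catch drops below the background catch: `ln q < 0`, output sums
cross zero, and relative outputs diverge. The package deliberately
propagates these values — they are the phenomenon under study — and
flags them: `run_model` records warnings ("negative log-transformed
outputs", near-singular output sums below |ΣE| < 1e−8) on the result
object so pipelines can count spurious cases. An output sum of exactly
zero raises, with one exception: a stimulus identical to the background
produces an all-equal output vector (all zero under `ln`), which is
mapped to the simplex center (locus at the origin, ΔS = 0) by
continuity rather than raising — every model must send the background to
the origin. A relative catch of exactly zero under `ln` is an error
naming the receptor, not `−inf`, because downstream geometry cannot
consume non-finite values.

## Synthetic inputs and what they do (not) show

The generators emulate the standard study designs: logistic (step-like)
reflectances spanning 10–60% with midpoints swept 300–700 nm at 5-nm
steps (81 spectra; the logistic slope defaults to 0.05 nm⁻¹, giving
transitions ~100 nm wide, and is configurable), a 10-percentage-point
downward shift to force stimulus catches below a flat 7% background,
flat achromatic stimuli 5–95% in 10-point steps, and Gaussian band
reflectances. The packaged illuminant is the CIE D65 table at 10-nm
resolution interpolated linearly to the working grid; a constant-flux
`flat` illuminant supports controlled experiments. The chromatic
background is a synthetic leaf-like curve (low UV, green peak at
550 nm, red-edge rise toward 700 nm) standing in for measured
vegetation averages; any measured background CSV can replace it.

The packaged honeybee-like receptor set uses the A1 visual-pigment
nomogram (Govardovskii-type alpha band plus UV beta band) at λmax 344,
436 and 544 nm with channel noise 0.13/0.06/0.12 — a synthetic stand-in
for measured *Apis mellifera* curves. Behaviour *classes* reproduce with
these templates (bell-shaped ΔS curves; the shifted sweep's spurious EM
maximum at mid-spectrum midpoints and log-RNL maximum at 700 nm;
constant log-RNL ΔS across achromatic levels), but exact magnitudes —
in particular the precise location and height of near-singular EM
spikes, which depend sensitively on where the output sum crosses zero —
require the measured curves, loadable via `read_spectrum_table`.
Passing tests on synthetic inputs therefore validate the machinery and
the qualitative model behaviours, not species-specific quantitative
predictions.

The synthetic flower library (baseline + one or two Gaussian bands +
occasional long-pass shoulder) mimics the shape vocabulary of flower
reflectance databases and is seed-deterministic; it does not reproduce
any database's actual distribution, so screening outcomes on it
illustrate the harness rather than settle which receptor sets are
optimal for real flora.

## Simulation harnesses

Sweeps run `run_model` per stimulus and tabulate outputs, loci, ΔS and
warning flags; the screening harness enumerates all peak combinations
of each requested size (the 11-peak, sizes 2–5 default gives 1012
combinations), scores mean ΔS over the stimulus library with Gaussian
sensitivities (default sd 50 nm), and ranks with the maximum-mean-ΔS
rule, breaking ties lexicographically by peak wavelengths so rankings
are deterministic. The screening path is vectorized; its agreement with
stimulus-by-stimulus `run_model` calls is asserted by a test. Stimulus
subsampling uses a caller-supplied seed. Model concordance uses Spearman
rank correlation (average ranks for ties, two-sided p) on paired ΔS
series. Default problem sizes (81-spectrum sweeps, 50-flower libraries,
1012-combination screens on the 1-nm grid) run in under a second each.

## Known limitations

No achromatic channel, no ocular-media or oil-droplet filtering, no
shot-noise/dim-light corrections, no behavioural discrimination
psychometrics: ΔS = 1 in RNL units approximates threshold only under
the model's calibrating conditions, and the ΔS-to-behaviour mapping is
species- and context-dependent. Plotting covers 2-D (trichromat) spaces
only. CSV is the only spectral input format; no smoothing or instrument
corrections are applied beyond optional negative-value clamping.
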