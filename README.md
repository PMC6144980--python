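# nchroma

Color vision models for ecology and evolution, generalized to any number
of photoreceptor types.

Animals see color by comparing the outputs of their photoreceptor
classes against each other (opponency). Color vision models turn a
measured reflectance spectrum into a point in the animal's chromaticity
diagram and a chromatic distance ΔS to the adapting background — the
standard currency for asking whether a flower, a fruit or a rival is
conspicuous to a bee, a bird or a spider. `nchroma` implements the
widely used models — the color hexagon (CH), the Endler–Mielke color
triangle/tetrahedron (EM), and the linear and log receptor-noise-limited
(RNL) models — as configurations of one generic pipeline that works for
di-, tri-, tetra-, penta- or any higher-chromatic visual system, and
makes it easy to define new model variants.

## The model

For an eye with *i* receptor classes, each stimulus is processed as:

1. **Quantum catch** — `Q_i = ∫ R(λ) I(λ) S_i(λ) dλ`, the photon capture
   of receptor class *i* viewing reflectance *R* under illuminant *I*
   with sensitivity *S_i*.
2. **von Kries adaptation** — `q_i = Q_i / Q_Bi`, catches relative to
   the background the eye is adapted to; the background itself maps to
   `q = 1` in every receptor.
3. **Transform** — a receptor input–output function `E_i = f(q_i)`:
   identity (linear RNL), `ln q` (EM, log RNL; the Fechner–Weber law) or
   the saturating hyperbolic `q/(q+1)` (CH). EM additionally normalizes
   outputs to sum to 1.
4. **Projection** — the chromaticity diagram has `n = i − 1` dimensions
   and one vector per receptor, all of equal length, at pairwise angle
   `θ = arccos(−1/n)`, summing to zero. Stacked as columns of the matrix
   **V**, the color locus is `x = V·p` and the chromatic distance between
   two stimuli is the Euclidean distance between their loci
   (`ΔS = |x_a − x_b|`); the background sits at the origin.
5. **Receptor noise (RNL)** — with per-receptor Weber fractions `e_i`,
   distances are measured in noise units via the whitening transform
   `s = (V R Vᵀ)^(−1/2) x` with `R = diag(e_i²)`, so `|s|` equals the
   classical closed-form RNL ΔS (≈ just-noticeable differences) while
   remaining plottable — and defined for any *i*, not just 2–4.

The diagram can be scaled by receptor-vector length (1 for CH, 0.75 for
EM) or by vertex-to-vertex distance, the trade-off that matters when
comparing ΔS across dimensionalities.

## Worked example

```python
import nchroma as nc

grid = nc.default_grid()                       # 300–700 nm, 1-nm steps
bee = nc.honeybee_like_receptors(grid)         # λmax 344/436/544, noise 0.13/0.06/0.12
illuminant = nc.builtin_illuminant("D65", grid)
background = nc.flat_reflectance(0.07, grid)
stimulus = nc.logistic_reflectance(500.0, lower=0.10, upper=0.60, grid=grid)

for name, cfg in {"CH": nc.ModelConfig.ch(), "EM": nc.ModelConfig.em(),
                  "linear RNL": nc.ModelConfig.rnl_linear((0.13, 0.06, 0.12)),
                  "log RNL": nc.ModelConfig.rnl_log((0.13, 0.06, 0.12))}.items():
    res = nc.run_model(stimulus, background, illuminant, bee, cfg)
    print(name, res.locus.round(4), round(res.delta_s_background, 4))
```

prints

```
CH [0.0714 0.2277] 0.2387
EM [0.0802 0.329 ] 0.3386
linear RNL [0.5296 4.31  ] 31.4901
log RNL [0.3076 1.2618] 9.0473
```

The four models place the step-like green stimulus in the same quadrant
of the trichromatic diagram; CH and EM report bounded diagram distances
(maximum 1 and 0.75 respectively) while the RNL models report distances
in units of receptor noise, where ΔS = 1 approximates a discrimination
threshold under the calibrating conditions.

The `examples/` scripts walk through the main capabilities: the basic
run above, the fixed-edge geometry trade-off across dimensionalities,
the spurious regimes of log-transforming and sum-normalizing models
(dim stimuli, chromatic backgrounds), and exhaustive screening of
photoreceptor peak combinations against a stimulus library. A thin CLI
wraps the same functions:

```
nchroma run --model em --stimuli flowers.csv --background flat:0.07 \
        --illuminant D65 --receptors bee --out results/
nchroma simulate screen --model rnl-log --noise 0.1 --peaks 330:630:30 \
        --sizes 2-5 --seed 1 --out screening/
```

Spectra are plain CSV: a `wavelength_nm` column followed by one column
per spectrum (`--value-scale percent` for 0–100 data). Every CLI run
writes a JSON manifest (resolved configuration, input digests, seed,
version) beside its results.

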