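"""Score one stimulus under all four models against a flat background.

A logistic (step-like) reflectance with its transition at 500 nm is
viewed by a honeybee-like trichromat under D65 daylight, adapted to a
flat 7% background. Each model reports the stimulus's chromatic distance
to the background (ΔS): unitless diagram distance for the hexagon and
Endler-Mielke models, units of receptor noise (≈ just-noticeable
differences) for the RNL models.
"""

import nchroma as nc

grid = nc.default_grid()
bee = nc.honeybee_like_receptors(grid)          # λmax 344, 436, 544 nm
illuminant = nc.builtin_illuminant("D65", grid)
background = nc.flat_reflectance(0.07, grid)
stimulus = nc.logistic_reflectance(500.0, lower=0.10, upper=0.60, grid=grid)

configs = {
    "color hexagon (CH)": nc.ModelConfig.ch(),
    "Endler-Mielke (EM)": nc.ModelConfig.em(),
    "linear RNL": nc.ModelConfig.rnl_linear((0.13, 0.06, 0.12)),
    "log RNL": nc.ModelConfig.rnl_log((0.13, 0.06, 0.12)),
}

print(f"stimulus: {stimulus.name}, background: flat 7%, illuminant: D65\n")
for name, cfg in configs.items():
    res = nc.run_model(stimulus, background, illuminant, bee, cfg)
    locus = ", ".join(f"{x:+.4f}" for x in res.locus)
    print(f"{name:20s} locus = ({locus})   ΔS = {res.delta_s_background:.4f}")

print(
    "\nΔS is the chromatic distance between stimulus and background; the"
    "\nmodels agree qualitatively here because stimulus catches exceed the"
    "\nbackground's in every receptor (the regime all models were built for)."
)
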