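"""Where models break: dim stimuli and chromatic backgrounds.

Two stress tests. First, a midpoint sweep of logistic stimuli shifted
10 percentage points below their generated reflectance, so quantum
catches fall below the 7%-flat background's: the Endler-Mielke model's
sum-normalized log outputs explode past the model's own 0.75 ceiling,
and the log-RNL ΔS becomes a sigmoid peaking at the longest midpoint.
Second, flat achromatic stimuli (5-95%) against a chromatic leaf-like
background: log-RNL ΔS is constant in stimulus intensity, linear-RNL
grows linearly, and the bounded hexagon model scores the darkest
stimulus as the most conspicuous.
"""

import nchroma as nc

grid = nc.default_grid()
bee = nc.honeybee_like_receptors(grid)
d65 = nc.builtin_illuminant("D65", grid)
flat7 = nc.flat_reflectance(0.07, grid)
leaf = nc.leaf_background(grid)
noise = (0.13, 0.06, 0.12)

print("-- shifted midpoint sweep (stimulus catches below background) --")
for name, cfg in [("EM", nc.ModelConfig.em()),
                  ("log RNL", nc.ModelConfig.rnl_log(noise))]:
    sweep = nc.midpoint_sweep(bee, d65, flat7, cfg, shift=-10.0)
    mp, ds = sweep.peak
    print(f"{name:8s} max ΔS = {ds:8.2f} at midpoint {mp:g} nm "
          f"({sweep.n_spurious}/81 stimuli flagged)")
print("EM's ceiling is 0.75 by construction: anything above it is spurious,\n"
      "driven by photoreceptor output sums crossing zero.\n")

print("-- achromatic stimuli vs chromatic background --")
for name, cfg in [("CH", nc.ModelConfig.ch()),
                  ("linear RNL", nc.ModelConfig.rnl_linear(noise)),
                  ("log RNL", nc.ModelConfig.rnl_log(noise))]:
    sweep = nc.achromatic_sweep(bee, d65, leaf, cfg)
    ds = sweep.table["delta_s"]
    print(f"{name:10s} ΔS at 5% = {ds.iloc[0]:7.3f}   at 95% = {ds.iloc[-1]:7.3f}")
print("A model whose ΔS falls as reflectance rises predicts a white target\n"
      "is harder to see against green foliage than a grey one.")
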