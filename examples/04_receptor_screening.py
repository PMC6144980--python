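"""Which photoreceptor peaks best discriminate a flower library?

Every combination of 2-5 peak wavelengths from an 11-step ladder
(330-630 nm, 30-nm spacing) is evaluated against 50 synthetic
flower-like spectra viewed on a leaf-like background under D65, using
the log-RNL model with 0.1 noise in every receptor. The selection rule
is the maximum mean ΔS; ties break lexicographically.
"""

import numpy as np

import nchroma as nc

grid = nc.default_grid()
flora = nc.synthetic_flora(50, grid, seed=1)
leaf = nc.leaf_background(grid)
d65 = nc.builtin_illuminant("D65", grid)
peaks = list(np.arange(330.0, 631.0, 30.0))

result = nc.screen_receptor_sets(
    flora, leaf, d65, peaks, set_sizes=[2, 3, 4, 5],
    config=nc.ModelConfig.rnl_log(0.1), seed=1,
)

print(f"{result.n_combinations} receptor-set combinations evaluated "
      f"against {result.n_stimuli} stimuli\n")
for k in (2, 3, 4, 5):
    best = result.best(k)
    row = result.table[result.table["peaks_nm"] == best].iloc[0]
    print(f"best {k}-receptor set: {', '.join(f'{p:g} nm' for p in best)}"
          f"   mean ΔS = {row['mean_delta_s']:.2f}")

print(
    "\nMean ΔS rises with receptor count, but with diminishing returns —"
    "\nthe gain from the 4th and 5th receptor is small on this library."
    "\n(Which peaks win depends on the stimulus set; rerun with your own"
    "\nspectra via read_spectrum_table.)"
)
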