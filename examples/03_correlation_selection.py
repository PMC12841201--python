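"""Stage 3: the Pearson selection rule on the published coefficient grid.

Each gene has four coefficients — protein abundance vs. percent statistic
in {brainstem, forebrain} x {100, 250 mg/kg choline}.  A gene is selected
when at least 3 of the 4 coefficients exceed 0.7.
"""

import cholscreen as cs

grid = cs.load_correlation_grid()
cfg = cs.ScreenConfig()  # r > 0.7 in >= 3 of 4 conditions
selected = cs.select_from_grid(grid, cfg)

print(grid.to_string())
print(f"\nselected with r > {cfg.r_threshold} in >= {cfg.min_conditions}"
      f" of {cfg.n_conditions} conditions: {selected}")
# Cept1 passes 4 of 4 and Slc44a1 passes 3 of 4 (0.521 in the forebrain
# at 100 mg/kg fails); Aldh7a1 passes none and is eliminated.
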