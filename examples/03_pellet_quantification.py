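"""Cell-pellet dilution series: image-derived gold mass vs ground truth.

Runs the printed pellet sizes (1e6 ... 0.125e6 cells at 128 pg gold each,
plus an empty tube) through acquisition, maximum-likelihood decomposition,
FBP and ROI quantification, then fits estimated against true gold mass.
"""

from spcct.experiments import run_pellet_series
from spcct.stats import linreg

table = run_pellet_series(seed=0)
print(table[["cells", "true_gold_ug", "est_gold_ug", "est_cells"]].round(1).to_string(index=False))

fit = linreg(table["true_gold_ug"].to_numpy(), table["est_gold_ug"].to_numpy())
print(f"linear fit: slope {fit.slope:.3f}, R2 {fit.r_squared:.4f}")
# R2 >= 0.99 reproduces the in-vitro linearity of K-edge quantification; a
# slope slightly below 1 reflects the mild underestimation of thresholded
# ROIs (edge voxels blurred below the 2-sigma cut are excluded).
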