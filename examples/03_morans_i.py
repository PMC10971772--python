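"""Spatial autocorrelation diagnostics on per-range impact values.

Global Moran's I asks whether nearby ranges carry similar impact values
overall; the local (Anselin) decomposition flags individual ranges that sit
in significant high-high / low-low clusters or are high-low / low-high
outliers relative to their neighbours.
"""

import numpy as np

from cyclemur import global_morans_i, inverse_distance_weights, local_morans_i
from cyclemur.moran import moran_frame

rng = np.random.default_rng(0)
# two spatial regimes: a high-impact north coast and a low-impact south
north = np.column_stack([rng.uniform(0, 500, 10), rng.uniform(800, 1000, 10)])
south = np.column_stack([rng.uniform(0, 500, 10), rng.uniform(0, 200, 10)])
centroids = np.vstack([north, south])
impact = np.r_[rng.normal(30, 3, 10), rng.normal(5, 3, 10)]

W = inverse_distance_weights(centroids, row_standardize=True)
g = global_morans_i(impact, W)
print(f"Global Moran's I = {g.I:.3f}  (E[I] = {g.expected:.3f}, z = {g.z:.2f}, p = {g.p:.2g})")
# I > 0 with small p: impact is spatially clustered, as cyclone exposure is

local = local_morans_i(impact, W, n_perm=999, seed=1)
frame = moran_frame([f"s{i:02d}" for i in range(20)], local)
print(frame.round(3).to_string(index=False))
# HH rows are the high-impact cluster; LL the low; ns = not significant
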