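"""Build a 2D bagplot from scratch and read off its parts.

Draws 100 points from a standard bivariate normal, computes the halfspace
depth grid, and prints the quantities that define the bagplot: the depth
median T (the deepest location), the level k* whose depth region first holds
at most half the observations, the interpolation weight lambda, and the
number of points inside the bag (the 2D analogue of the boxplot's box, which
should hold ~50% of the data).
"""

import numpy as np

import depthqc as dq

rng = np.random.default_rng(7)
cloud = dq.PointCloud.from_array(rng.standard_normal((100, 2)))

result = dq.bagplot(cloud, resolution=30)

in_bag = int(result.bag.hull.contains(cloud.coords, 1e-7).sum())
print(f"depth median T        : {np.round(result.median.location, 3)}")
print(f"maximal node depth    : {result.median.max_depth}")
print(f"k*                    : {result.k_star}")
print(f"#D_k*, #D_(k*-1)      : {result.count_inner}, {result.count_outer}")
print(f"lambda                : {result.lam:.3f}")
print(f"points inside the bag : {in_bag} of {cloud.n}")
print(f"outliers (outside the 3x fence): {sorted(result.outliers) or 'none'}")

# T approximates the distribution's center (0, 0); the bag holds ~50 points
# because lambda interpolates between the depth regions bracketing n/2; for
# clean Gaussian data the factor-3 fence flags at most an occasional point.
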