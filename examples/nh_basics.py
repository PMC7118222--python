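"""Network homogeneity on toy series: the statistic and its identities.

NH(i) is the mean Pearson correlation between voxel i's time series and
every other voxel inside the network mask.  Identical series give NH = 1,
an anti-correlated pair gives -1, and independent noise hovers near 0.
"""

import numpy as np

from nethom import compute_nh, compute_nh_brute
from nethom.preprocess import BOLDRun


def as_run(series):
    return BOLDRun(np.asarray(series, float)[:, None, None, :], 2.0,
                   "toy", "baseline", np.eye(4))


mask = lambda n: np.ones((n, 1, 1), bool)

shared = np.sin(np.arange(100) / 4.0)
print("identical series: NH =",
      np.round(compute_nh(as_run(np.tile(shared, (5, 1))), mask(5)).values, 4))

x = np.random.default_rng(0).standard_normal(100)
print("x and -x:         NH =",
      np.round(compute_nh(as_run([x, -x]), mask(2)).values, 4))

noise = np.random.default_rng(1).standard_normal((40, 230))
nh = compute_nh(as_run(noise), mask(40))
print(f"independent noise: mean NH = {nh.values.mean():+.4f} (should be ~0)")

fast = compute_nh(as_run(noise), mask(40)).values
brute = compute_nh_brute(as_run(noise), mask(40)).values
print(f"fast O(N*t) path vs pairwise oracle: max |diff| = "
      f"{np.abs(fast - brute).max():.2e}")
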