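"""Generate a synthetic two-class brain-volume cohort with a planted effect.

Builds the desk-scale strong-signal fixture — a 24^3 grid with an
ellipsoidal "brain" mask and one spherical cluster whose class-D mean is
shifted by 5x the white-noise sd — and shows that mass-univariate t
statistics peak exactly on the planted support.
"""

import numpy as np
from scipy import stats as sps

import pldacv as p

spec = p.strong_signal_spec(seed=3)
data, truth = p.generate_cohort(spec)

print(f"cohort: {data.n} subjects ({data.n_H} H / {data.n_D} D), "
      f"{data.p} in-mask voxel features")
print(f"planted support: {truth.support.size} voxels, effect size "
      f"{truth.effect[truth.support][0]:+.1f} (class D minus class H)")

t = sps.ttest_ind(data.X[data.mask_H], data.X[data.mask_D],
                  axis=0, equal_var=True).statistic
inside = np.abs(t[truth.support])
outside = np.abs(np.delete(t, truth.support))
print(f"|t| on planted voxels : min {inside.min():.1f}, max {inside.max():.1f}")
print(f"|t| elsewhere         : median {np.median(outside):.2f}, "
      f"max {outside.max():.1f}")
print("-> the planted cluster dominates every background voxel, so feature-"
      "selection methods have an unambiguous ground truth to recover.")
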