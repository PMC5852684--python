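"""Quantile-mapping bias correction of compressed predictions.

Analog methods under-predict dense forest; this fits the empirical
calibration curve on cross-validation pairs with an engineered compressive
bias and shows the per-class median residuals before and after.
"""

import numpy as np

from pollenmat import fit_curve
from pollenmat.biascorr import ResampleConfig

rng = np.random.default_rng(4)
observed = np.clip(100.0 * rng.beta(1.3, 2.2, 2000), 0.0, 100.0)
modeled = np.clip(0.6 * observed + rng.normal(0.0, 2.0, 2000), 0.0, 100.0)

curve = fit_curve(modeled, observed, ResampleConfig(iterations=199, seed=4))
print("observed class | median residual before | after correction")
for cls, row in curve.diagnostics.iterrows():
    print(f"   {cls:3d}-{cls + 10:<3d}    | {row['median_residual_pre']:12.1f}         "
          f"| {row['median_residual_post']:6.1f}")
print("the curve is monotone and pulls every class's median toward zero")
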