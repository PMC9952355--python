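"""Compare conventional model-based R2* fitters on noisy replicate voxels.

Simulates 500 Rician-noisy realizations of a single fast-decaying voxel
(R2* = 800 s^-1, S0 = 216.6, sigma_g = 17 -- severe iron overload at high
noise) and fits each with four pixel-wise methods.  The mean estimates show
the characteristic bias structure: the offset model overestimates, the
truncation model underestimates, plain least squares is badly biased by the
noise floor, and the first-moment noise-corrected model (M1NCM) comes
closest to the truth.
"""

import numpy as np

from r2cascade import MultiEchoSeries, default_te_schedule
from r2cascade.fitting import FitOptions, fit_map

R2_TRUE, S0, SIGMA, N = 800.0, 216.6, 17.0, 500
te = default_te_schedule()

rng = np.random.default_rng(0)
clean = S0 * np.exp(-te.te_s * R2_TRUE)
noisy = np.hypot(clean[None, :] + rng.normal(0, SIGMA, (N, 12)),
                 rng.normal(0, SIGMA, (N, 12)))
series = MultiEchoSeries(noisy[:, None, :], te)

print(f"truth: R2* = {R2_TRUE:.0f} s^-1, sigma_g = {SIGMA:.0f}")
for method in ("nlls", "offset", "truncation", "m1ncm"):
    res = fit_map(series, method, opts=FitOptions(sigma=SIGMA))
    est = res.maps.r2star[:, 0]
    print(f"{method:>10}: mean {est.mean():7.1f} s^-1  "
          f"(bias {est.mean() - R2_TRUE:+7.1f}, sd {est.std(ddof=1):6.1f})")
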