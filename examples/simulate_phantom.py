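"""Simulate one synthetic liver subject and inspect its noise properties.

Builds a 64x128 liver phantom with parenchymal R2* uniform over 45-956 s^-1,
synthesizes the 12-echo decay series, adds Rician noise at sigma_g = 9, and
checks the background-ROI noise estimate and the parenchyma SNR.
"""

import numpy as np

from r2cascade import (
    NoiseSpec,
    PhantomSpec,
    compute_snr,
    estimate_sigma_background,
    simulate_dataset,
)

ds = simulate_dataset(PhantomSpec(seed=42), noise=NoiseSpec(9.0, seed=43))

par = ds.masks["parenchyma"]
print(f"phantom {ds.truth.shape}, {par.sum()} parenchyma voxels")
print(f"parenchyma R2*: {ds.truth.r2star[par].min():.0f}"
      f"-{ds.truth.r2star[par].max():.0f} s^-1 "
      f"(mean {ds.truth.r2star[par].mean():.0f})")

sigma_est = estimate_sigma_background(ds.noisy, ds.masks["background"])
print(f"background-ROI sigma estimate: {sigma_est:.2f} (true 9.00)")
print(f"parenchyma SNR at first echo: "
      f"{compute_snr(ds.noisy, par, ds.noise.sigma_g):.1f}")
print(f"recorded clean-signal SNR: {ds.snr:.1f}")

# The first echo is the brightest; the clean series decays monotonically.
first, last = ds.clean.data[par, 0].mean(), ds.clean.data[par, -1].mean()
print(f"mean clean parenchyma signal: {first:.1f} (TE 0.93 ms) "
      f"-> {last:.1f} (TE 15.67 ms)")
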