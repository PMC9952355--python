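# r2cascade

R2\* relaxometry of iron-loaded liver from multi-echo magnitude MRI.

Hepatic iron concentration is assessed clinically through the effective
transverse relaxation rate R2\* = 1/T2\* of liver parenchyma, obtained by
pixel-wise fitting of a multi-gradient-echo series to the mono-exponential
decay S(TE) = S0·exp(−TE·R2\*).  Magnitude MRI noise is Rician, and its
nonzero floor biases naive fitting exactly where it matters most — severe
iron overload, where the signal decays into the noise within a few echoes.

This package implements the full desk-scale stack for studying that problem:

- **Signal model** — mono-exponential decay synthesis, Rician noise
  generation and exact moments, background-ROI noise estimation
  (0.80 × mean background magnitude), SNR bookkeeping.
- **Synthetic livers** — seeded 64×128 phantoms with parenchymal R2\*
  uniform over 45–956 s⁻¹, vessels, masks; patch extraction (32×32×12,
  stride 8), augmentation and corpus manifests.
- **Model-based fitting** — vectorized Levenberg–Marquardt implementations
  of log-linear, plain NLLS, offset, automatic truncation, and the first-
  and second-moment Rician noise-corrected models (M¹NCM / M²NCM).
- **Cascade networks** — a separable-convolution residual denoiser followed
  by a U-Net mapper (the CadamNet architecture family) trained with a
  model-consistency (physics) loss: images re-synthesized from the predicted
  maps must match the noise-free references.  Implemented on a compact
  numpy layer stack with exact manual gradients; fully deterministic
  training given a seed.
- **Evaluation** — NRMSE and global SSIM over liver masks, parenchyma mean
  R2\*, Bland–Altman agreement, Wilcoxon signed-rank comparisons, and
  benchmark harnesses across the clinical noise ladder σ_g = 7…17.

See `docs/methods.md` for the model details and the package's design
choices, and `examples/` for short narrative scripts, one per capability.

## Worked example

Fit 500 noisy replicates of one severely iron-loaded voxel
(R2\* = 800 s⁻¹, σ_g = 17, the 12-echo 0.93 + 1.34·k ms schedule):

```sh
$ python examples/fit_conventional.py
truth: R2* = 800 s^-1, sigma_g = 17
      nlls: mean   331.0 s^-1  (bias  -469.0, sd  288.3)
    offset: mean  1057.4 s^-1  (bias  +257.4, sd  566.1)
truncation: mean   681.7 s^-1  (bias  -118.3, sd  273.2)
     m1ncm: mean   888.1 s^-1  (bias   +88.1, sd  495.2)
```

The noise floor makes plain least squares collapse (−469 s⁻¹ mean bias),
the offset model overshoots, truncation undershoots, and the first-moment
noise-corrected model — which fits the exact Rician expectation of the
decaying signal — comes closest to the truth.

`examples/train_cascade.py` trains a small denoise→map cascade on simulated
subjects and compares its held-out NRMSE with the single-stage mapper and
pixel-wise least squares; `examples/simulate_phantom.py` and
`examples/agreement_statistics.py` demonstrate the simulator and the paired
statistics.

A thin CLI wraps the same library calls:

```sh
r2cascade simulate --sigma 15 --seed 1 --out ds/
r2cascade fit ds/noisy.nii.gz --method m1ncm --sigma auto \
          --mask ds/mask_liver.nii.gz --out est
r2cascade evaluate --reference ds/truth --estimate est \
          --mask ds/mask_liver.nii.gz
```

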