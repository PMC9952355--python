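"""End-to-end benchmark harnesses.

Two entry points:

- :func:`fitting_benchmark` — the conventional-methods grid: simulate
  subjects across the noise ladder (sigma_g 7..17), fit each model-based
  method pixel-wise, and tabulate mean (sd) NRMSE / SSIM over subjects.

- :func:`cascade_benchmark` — the scaled-down learning benchmark: train the
  cascade (denoiser + mapper), the single-stage mapper, and a mixed-noise
  cascade on simulated corpora, then compare their held-out NRMSE with
  pixel-wise least squares and the first-moment noise-corrected fit on the
  same noisy test subjects.

External R2* maps (e.g. from a spatially regularized fitter implemented
elsewhere) can be scored against the same subjects via
:func:`evaluate_external_maps`.
"""

from __future__ import annotations

import numpy as np

from .fitting import FitOptions, fit_map
from .metrics import nrmse, roi_mean_r2star, ssim_global
from .phantom import (
    MIXED_SIGMA_LEVELS,
    PhantomSpec,
    build_training_corpus,
    default_te_schedule,
    simulate_dataset,
)
from .signal_model import NoiseSpec

__all__ = ["fitting_benchmark", "cascade_benchmark", "evaluate_external_maps"]


def _test_subjects(n_test: int, sigma: float, seed: int, spec: PhantomSpec):
    """Held-out subjects; seeds disjoint from any training corpus seeds."""
    from dataclasses import replace

    ss = np.random.SeedSequence([seed, 0x7E57]).generate_state(2 * n_test)
    subjects = []
    for k in range(n_test):
        subjects.append(
            simulate_dataset(
                replace(spec, seed=int(ss[2 * k] % 2**31)),
                noise=NoiseSpec(sigma, seed=int(ss[2 * k + 1] % 2**31)),
                dataset_id=f"test{k:03d}",
            )
        )
    return subjects


def fitting_benchmark(
    sigmas=(7.0, 9.0, 11.0, 13.0, 15.0, 17.0),
    methods=("nlls", "m1ncm"),
    n_subjects: int = 4,
    seed: int = 0,
    spec: PhantomSpec = PhantomSpec(),
) -> dict:
    """Mean (sd) NRMSE/SSIM of model-based fits across the noise ladder.

    NRMSE and SSIM are computed over the whole liver (parenchyma + vessels)
    against the exact simulated truth, and reported in percent.
    """
    grid: dict = {"sigmas": list(sigmas), "methods": list(methods), "results": {}}
    for sigma in sigmas:
        subjects = _test_subjects(n_subjects, sigma, seed, spec)
        for method in methods:
            nr, ss_ = [], []
            for ds in subjects:
                res = fit_map(
                    ds.noisy, method, ds.masks["liver"], FitOptions(sigma=sigma)
                )
                nr.append(100 * nrmse(ds.truth.r2star, res.maps.r2star, ds.masks["liver"]))
                ss_.append(
                    100 * ssim_global(ds.truth.r2star, res.maps.r2star, ds.masks["liver"])
                )
            grid["results"].setdefault(method, {})[f"sigma={sigma:g}"] = {
                "nrmse_mean": float(np.mean(nr)),
                "nrmse_sd": float(np.std(nr, ddof=1)) if len(nr) > 1 else 0.0,
                "ssim_mean": float(np.mean(ss_)),
                "ssim_sd": float(np.std(ss_, ddof=1)) if len(ss_) > 1 else 0.0,
            }
    return grid


def evaluate_external_maps(r2star_maps, subjects) -> dict:
    """Score externally computed R2* maps against simulated subjects."""
    nr = [
        100 * nrmse(ds.truth.r2star, est, ds.masks["liver"])
        for est, ds in zip(r2star_maps, subjects)
    ]
    return {"nrmse_percent": nr, "nrmse_mean": float(np.mean(nr))}


def cascade_benchmark(
    seed: int = 0,
    sigma: float = 15.0,
    n_train: int = 40,
    n_test: int = 8,
    epochs: int = 8,
    stride: int = 24,
    batch_size: int = 32,
    augment_ops: tuple[str, ...] = ("flip_h", "flip_v"),
    spec: PhantomSpec = PhantomSpec(),
    include_mixed: bool = True,
    fit_methods=("nlls", "m1ncm"),
) -> dict:
    """Scaled-down cascade-vs-baselines comparison at one noise level.

    Trains on ``n_train`` simulated subjects and evaluates on ``n_test``
    held-out subjects at the given sigma.  Reduced network widths (4
    denoiser layers, mapper base width 16) and a handful of epochs keep the
    run desk-scale; the comparison is the qualitative ordering, not the
    full-scale error magnitudes.  Returns per-subject NRMSE (%) lists and
    their means for: ``cascade``, ``mapping_only``, ``cascade_mixed`` (if
    requested) and each model-based method.
    """
    from .nn import (
        CascadeModel,
        DenoiserConfig,
        MapperConfig,
        TrainConfig,
        predict_cascade,
        train_cascade,
    )

    te = default_te_schedule()
    cfg = TrainConfig(epochs=epochs, seed=seed, batch_size=batch_size)
    dcfg = DenoiserConfig(
        n_layers=4, spatial_kernels_per_channel=4, temporal_out_channels=24, seed=seed
    )
    mcfg = MapperConfig(base_width=16, depth=3, seed=seed)

    fixed_patches, _ = build_training_corpus(
        n_train, spec, noise_policy=sigma, seed=seed, stride=stride,
        augment_ops=list(augment_ops),
    )
    cascade, hist = train_cascade(fixed_patches, cfg, dcfg, mcfg, te)
    mapping_only, hist_m = train_cascade(
        fixed_patches, cfg, dcfg, mcfg, te, with_denoiser=False
    )
    del fixed_patches  # free before the mixed corpus is materialized
    models = {"cascade": cascade, "mapping_only": mapping_only}
    history = {"cascade": hist, "mapping_only": hist_m}
    if include_mixed:
        mixed_patches, _ = build_training_corpus(
            n_train, spec, noise_policy="mixed", seed=seed, stride=stride,
            augment_ops=list(augment_ops), sigma_levels=MIXED_SIGMA_LEVELS,
        )
        models["cascade_mixed"], history["cascade_mixed"] = train_cascade(
            mixed_patches, cfg, dcfg, mcfg, te
        )

    subjects = _test_subjects(n_test, sigma, seed, spec)
    out: dict = {
        "sigma": sigma, "seed": seed, "n_train": n_train, "n_test": n_test,
        "epochs": epochs, "nrmse_percent": {}, "roi_mean_r2star": {}, "history": history,
    }
    out["roi_mean_r2star"]["reference"] = [
        roi_mean_r2star(ds.truth, ds.masks["parenchyma"]) for ds in subjects
    ]
    for name, model in models.items():
        nr, roi = [], []
        for ds in subjects:
            maps = predict_cascade(model, ds.noisy)
            nr.append(100 * nrmse(ds.truth.r2star, maps.r2star, ds.masks["liver"]))
            roi.append(roi_mean_r2star(maps, ds.masks["parenchyma"]))
        out["nrmse_percent"][name] = nr
        out["roi_mean_r2star"][name] = roi
    for method in fit_methods:
        nr, roi = [], []
        for ds in subjects:
            res = fit_map(ds.noisy, method, ds.masks["liver"], FitOptions(sigma=sigma))
            nr.append(100 * nrmse(ds.truth.r2star, res.maps.r2star, ds.masks["liver"]))
            roi.append(
                roi_mean_r2star(res.maps, ds.masks["parenchyma"])
            )
        out["nrmse_percent"][method] = nr
        out["roi_mean_r2star"][method] = roi
    out["nrmse_mean"] = {
        k: float(np.mean(v)) for k, v in out["nrmse_percent"].items()
    }
    return out
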