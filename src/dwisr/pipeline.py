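"""End-to-end orchestration: degrade -> interpolate -> train/predict ->
renormalize -> evaluate -> GQI, for one subject or a cohort.

``run_experiment`` reproduces the study design at a configurable scale:
a cohort of phantom subjects is split 11:1 into training and test sets at
the subject level, the three per-shell models are trained, every checkpoint
is evaluated on the held-out subject(s) with PSNR/SSIM/cosine, the best
checkpoint is chosen by the normalized three-index product, and the
predicted volumes, metric JSON, intensity histograms and GQI index maps
(for both the interpolation baseline and the network prediction) are
written to the output directory.  Everything is derived from the run seed,
so two runs with the same config are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import gqi as gqi_mod
from . import metrics
from .io import DWIVolume, write_dwi
from .network import SRCNNSpec, save_checkpoint
from .phantom import default_phantom_spec, generate_phantom
from .resample import ResampleSpec, downsample, interpolate_up, normalize_range
from .training import (
    SuperResolution3D,
    SuperResolutionResults,
    TrainingSpec,
    select_best_checkpoint,
)

__all__ = ["RunConfig", "predict", "predict_grid", "downsample_volume", "run_experiment"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one full experiment run."""

    n_subjects: int = 12
    grid_shape: tuple = (24, 24, 12)
    noise_sigma_fraction: float = 0.02  # Rician scale as a fraction of s0
    train_test_ratio: float = 11.0
    resample: ResampleSpec = dataclasses.field(default_factory=ResampleSpec)
    srcnn: SRCNNSpec = dataclasses.field(default_factory=SRCNNSpec)
    training: TrainingSpec = dataclasses.field(default_factory=TrainingSpec)
    gqi: gqi_mod.GQISpec = dataclasses.field(default_factory=gqi_mod.GQISpec)
    output_dir: Optional[str] = None
    run_gqi: bool = True
    write_volumes: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, factory in (
            ("resample", ResampleSpec),
            ("srcnn", SRCNNSpec),
            ("training", TrainingSpec),
            ("gqi", gqi_mod.GQISpec),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = factory(**d[key])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "srcnn" in d and isinstance(d["srcnn"], SRCNNSpec):
            pass
        return cls(**d)


def predict_grid(results: SuperResolutionResults, low_res: np.ndarray,
                 bval: float, resample_spec: ResampleSpec,
                 renormalize_to: str = "interpolated") -> np.ndarray:
    """Super-resolve a single 3-D grid with the model of its shell.

    interpolate up -> restore the low-resolution original's intensity range
    -> network forward pass -> restore the interpolated source's range
    (``renormalize_to='low_res'`` uses the low-resolution original instead).
    """
    from .network import forward

    state = results.model_for_bval(bval)
    interp = interpolate_up(low_res, resample_spec.factor, resample_spec.method)
    if resample_spec.renormalize and low_res.max() > low_res.min():
        interp = normalize_range(interp, low_res)
    out = forward(state, interp)
    reference = low_res if renormalize_to == "low_res" else interp
    if resample_spec.renormalize and reference.max() > reference.min():
        out = normalize_range(out, reference)
    return out


def predict(results: SuperResolutionResults, lr_vol: DWIVolume,
            resample_spec: ResampleSpec = ResampleSpec(),
            renormalize_to: str = "interpolated") -> DWIVolume:
    """Super-resolve every gradient entry, routing each shell to its model."""
    f = resample_spec.factor
    out = np.empty(tuple(s * f for s in lr_vol.data.shape[:3]) + (lr_vol.n_gradients,))
    for g in range(lr_vol.n_gradients):
        out[..., g] = predict_grid(
            results, lr_vol.data[..., g], float(lr_vol.bvals[g]), resample_spec,
            renormalize_to=renormalize_to,
        )
    affine = lr_vol.affine.copy()
    affine[:3, :3] /= f
    return DWIVolume(
        data=out,
        voxel_size=tuple(v / f for v in lr_vol.voxel_size),
        bvals=lr_vol.bvals.copy(),
        bvecs=lr_vol.bvecs.copy(),
        affine=affine,
    )


def _interpolation_baseline(low: np.ndarray, spec: ResampleSpec) -> np.ndarray:
    interp = interpolate_up(low, spec.factor, spec.method)
    if spec.renormalize and low.max() > low.min():
        interp = normalize_range(interp, low)
    return interp


def _evaluate_volumes(pred: np.ndarray, target: np.ndarray):
    """Per-gradient metric reports (4-D arrays, gradient axis last)."""
    return [
        metrics.evaluate_pair(pred[..., g], target[..., g])
        for g in range(pred.shape[-1])
    ]


def downsample_volume(vol: DWIVolume, factor: int = 3) -> DWIVolume:
    """Degrade a whole 4-D volume: block-average each gradient entry and
    scale the voxel size/affine accordingly."""
    low = np.stack(
        [downsample(vol.data[..., g], factor) for g in range(vol.n_gradients)],
        axis=-1,
    )
    affine = vol.affine.copy()
    affine[:3, :3] *= factor
    return DWIVolume(
        data=low,
        voxel_size=tuple(v * factor for v in vol.voxel_size),
        bvals=vol.bvals.copy(),
        bvecs=vol.bvecs.copy(),
        affine=affine,
    )


def run_experiment(config: RunConfig) -> dict:
    """Run the full phantom study; returns the report bundle as a dict.

    Stages: cohort generation, subject-level 11:1 split, per-group training,
    per-checkpoint evaluation on the held-out subject(s), product-based
    checkpoint selection, final prediction + metrics + histograms, and GQI
    index maps for target / baseline / prediction.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- cohort ------------------------------------------------------------
    subjects = []
    for s in range(config.n_subjects):
        spec = default_phantom_spec(
            seed=config.seed * 100003 + s,
            grid_shape=config.grid_shape,
        )
        spec.noise_sigma = config.noise_sigma_fraction * spec.s0
        subjects.append(generate_phantom(spec))

    n_test = max(1, round(config.n_subjects / (config.train_test_ratio + 1.0)))
    order = rng.permutation(config.n_subjects)
    test_ids = sorted(int(i) for i in order[:n_test])
    train_ids = sorted(int(i) for i in order[n_test:])
    train_vols = [subjects[i] for i in train_ids]
    test_vols = [subjects[i] for i in test_ids]

    # --- training ----------------------------------------------------------
    model = SuperResolution3D(
        train_vols,
        resample_spec=config.resample,
        srcnn_spec=config.srcnn,
        training_spec=config.training,
    )
    results = model.fit()

    # --- per-checkpoint evaluation & selection ------------------------------
    factor = config.resample.factor
    test_low = [downsample_volume(v, factor) for v in test_vols]
    selection = {}
    for label, log in results.logs.items():
        members = dict(model.grouping)[label]
        summaries = []
        for it, state in log.checkpoints:
            tmp = SuperResolutionResults(model, {label: state}, {label: log})
            reports = []
            for low, hr in zip(test_low, test_vols):
                for g in range(hr.n_gradients):
                    if float(hr.bvals[g]) not in members:
                        continue
                    pred = predict_grid(
                        tmp, low.data[..., g], float(hr.bvals[g]), config.resample
                    )
                    reports.append(metrics.evaluate_pair(pred, hr.data[..., g]))
            summaries.append(metrics.summarize_reports(reports))
        best_it = select_best_checkpoint(log, summaries)
        selection[label] = {
            "checkpoint_iterations": log.checkpoint_ids(),
            "product_scores": metrics.product_score(summaries),
            "selected_iteration": best_it,
        }
        # Swap the selected checkpoint in as the group's final model.
        for it, state in log.checkpoints:
            if it == best_it:
                results.models[label] = state
                break

    # --- final prediction & metrics -----------------------------------------
    report = {
        "config": {
            "n_subjects": config.n_subjects,
            "grid_shape": list(config.grid_shape),
            "noise_sigma_fraction": config.noise_sigma_fraction,
            "seed": config.seed,
            "train_subjects": train_ids,
            "test_subjects": test_ids,
        },
        "training": {
            label: {
                "iterations": len(log.iterations),
                # first/last epoch means of the per-subject aggregated loss —
                # the stable training curve, not a single-pair sample
                "initial_loss": log.epoch_losses()[0],
                "final_loss": log.epoch_losses()[-1],
                "epoch_losses": log.epoch_losses(),
                "subject_losses": [
                    [repr(s), e, l] for s, e, l in log.subject_losses
                ],
            }
            for label, log in results.logs.items()
        },
        "selection": selection,
    }

    baseline_reports, srcnn_reports = [], []
    histograms = []
    for t_idx, (low, hr) in enumerate(zip(test_low, test_vols)):
        pred_vol = predict(results, low, config.resample)
        baseline = np.stack(
            [
                _interpolation_baseline(low.data[..., g], config.resample)
                for g in range(low.n_gradients)
            ],
            axis=-1,
        )
        baseline_reports.extend(_evaluate_volumes(baseline, hr.data))
        srcnn_reports.extend(_evaluate_volumes(pred_vol.data, hr.data))

        hist_range = (0.0, float(hr.data.max()))
        histograms.append(
            {
                "subject": test_ids[t_idx],
                "range": list(hist_range),
                "bins": 64,
                "target": metrics.intensity_histogram(hr.data, 64, hist_range).tolist(),
                "interpolated": metrics.intensity_histogram(baseline, 64, hist_range).tolist(),
                "srcnn": metrics.intensity_histogram(pred_vol.data, 64, hist_range).tolist(),
            }
        )

        if out_dir and config.write_volumes:
            stem = out_dir / f"subject{test_ids[t_idx]:02d}"
            write_dwi(pred_vol, f"{stem}_srcnn.nii", f"{stem}.bval", f"{stem}.bvec")
            base_vol = dataclasses.replace(pred_vol, data=baseline)
            write_dwi(base_vol, f"{stem}_interp.nii", f"{stem}.bval", f"{stem}.bvec")

        if config.run_gqi:
            sphere = gqi_mod.tessellate_sphere(config.gqi.tessellation_level)
            gqi_block = {}
            for name, vol4d in (
                ("target", hr.data),
                ("interpolated", baseline),
                ("srcnn", pred_vol.data),
            ):
                dwi = DWIVolume(
                    data=vol4d,
                    voxel_size=hr.voxel_size,
                    bvals=hr.bvals,
                    bvecs=hr.bvecs,
                )
                sdf = gqi_mod.reconstruct_sdf(dwi, config.gqi, sphere)
                maps = gqi_mod.compute_index_maps(sdf)
                gqi_block[name] = {
                    "gfa_mean": float(maps.gfa.mean()),
                    "iso_mean": float(maps.iso.mean()),
                    "nqa_mean": float(maps.nqa.mean()),
                }
                if out_dir and config.write_volumes:
                    import nibabel as nib

                    for idx_name, arr in (
                        ("gfa", maps.gfa), ("qa", maps.qa),
                        ("nqa", maps.nqa), ("iso", maps.iso),
                    ):
                        img = nib.Nifti1Image(
                            arr.astype(np.float32), np.eye(4)
                        )
                        nib.save(img, str(out_dir / (
                            f"subject{test_ids[t_idx]:02d}_{name}_{idx_name}.nii"
                        )))
            report.setdefault("gqi", []).append(
                {"subject": test_ids[t_idx], **gqi_block}
            )

    report["metrics"] = {
        "interpolated": metrics.summarize_reports(baseline_reports),
        "srcnn": metrics.summarize_reports(srcnn_reports),
    }
    report["histograms"] = histograms

    if out_dir:
        for label, state in results.models.items():
            save_checkpoint(state, out_dir / f"model_{label}.npz")
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    report["_results"] = results
    return report
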