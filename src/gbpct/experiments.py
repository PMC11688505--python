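"""The two scripted studies: split-count comparison and denoiser comparison.

Both consume a :class:`~gbpct.config.RunConfig`, write every output under
one run directory together with a frozen copy of the config, and are fully
seeded: re-running from the frozen config reproduces all CSVs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import n2i
from .acquisition import AcquisitionGeometry, simulate_stepping
from .baselines import gaussian_blur
from .config import RunConfig
from .iqa import CannyParams, assess_stack
from .nps import band_power, nps_radial
from .phantom import PhantomVolume, make_phantom_stack
from .recon import Tomogram, reconstruct_attenuation, reconstruct_electron_density
from .retrieval import retrieve, retrieve_patchwise

log = logging.getLogger("gbpct")

__all__ = ["run_split_experiment", "run_comparison_experiment"]

SIGNALS = ("attenuation", "electron_density")


def _geometry(config: RunConfig, flux_multiplier: float = 1.0,
              seed: int | None = None) -> AcquisitionGeometry:
    return AcquisitionGeometry(
        n_angles=config.n_angles,
        n_steps=config.n_steps,
        visibility=config.visibility,
        flux_per_step=config.flux_per_step * flux_multiplier,
        phase_sensitivity=config.phase_sensitivity,
        seed=config.scan_seed if seed is None else seed,
    )


def _ground_truth(phantom: PhantomVolume, signal: str) -> np.ndarray:
    return phantom.mu if signal == "attenuation" else phantom.delta


def _reconstruct(sino, signal: str, config: RunConfig, subset=None) -> Tomogram:
    if signal == "attenuation":
        return reconstruct_attenuation(sino, subset)
    return reconstruct_electron_density(
        sino, subset, phase_sensitivity=config.phase_sensitivity
    )


def _canny(config: RunConfig) -> CannyParams:
    return CannyParams(config.canny_sigma, config.canny_low, config.canny_high)


def _train_n2i(sino, signal: str, config: RunConfig, K: int,
               reference: np.ndarray | None = None) -> tuple:
    """Train one N2I model; with a reference image, use the protocol's
    reference-guided (restart, epoch) selection."""
    splits = n2i.make_split_set(
        sino, K, signal, phase_sensitivity=config.phase_sensitivity
    )
    pairs = n2i.make_training_pairs(splits)
    kwargs = dict(
        net_config=config.n2i.net_config(),
        epochs=config.n2i.epochs,
        lr=config.n2i.lr,
        patch_size=config.n2i.patch_size,
        patches_per_pair=config.n2i.patches_per_pair,
        K=K,
        signal_type=signal,
    )
    if reference is None:
        run = n2i.train(pairs, seed=config.n2i.seed, keep_checkpoints=False, **kwargs)
    else:
        run = n2i.train_and_select(
            pairs, splits, reference,
            restarts=config.n2i.restarts, seed=config.n2i.seed, **kwargs,
        )
    return run, splits


def _summary_row(denoised: np.ndarray, reference: np.ndarray,
                 config: RunConfig, **tags) -> dict:
    report = assess_stack(denoised, reference, canny_params=_canny(config))
    row = dict(tags)
    for _, rec in report.summary.iterrows():
        row[f"{rec['metric']}_mean"] = rec["mean"]
        row[f"{rec['metric']}_std"] = rec["std"]
    return row


def _prepare_run_dir(config: RunConfig, out_dir) -> Path:
    errors = config.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    return out_dir


def run_split_experiment(config: RunConfig, out_dir, dry_run: bool = False,
                         split_counts: tuple[int, ...] = (2, 4)) -> Path:
    """Noise2Inverse split-count study.

    One double-sampled noisy low-dose scan; N2I at each split count (default
    K = 2 and K = 4) for both signal types; IQA against the synthetic ground
    truth plus difference images.  Emits ``split_iqa.csv`` with one row per
    (signal, K).
    """
    out_dir = _prepare_run_dir(config, out_dir)
    plan = [f"simulate {config.phantom_size}px phantom, {config.n_angles} angles "
            f"(double-sampled), low dose"]
    plan += [f"N2I K={k} on {s}" for s in SIGNALS for k in split_counts]
    if dry_run:
        (out_dir / "plan.txt").write_text("\n".join(plan) + "\n")
        log.info("dry run: %s", plan)
        return out_dir

    phantom = make_phantom_stack(
        config.n_slices, (config.phantom_size, config.phantom_size),
        seed=config.phantom_seed,
    )
    geo = _geometry(config, config.dose_presets["low"])
    sino = retrieve(simulate_stepping(phantom, geo, noise=True))

    rows = []
    for signal in SIGNALS:
        truth = _ground_truth(phantom, signal)
        for k in split_counts:
            run, splits = _train_n2i(sino, signal, config, k, reference=truth)
            out = n2i.denoise(run, splits)
            rows.append(
                _summary_row(out.data, truth, config, signal=signal, splits=k)
            )
            tifffile.imwrite(
                out_dir / f"diff_{signal}_K{k}.tif",
                (out.data - truth).astype(np.float32),
                photometric="minisblack",
            )
            log.info("split experiment: %s K=%d done", signal, k)
    pd.DataFrame(rows).to_csv(out_dir / "split_iqa.csv", index=False)
    return out_dir


def run_comparison_experiment(config: RunConfig, out_dir,
                              with_nps: bool = True) -> Path:
    """Denoiser comparison study.

    A noisy low-dose scan is processed by FBP, patchwise phase retrieval,
    Gaussian blur and N2I (per-signal default split count); each result is
    scored against the reconstruction of a high-flux reference scan.
    Optionally adds the no-sample NPS analysis (FBP vs blur vs N2I band
    powers).  Emits ``comparison_iqa.csv`` and ``nps_curves.csv``.
    """
    out_dir = _prepare_run_dir(config, out_dir)
    phantom = make_phantom_stack(
        config.n_slices, (config.phantom_size, config.phantom_size),
        seed=config.phantom_seed,
    )
    geo_low = _geometry(config, config.dose_presets["low"])
    geo_ref = _geometry(config, config.dose_presets["reference"],
                        seed=config.scan_seed + 1)
    scan_low = simulate_stepping(phantom, geo_low, noise=True)
    sino_low = retrieve(scan_low)
    sino_ppr = retrieve_patchwise(scan_low, radius=config.ppr_radius)
    sino_ref = retrieve(simulate_stepping(phantom, geo_ref, noise=True))

    rows = []
    for signal in SIGNALS:
        reference = _reconstruct(sino_ref, signal, config).data
        fbp = _reconstruct(sino_low, signal, config)
        k = config.n2i.splits[signal]
        run, splits = _train_n2i(sino_low, signal, config, k, reference=reference)
        outputs = {
            "FBP": fbp.data,
            "PPR": _reconstruct(sino_ppr, signal, config).data,
            "Gaussian": gaussian_blur(fbp, config.gaussian_sigma).data,
            f"N2I {k}s": n2i.denoise(run, splits).data,
        }
        for method, img in outputs.items():
            rows.append(
                _summary_row(img, reference, config, signal=signal, method=method)
            )
        log.info("comparison: %s scored (%d methods)", signal, len(outputs))
    pd.DataFrame(rows).to_csv(out_dir / "comparison_iqa.csv", index=False)

    if with_nps:
        _nps_analysis(config, out_dir)
    return out_dir


def _nps_analysis(config: RunConfig, out_dir: Path) -> None:
    """No-sample noise study: NPS of FBP, blurred and N2I reconstructions."""
    records = []
    empty = PhantomVolume(
        mu=np.zeros((config.phantom_size,) * 2),
        delta=np.zeros((config.phantom_size,) * 2),
    )
    # one shared ensemble of empty-sample sinograms per run
    sinos = [
        retrieve(simulate_stepping(empty, _geometry(
            config, config.dose_presets["low"], seed=config.nps_seed + 100 + i,
        ), noise=True))
        for i in range(config.nps_realizations)
    ]
    for signal in SIGNALS:
        # one extra noise scan trains the N2I model used on the ensemble
        geo_train = _geometry(config, config.dose_presets["low"],
                              seed=config.nps_seed + 1)
        sino_train = retrieve(simulate_stepping(empty, geo_train, noise=True))
        k = config.n2i.splits[signal]
        run, _ = _train_n2i(sino_train, signal, config, k)

        fbp = [_reconstruct(s, signal, config) for s in sinos]
        variants = {
            "fbp": [t.data for t in fbp],
            "gaussian": [gaussian_blur(t, config.gaussian_sigma).data for t in fbp],
            "n2i": [
                n2i.denoise(
                    run,
                    n2i.make_split_set(
                        s, k, signal, phase_sensitivity=config.phase_sensitivity
                    ),
                ).data
                for s in sinos
            ],
        }
        for method, images in variants.items():
            curve = nps_radial(images)
            low = band_power(curve, 0.0, 0.1)
            high = band_power(curve, 0.3, 0.5)
            for kk, pp in zip(curve.k, curve.power):
                records.append({"signal": signal, "method": method,
                                "k": kk, "power": pp,
                                "low_band": low, "high_band": high})
        log.info("nps analysis: %s done", signal)
    pd.DataFrame(records).to_csv(out_dir / "nps_curves.csv", index=False)
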