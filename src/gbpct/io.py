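"""File containers: TIFF stacks + YAML sidecars for humans, NPZ for tests.

Layouts
-------
* SteppingScan directory: ``angle_0000.tif`` ... (multi-page TIFF, one page
  per grating step), ``reference.tif``, ``geometry.yaml``; or a single
  ``.npz`` with arrays ``sample``, ``reference`` and geometry fields.
* SinogramPair: ``.npz`` with ``transmission``, ``dphase``, ``angles``
  (+ optional ``mask``), or per-signal TIFF.
* Tomogram: float32 multi-page TIFF plus a YAML provenance sidecar.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .acquisition import AcquisitionGeometry, SteppingScan
from .recon import Tomogram
from .retrieval import SinogramPair

__all__ = [
    "save_scan_npz", "load_scan_npz", "save_scan_tiff", "load_scan_tiff",
    "save_sinogram", "load_sinogram", "save_tomogram", "load_tomogram",
]

_GEO_FIELDS = [f.name for f in dataclasses.fields(AcquisitionGeometry)]


def _geometry_dict(geo: AcquisitionGeometry) -> dict:
    return {k: getattr(geo, k) for k in _GEO_FIELDS}


def save_scan_npz(scan: SteppingScan, path) -> Path:
    path = Path(path)
    np.savez(path, sample=scan.sample, reference=scan.reference,
             **{f"geo_{k}": v for k, v in _geometry_dict(scan.geometry).items()})
    return path


def load_scan_npz(path) -> SteppingScan:
    with np.load(path) as z:
        geo = AcquisitionGeometry(**{k: z[f"geo_{k}"].item() for k in _GEO_FIELDS})
        return SteppingScan(sample=z["sample"], reference=z["reference"], geometry=geo)


def save_scan_tiff(scan: SteppingScan, directory) -> Path:
    """Per-angle multi-page TIFF stacks plus a YAML geometry sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(scan.sample.shape[0]):
        tifffile.imwrite(directory / f"angle_{i:04d}.tif",
                         scan.sample[i].astype(np.float32),
                         photometric="minisblack")
    tifffile.imwrite(directory / "reference.tif",
                     scan.reference.astype(np.float32), photometric="minisblack")
    with open(directory / "geometry.yaml", "w") as fh:
        yaml.safe_dump(_geometry_dict(scan.geometry), fh)
    return directory


def load_scan_tiff(directory) -> SteppingScan:
    directory = Path(directory)
    with open(directory / "geometry.yaml") as fh:
        geo = AcquisitionGeometry(**yaml.safe_load(fh))
    angle_files = sorted(directory.glob("angle_*.tif"))
    sample = np.stack([tifffile.imread(f) for f in angle_files]).astype(np.float64)
    reference = tifffile.imread(directory / "reference.tif").astype(np.float64)
    return SteppingScan(sample=sample, reference=reference, geometry=geo)


def save_sinogram(sino: SinogramPair, path) -> Path:
    path = Path(path)
    arrays = {"transmission": sino.transmission, "dphase": sino.dphase,
              "angles": sino.angles}
    if sino.mask is not None:
        arrays["mask"] = sino.mask
    np.savez(path, **arrays)
    return path


def load_sinogram(path) -> SinogramPair:
    with np.load(path) as z:
        return SinogramPair(
            transmission=z["transmission"], dphase=z["dphase"], angles=z["angles"],
            mask=z["mask"] if "mask" in z else None,
        )


def save_tomogram(tomo: Tomogram, path) -> Path:
    """Float32 (multi-page) TIFF plus `<stem>.yaml` provenance sidecar."""
    path = Path(path)
    tifffile.imwrite(path, tomo.data.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(".yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"signal_type": tomo.signal_type,
                        "provenance": tomo.provenance}, fh)
    return path


def load_tomogram(path) -> Tomogram:
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = path.with_suffix(".yaml")
    meta = {"signal_type": "attenuation", "provenance": {}}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
    return Tomogram(data=data, signal_type=meta["signal_type"],
                    provenance=meta.get("provenance") or {})
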