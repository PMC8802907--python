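"""On-disk interchange formats.

* Raw stacks: multi-page 32-bit float TIFF (one page per LED, plan order)
  plus a JSON manifest carrying the optical configuration, the illumination
  plan with wave vectors, the acquisition options, and per-page SHA-256
  checksums.  Reading validates page count and checksums and names the
  offending page on mismatch.
* Phantoms: paired 32-bit float TIFFs (amplitude, phase) plus a JSON truth
  sidecar (bar index or chromosome truth).
* Reconstruction results: HDF5 with amplitude, phase, complex pupil, and the
  residual history, plus an options echo in attributes.
* Optical configuration: a YAML document with the exact dataclass field
  names (lengths in mm, wavelengths and pixels in um).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .forward import AcquisitionOptions, RawStack
from .optics import IlluminationPlan, LEDArrayGeometry, OpticalSystemConfig
from .phantoms import (BarPatternIndex, ChromosomeTruth, ComplexObject)
from .recon import ReconstructionResult

SCHEMA_VERSION = 1


class StackIOError(ValueError):
    """A stack file and its manifest disagree or are corrupt."""


def _page_checksum(page: np.ndarray) -> str:
    return hashlib.sha256(
        np.ascontiguousarray(page, dtype=np.float32).tobytes()).hexdigest()


def _manifest_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(".json")


def write_stack(path, stack: RawStack, manifest_path=None,
                geometry: LEDArrayGeometry | None = None) -> Path:
    """Write a multi-page float32 TIFF plus its JSON manifest; returns the
    manifest path."""
    path = Path(path)
    manifest_path = Path(manifest_path) if manifest_path else _manifest_path(path)
    pages = np.asarray(stack.images, dtype=np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": stack.config.to_dict(),
        "plan": stack.plan.to_dict(),
        "options": dataclasses.asdict(stack.options),
        "pixel_um": stack.pixel_um,
        "n_images": stack.n_images,
        "image_shape": list(stack.image_shape),
        "checksums": [_page_checksum(p) for p in pages],
    }
    if geometry is not None:
        manifest["geometry"] = geometry.to_dict()
    if stack.shift_px is not None:
        manifest["shift_px"] = stack.shift_px.tolist()
        manifest["shift_residual"] = stack.shift_residual.tolist()
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_stack(path, manifest_path=None) -> RawStack:
    """Read and validate a stack written by :func:`write_stack`."""
    path = Path(path)
    manifest_path = Path(manifest_path) if manifest_path else _manifest_path(path)
    if not manifest_path.exists():
        raise StackIOError(f"manifest {manifest_path} not found")
    manifest = json.loads(manifest_path.read_text())
    if "schema_version" not in manifest:
        raise StackIOError("manifest lacks a schema_version")
    images = tifffile.imread(path)
    if images.ndim == 2:
        images = images[None]
    if images.shape[0] != manifest["n_images"]:
        raise StackIOError(
            f"manifest declares {manifest['n_images']} pages but the stack "
            f"holds {images.shape[0]}")
    for i, (page, ref) in enumerate(zip(images, manifest["checksums"])):
        if _page_checksum(page) != ref:
            raise StackIOError(f"checksum mismatch on page {i}")
    stack = RawStack(
        images=np.asarray(images, dtype=float),
        plan=IlluminationPlan.from_dict(manifest["plan"]),
        config=OpticalSystemConfig.from_dict(manifest["config"]),
        options=AcquisitionOptions(**manifest["options"]),
        pixel_um=manifest["pixel_um"],
        shift_px=np.array(manifest["shift_px"], dtype=int)
        if "shift_px" in manifest else None,
        shift_residual=np.array(manifest["shift_residual"])
        if "shift_residual" in manifest else None,
    )
    return stack


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def write_phantom(prefix, obj: ComplexObject) -> None:
    """Write ``<prefix>_amplitude.tiff``, ``<prefix>_phase.tiff`` and, when a
    truth record is attached, ``<prefix>_truth.json``."""
    prefix = Path(prefix)
    tifffile.imwrite(prefix.parent / f"{prefix.name}_amplitude.tiff",
                     obj.amplitude.astype(np.float32))
    tifffile.imwrite(prefix.parent / f"{prefix.name}_phase.tiff",
                     obj.phase.astype(np.float32))
    meta = {"pixel_um": obj.pixel_um}
    if isinstance(obj.truth, BarPatternIndex):
        meta["truth_kind"] = "usaf"
        meta["truth"] = obj.truth.to_dict()
    elif isinstance(obj.truth, ChromosomeTruth):
        meta["truth_kind"] = "chromosome"
        meta["truth"] = obj.truth.to_dict()
    (prefix.parent / f"{prefix.name}_truth.json").write_text(
        json.dumps(meta, indent=1))


def read_phantom(prefix) -> ComplexObject:
    prefix = Path(prefix)
    amplitude = tifffile.imread(prefix.parent / f"{prefix.name}_amplitude.tiff")
    phase = tifffile.imread(prefix.parent / f"{prefix.name}_phase.tiff")
    meta = json.loads((prefix.parent / f"{prefix.name}_truth.json").read_text())
    truth = None
    if meta.get("truth_kind") == "usaf":
        truth = BarPatternIndex.from_dict(meta["truth"])
    return ComplexObject(np.asarray(amplitude, dtype=float),
                         np.asarray(phase, dtype=float),
                         meta["pixel_um"], truth=truth)


# ---------------------------------------------------------------------------
# reconstruction results
# ---------------------------------------------------------------------------

def write_result(path, result: ReconstructionResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("amplitude", data=result.amplitude)
        f.create_dataset("phase", data=result.phase)
        f.create_dataset("pupil", data=result.pupil.array)
        f.create_dataset("residuals", data=np.asarray(result.residual_history))
        f.attrs["pixel_um"] = result.pixel_um
        f.attrs["pupil_na"] = result.pupil.na
        f.attrs["pupil_sampling"] = result.pupil.spectrum_sampling
        f.attrs["wavelength_um"] = result.pupil.wavelength_um
        opts = dataclasses.asdict(result.options)
        opts.pop("initial_pupil", None)
        opts.pop("callback", None)
        f.attrs["options"] = json.dumps(opts)


def read_result(path) -> dict:
    """Load a result container as a plain dict (arrays + metadata)."""
    with h5py.File(path, "r") as f:
        return {
            "amplitude": f["amplitude"][()],
            "phase": f["phase"][()],
            "pupil": f["pupil"][()],
            "residuals": f["residuals"][()].tolist(),
            "pixel_um": float(f.attrs["pixel_um"]),
            "options": json.loads(f.attrs["options"]),
        }


# ---------------------------------------------------------------------------
# configuration documents
# ---------------------------------------------------------------------------

def save_config(path, config: OpticalSystemConfig,
                geometry: LEDArrayGeometry | None = None) -> None:
    doc = {"optical_system": config.to_dict()}
    if geometry is not None:
        doc["led_array"] = geometry.to_dict()
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> tuple[OpticalSystemConfig, LEDArrayGeometry | None]:
    doc = yaml.safe_load(Path(path).read_text())
    config = OpticalSystemConfig.from_dict(doc["optical_system"])
    geometry = (LEDArrayGeometry.from_dict(doc["led_array"])
                if "led_array" in doc else None)
    return config, geometry
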