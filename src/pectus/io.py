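"""Readers and writers for axial stacks: DICOM series, NIfTI, PNG + JSON.

Slices are always returned ordered by their z position, with an explicit
pixel spacing in mm.  Spacing is taken from DICOM ``PixelSpacing``, the
NIfTI header zooms, or a JSON sidecar next to a PNG stack; a missing
spacing with no override is an error, never a silent default.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom
from PIL import Image

from .errors import DataError, ParameterError
from .phantom import AxialSlice

__all__ = ["read_stack", "write_stack_nifti", "write_stack_png",
           "write_mask_png", "read_mask_png", "detect_format"]

_SPACING_TOL = 1e-3  # relative tolerance on per-slice spacing agreement


def detect_format(path: str | Path) -> str:
    path = Path(path)
    if path.is_dir():
        if list(path.glob("*.dcm")):
            return "dicom_dir"
        if list(path.glob("*.png")):
            return "png_stack"
        raise DataError(f"directory {path} holds neither .dcm nor .png slices")
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        return "nifti"
    raise DataError(f"cannot infer input format of {path}")


def read_stack(path: str | Path, fmt: str | None = None,
               spacing_override: float | None = None) -> list[AxialSlice]:
    """Read an ordered axial stack from DICOM, NIfTI, or PNG + sidecar."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"input path {path} does not exist")
    fmt = fmt or detect_format(path)
    if fmt == "dicom_dir":
        return _read_dicom_dir(path, spacing_override)
    if fmt == "nifti":
        return _read_nifti(path, spacing_override)
    if fmt == "png_stack":
        return _read_png_stack(path, spacing_override)
    raise ParameterError(f"unsupported format {fmt!r}")


def _read_dicom_dir(path: Path, spacing_override: float | None) -> list[AxialSlice]:
    files = sorted(path.glob("*.dcm"))
    if not files:
        raise DataError(f"no .dcm files in {path}")
    loaded = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception as exc:  # unreadable file is a data error
            raise DataError(f"unreadable DICOM file {f}: {exc}") from exc
        z = float(getattr(ds, "ImagePositionPatient", [0, 0, len(loaded)])[2])
        loaded.append((z, ds, f))
    orientations = {
        tuple(np.round(np.asarray(ds.ImageOrientationPatient, float), 4))
        for _, ds, _ in loaded if hasattr(ds, "ImageOrientationPatient")
    }
    if len(orientations) > 1:
        raise DataError(f"mixed slice orientations in {path}")
    spacings = []
    for _, ds, f in loaded:
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            if abs(float(ps[0]) - float(ps[1])) > _SPACING_TOL * float(ps[0]):
                raise DataError(f"anisotropic in-plane spacing in {f}")
            spacings.append(float(ps[0]))
    spacing = _resolve_spacing(spacings, spacing_override, path)
    loaded.sort(key=lambda t: t[0])
    return [
        AxialSlice(image=ds.pixel_array.astype(np.float32),
                   spacing_mm=spacing, z_index=i)
        for i, (_, ds, _) in enumerate(loaded)
    ]


def _read_nifti(path: Path, spacing_override: float | None) -> list[AxialSlice]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise DataError(f"expected a 2-d or 3-d NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:2]
    if abs(zooms[0] - zooms[1]) > _SPACING_TOL * max(zooms[0], 1e-9):
        raise DataError(f"anisotropic in-plane spacing {zooms} in {path}")
    spacing = _resolve_spacing([float(zooms[0])] if zooms[0] > 0 else [],
                               spacing_override, path)
    return [
        AxialSlice(image=np.ascontiguousarray(data[:, :, k]),
                   spacing_mm=spacing, z_index=k)
        for k in range(data.shape[2])
    ]


def _read_png_stack(path: Path, spacing_override: float | None) -> list[AxialSlice]:
    files = sorted(path.glob("*.png"))
    files = [f for f in files if not f.stem.endswith("_mask")]
    if not files:
        raise DataError(f"no .png slices in {path}")
    sidecar = path / "stack.json"
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    spacings = [float(meta["spacing_mm"])] if "spacing_mm" in meta else []
    spacing = _resolve_spacing(spacings, spacing_override, path)
    slices = []
    scale = float(meta.get("intensity_scale", 1.0))
    offset = float(meta.get("intensity_offset", 0.0))
    for i, f in enumerate(files):
        arr = np.asarray(Image.open(f), dtype=np.float32)
        slices.append(AxialSlice(image=arr * scale + offset,
                                 spacing_mm=spacing, z_index=i))
    return slices


def _resolve_spacing(spacings: list[float], override: float | None,
                     path: Path) -> float:
    if override is not None:
        if override <= 0:
            raise ParameterError(f"spacing override must be > 0, got {override}")
        return float(override)
    if not spacings:
        raise DataError(
            f"{path}: no pixel spacing in the input and no --spacing override; "
            "refusing to guess"
        )
    ref = spacings[0]
    if any(abs(s - ref) > _SPACING_TOL * ref for s in spacings):
        raise DataError(f"{path}: non-uniform pixel spacing across slices")
    return ref


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_stack_nifti(slices: list[AxialSlice], path: str | Path,
                      slice_thickness_mm: float = 5.0) -> Path:
    """Write a stack as one NIfTI volume with spacing in the header."""
    if not slices:
        raise ParameterError("empty stack")
    spacing = slices[0].spacing_mm
    vol = np.stack([s.image for s in slices], axis=2).astype(np.float32)
    affine = np.diag([spacing, spacing, slice_thickness_mm, 1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((spacing, spacing, slice_thickness_mm))
    path = Path(path)
    nib.save(img, str(path))
    return path


def write_stack_png(slices: list[AxialSlice], outdir: str | Path,
                    ground_truth: dict | None = None) -> Path:
    """Write per-slice 16-bit PNGs plus a JSON sidecar with the spacing.

    Intensities are affinely mapped into the 16-bit range; the sidecar
    records the inverse map so reading restores the original values.
    """
    if not slices:
        raise ParameterError("empty stack")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lo = min(float(s.image.min()) for s in slices)
    hi = max(float(s.image.max()) for s in slices)
    span = (hi - lo) or 1.0
    scale = span / 65535.0
    for i, s in enumerate(slices):
        arr = np.round((s.image - lo) / scale).astype(np.uint16)
        Image.fromarray(arr).save(outdir / f"slice_{i:04d}.png")
    sidecar = {
        "spacing_mm": slices[0].spacing_mm,
        "intensity_scale": scale,
        "intensity_offset": lo,
        "n_slices": len(slices),
        "slice_indexing": "0-based",
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth
    (outdir / "stack.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def write_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray((np.asarray(mask, bool) * 255).astype(np.uint8)).save(path)
    return path


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127
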