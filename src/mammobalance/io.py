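"""Readers and writers for the raster formats mammograms ship in.

DICOM files are read with pydicom (pixel data plus ``PatientID``,
``ImageLaterality``, ``ViewPosition`` and ``PixelSpacing`` when present);
PNG/TIFF 8- and 16-bit images with Pillow.  Integer data is rescaled by
its dtype maximum to floats in [0, 1].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ConfigurationError
from .types import Mammogram


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / float(info.max)
    return np.clip(arr.astype(float), 0.0, 1.0)


def read_image(path: str | Path, **meta) -> Mammogram:
    """Read a mammogram from DICOM/PNG/TIFF; keyword metadata overrides."""
    path = Path(path)
    suffix = path.suffix.lower()
    fields: dict = {}
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        if arr.ndim != 2:
            raise ConfigurationError(f"{path}: expected a 2-D image")
        fields["patient_id"] = str(getattr(ds, "PatientID", ""))
        fields["laterality"] = str(getattr(ds, "ImageLaterality", "unknown")) or "unknown"
        fields["view"] = str(getattr(ds, "ViewPosition", "unknown")) or "unknown"
        spacing = getattr(ds, "PixelSpacing", None)
        if spacing is not None:
            fields["pixel_spacing_mm"] = float(spacing[0])
        pixels = _to_unit_float(np.asarray(arr))
    elif suffix in (".png", ".tif", ".tiff"):
        with Image.open(path) as im:
            arr = np.asarray(im)
        if arr.ndim == 3:  # collapse any palette/RGB to luminance
            arr = arr.mean(axis=2).astype(arr.dtype)
        pixels = _to_unit_float(arr)
    else:
        raise ConfigurationError(f"unsupported image format: {path.suffix}")

    fields.update(meta)
    return Mammogram(pixels=pixels, **fields)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as lossless 16-bit PNG."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray(np.round(arr * 65535).astype(np.uint16)).save(path)


def load_record(row, **meta) -> Mammogram:
    """Load one manifest row (a pandas Series or dict) into a Mammogram."""
    return read_image(
        row["path"],
        patient_id=str(row["patient_id"]),
        breast_id=str(row["breast_id"]),
        laterality=str(row["laterality"]),
        view=str(row["view"]),
        label=int(row["label"]),
        **meta,
    )
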