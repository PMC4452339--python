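"""Image and report I/O.

Grayscale PNG/TIFF (8- or 16-bit) are the native formats; single-slice
DICOM is read when ``pydicom`` is importable (pixel spacing is taken from
the PixelSpacing tag).  Reports are written as JSON and CSV twins holding
identical records with deterministic field order and fixed float precision.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .classify import DetectionReport
from .errors import FormatError
from .image import DEFAULT_SPACING_MM, Image2D

__all__ = ["load_image", "save_image", "write_report", "read_report"]

_REPORT_FIELDS = (
    "label",
    "centroid_row",
    "centroid_col",
    "area_px",
    "peak_response",
    "best_sigma_px",
    "d1_mm",
    "d2_mm",
)
_FLOAT_PRECISION = 6

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[..., :3].astype(np.float64) @ _LUMA
    raise FormatError(f"cannot interpret array of shape {arr.shape} as a 2D grayscale image")


def _load_dicom(path: Path) -> Image2D:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise FormatError(
            f"{path}: DICOM support requires the optional 'pydicom' package"
        ) from exc
    ds = pydicom.dcmread(path)
    spacing = DEFAULT_SPACING_MM
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None:
        spacing = float(ps[0])
    return Image2D(_to_grayscale(np.asarray(ds.pixel_array)), spacing)


def load_image(path: str | Path, spacing_mm: float | None = None) -> Image2D:
    """Load a PNG/TIFF/DICOM file as a grayscale :class:`Image2D`.

    ``spacing_mm`` overrides the file's spacing (DICOM) or the default.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        img = _load_dicom(path)
        if spacing_mm is not None:
            img = Image2D(img.data, spacing_mm)
        return img
    if suffix not in (".png", ".tif", ".tiff"):
        raise FormatError(f"{path}: unsupported image format {suffix!r}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise FormatError(f"{path}: could not read image ({exc})") from exc
    return Image2D(_to_grayscale(np.asarray(arr)), spacing_mm or DEFAULT_SPACING_MM)


def save_image(path: str | Path, image, bit_depth: int = 8) -> None:
    """Save an image/array as 8- or 16-bit grayscale PNG/TIFF, rescaling
    floats to the full dtype range when values exceed it."""
    from .image import as_array

    data = as_array(image)
    if bit_depth == 8:
        dtype, vmax = np.uint8, 255.0
    elif bit_depth == 16:
        dtype, vmax = np.uint16, 65535.0
    else:
        raise FormatError(f"bit_depth must be 8 or 16, got {bit_depth}")
    top = float(data.max(initial=0.0))
    if top > vmax:
        data = data * (vmax / top)
    out = np.clip(np.rint(data), 0, vmax).astype(dtype)
    try:
        iio.imwrite(Path(path), out)
    except Exception as exc:
        raise FormatError(f"{path}: could not write image ({exc})") from exc


def _records(report: DetectionReport) -> list[dict]:
    records = []
    for decision in report.decisions:
        raw = decision.to_record()
        rec = {}
        for key in _REPORT_FIELDS:
            val = raw[key]
            if isinstance(val, float):
                val = round(val, _FLOAT_PRECISION)
            rec[key] = val
        records.append(rec)
    return records


def write_report(report: DetectionReport, path: str | Path, format: str = "json") -> None:
    """Write a detection report as JSON or CSV (identical records)."""
    path = Path(path)
    records = _records(report)
    try:
        if format == "json":
            payload = {
                "n_suspects": len(report.suspects),
                "n_unclassifiable": len(report.unclassifiable),
                "decisions": records,
            }
            if report.config is not None:
                payload["config"] = report.config.to_dict()
            path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
        elif format == "csv":
            with path.open("w", newline="") as fh:
                writer = csv.DictWriter(fh, fieldnames=_REPORT_FIELDS)
                writer.writeheader()
                writer.writerows(records)
        else:
            raise FormatError(f"unknown report format {format!r}")
    except OSError as exc:
        raise FormatError(f"{path}: could not write report ({exc})") from exc


def read_report(path: str | Path) -> list[dict]:
    """Read back the decision records of a JSON or CSV report."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with path.open(newline="") as fh:
            rows = list(csv.DictReader(fh))
        for row in rows:
            for key in _REPORT_FIELDS:
                if key != "label":
                    row[key] = float(row[key])
            row["area_px"] = int(row["area_px"])
        return rows
    return json.loads(path.read_text())["decisions"]
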