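"""Image readers/writers for the supported slice formats.

Supported inputs: 8/16-bit grayscale PNG/TIFF, single-slice NIfTI
(``.nii``/``.nii.gz``) and single-slice DICOM (requires the optional
``pydicom`` dependency).  Readers return ``(image, pixel_spacing_mm)`` where
the spacing is ``None`` when the format carries none.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["read_image", "write_labels", "write_centers_csv", "write_report",
           "write_overlay"]


def _read_nifti(path: Path):
    import nibabel as nib
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).squeeze()
    if data.ndim != 2:
        raise ValueError(
            f"expected a single-slice NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()
    spacing = float(zooms[0]) if zooms else None
    return np.asarray(data, dtype=float), spacing


def _read_dicom(path: Path):
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "DICOM input requires the optional 'pydicom' package "
            "(pip install discgabor[dicom])") from exc
    ds = pydicom.dcmread(str(path))
    data = ds.pixel_array.squeeze()
    if data.ndim != 2:
        raise ValueError(f"expected a single-slice DICOM, got {data.shape}")
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    return np.asarray(data, dtype=float), spacing


def read_image(path, spacing: float | None = None):
    """Read a 2-D grayscale slice; returns ``(float array, spacing_mm)``.

    An explicit ``spacing`` argument overrides any value in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        data, file_spacing = _read_nifti(path)
    elif suffixes.endswith((".dcm", ".dicom")):
        data, file_spacing = _read_dicom(path)
    else:
        import imageio.v3 as iio
        data = np.asarray(iio.imread(str(path)))
        if data.ndim == 3:  # RGB(A): accept gray-encoded color images
            data = data[..., :3].mean(axis=-1)
        file_spacing = None
    if data.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {data.shape}")
    return np.asarray(data, dtype=float), (spacing if spacing is not None
                                           else file_spacing)


def write_labels(path, label_image: np.ndarray) -> None:
    """Write a 16-bit label mask PNG (label k = disc k)."""
    from PIL import Image
    arr = np.asarray(label_image, dtype=np.uint16)
    Image.fromarray(arr).save(str(path))


def write_centers_csv(path, detections) -> None:
    import pandas as pd
    rows = [{"disc_id": k, "row": d.center[0], "col": d.center[1],
             "angle_deg": d.angle,
             "box_top": d.box[0], "box_bottom": d.box[1],
             "box_left": d.box[2], "box_right": d.box[3]}
            for k, d in enumerate(detections, start=1)]
    pd.DataFrame(rows).to_csv(str(path), index=False)


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)


def write_overlay(path, image: np.ndarray, detections, masks) -> None:
    """Render detections and mask contours over the slice."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6 * image.shape[0] / image.shape[1]))
    ax.imshow(image, cmap="gray")
    for k, det in enumerate(detections, start=1):
        r, c = det.center
        ax.plot(c, r, "r+", markersize=8)
        top, bottom, left, right = det.box
        ax.add_patch(plt.Rectangle((left, top), right - left, bottom - top,
                                   fill=False, edgecolor="yellow",
                                   linewidth=0.8))
        ax.annotate(str(k), (c + 4, r), color="red", fontsize=7)
    for mask in masks:
        if mask.any():
            ax.contour(mask, levels=[0.5], colors="lime", linewidths=0.8)
    ax.set_axis_off()
    fig.savefig(str(path), dpi=150, bbox_inches="tight")
    plt.close(fig)
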