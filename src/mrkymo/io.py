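"""Reading and writing of image stacks, sidecars, landmarks, and results.

Supported stack formats: multi-frame TIFF (grayscale float or 16-bit),
DICOM series (one file per frame, ordered by instance/temporal index), and
NIfTI 2D+t.  Pixel spacing and frame interval are taken from file metadata
where present and otherwise fall back to configured defaults (500/192 mm
and 0.6 s), with the provenance recorded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .phantom import AxisTruth, GroundTruth, PhantomConfig
from .series import ContourStack, Direction, ImageSeries, Plane
from .kymogram import Landmarks

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SPACING_MM = 500.0 / 192.0
DEFAULT_FRAME_INTERVAL_S = 0.6


# ---------------------------------------------------------------------------
# Stacks
# ---------------------------------------------------------------------------

def write_tiff(path: str | Path, series: ImageSeries | ContourStack) -> None:
    """Write a series as a multi-frame grayscale TIFF with resolution tags."""
    import tifffile

    frames = series.frames
    data = frames.astype(np.float32) if frames.dtype != bool else frames.astype(np.uint8) * 255
    tifffile.imwrite(
        str(path),
        data,
        metadata={
            "pixel_spacing_mm": series.pixel_spacing_mm,
            "frame_interval_s": series.frame_interval_s,
            "plane": series.plane.value,
        },
    )


def _read_tiff(path: Path, pixel_spacing_mm, frame_interval_s, plane) -> ImageSeries:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        frames = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    spacing = pixel_spacing_mm or meta.get("pixel_spacing_mm")
    interval = frame_interval_s or meta.get("frame_interval_s")
    plane = plane or meta.get("plane", Plane.CORONAL)
    if spacing is None:
        spacing = DEFAULT_PIXEL_SPACING_MM
        logger.info("TIFF without spacing metadata: using default %.4f mm/px", spacing)
    if interval is None:
        interval = DEFAULT_FRAME_INTERVAL_S
        logger.info("TIFF without frame interval: using default %.1f s", interval)
    return ImageSeries(frames=np.asarray(frames, float), pixel_spacing_mm=float(spacing),
                       frame_interval_s=float(interval), plane=Plane(plane))


def write_nifti(path: str | Path, series: ImageSeries) -> None:
    """Write a series as NIfTI 2D+t (x, y, 1, t on disk)."""
    import nibabel as nib

    data = np.transpose(series.frames, (2, 1, 0))[:, :, np.newaxis, :]
    affine = np.diag([series.pixel_spacing_mm, series.pixel_spacing_mm, 1.0, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    img.header.set_zooms((series.pixel_spacing_mm, series.pixel_spacing_mm, 1.0,
                          series.frame_interval_s))
    nib.save(img, str(path))


def _read_nifti(path: Path, pixel_spacing_mm, frame_interval_s, plane) -> ImageSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        data = data[:, :, 0, :]
    if data.ndim != 3:
        raise ValueError(f"NIfTI stack must be 2D+t, got shape {data.shape}")
    frames = np.transpose(data, (2, 1, 0))
    zooms = img.header.get_zooms()
    spacing = pixel_spacing_mm or float(zooms[0])
    interval = frame_interval_s or (float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0
                                    else DEFAULT_FRAME_INTERVAL_S)
    return ImageSeries(frames=frames, pixel_spacing_mm=spacing,
                       frame_interval_s=float(interval), plane=Plane(plane or Plane.CORONAL))


def write_dicom_series(path: str | Path, series: ImageSeries) -> None:
    """Write one DICOM file per frame (secondary-capture style) into a directory."""
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    peak = series.frames.max() or 1.0
    scaled = (series.frames / peak * 4095).astype(np.uint16)
    for k in range(series.n_frames):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
        ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.InstanceNumber = k + 1
        ds.PixelSpacing = [series.pixel_spacing_mm, series.pixel_spacing_mm]
        ds.FrameTime = series.frame_interval_s * 1000.0  # ms
        ds.SeriesDescription = series.plane.value
        ds.Rows, ds.Columns = scaled.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = scaled[k].tobytes()
        ds.save_as(outdir / f"frame_{k:04d}.dcm", enforce_file_format=True)


def _read_dicom(path: Path, pixel_spacing_mm, frame_interval_s, plane) -> ImageSeries:
    import pydicom

    files = sorted(Path(path).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    frames = []
    shape = None
    for i, ds in enumerate(datasets):
        arr = ds.pixel_array.astype(float)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"frame {i} has shape {arr.shape}, expected {shape}")
        frames.append(arr)
    ds0 = datasets[0]
    spacing = pixel_spacing_mm or (float(ds0.PixelSpacing[0]) if "PixelSpacing" in ds0
                                   else DEFAULT_PIXEL_SPACING_MM)
    interval = frame_interval_s or (float(ds0.FrameTime) / 1000.0 if "FrameTime" in ds0
                                    else DEFAULT_FRAME_INTERVAL_S)
    plane = plane or getattr(ds0, "SeriesDescription", Plane.CORONAL.value)
    try:
        plane = Plane(plane)
    except ValueError:
        plane = Plane.CORONAL
    return ImageSeries(frames=np.stack(frames), pixel_spacing_mm=spacing,
                       frame_interval_s=interval, plane=plane)


def read_stack(
    path: str | Path,
    format: str | None = None,
    pixel_spacing_mm: float | None = None,
    frame_interval_s: float | None = None,
    plane: Plane | str | None = None,
) -> ImageSeries:
    """Read a dynamic series from TIFF, DICOM directory, or NIfTI.

    Explicit arguments override file metadata, which overrides the
    acquisition defaults (500/192 mm/px, 0.6 s).
    """
    path = Path(path)
    if format is None:
        if path.is_dir():
            format = "dicom"
        elif path.suffix in (".nii", ".gz"):
            format = "nifti"
        else:
            format = "tiff"
    readers = {"tiff": _read_tiff, "dicom": _read_dicom, "nifti": _read_nifti}
    if format not in readers:
        raise ValueError(f"unknown stack format {format!r}")
    return readers[format](path, pixel_spacing_mm, frame_interval_s, plane)


# ---------------------------------------------------------------------------
# Sidecars, landmarks, results
# ---------------------------------------------------------------------------

def write_sidecar(path: str | Path, config: PhantomConfig, truth: GroundTruth) -> None:
    """JSON sidecar with the phantom configuration and its ground truth."""
    cfg = dataclasses.asdict(config)
    cfg["plane"] = config.plane.value
    payload = {
        "config": cfg,
        "ground_truth": {
            d.value: dataclasses.asdict(t) for d, t in truth.axes.items()
        },
        "cycle_scales": None if truth.cycle_scales is None else list(truth.cycle_scales),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_sidecar(path: str | Path) -> tuple[PhantomConfig, GroundTruth]:
    payload = json.loads(Path(path).read_text())
    cfg = payload["config"]
    cfg["plane"] = Plane(cfg["plane"])
    if cfg.get("thorax_semiaxes_mm"):
        cfg["thorax_semiaxes_mm"] = tuple(cfg["thorax_semiaxes_mm"])
    if cfg.get("irregular_cycle"):
        cfg["irregular_cycle"] = tuple(cfg["irregular_cycle"])
    config = PhantomConfig(**cfg)
    axes = {
        Direction(d): AxisTruth(**t) for d, t in payload["ground_truth"].items()
    }
    scales = payload.get("cycle_scales")
    truth = GroundTruth(axes=axes, config=config,
                        cycle_scales=None if scales is None else np.asarray(scales))
    return config, truth


def write_landmarks(path: str | Path, landmarks: Landmarks, frame: int = 0) -> None:
    """Landmarks as a CSV table with columns name, x, y, frame."""
    rows = [{"name": k, "x": x, "y": y, "frame": frame}
            for k, (x, y) in landmarks.points.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path: str | Path, frame_shape: tuple[int, int] | None = None) -> Landmarks:
    df = pd.read_csv(path)
    for col in ("name", "x", "y"):
        if col not in df.columns:
            raise ValueError(f"landmarks file missing column {col!r}")
    points = {str(r["name"]): (float(r["x"]), float(r["y"])) for _, r in df.iterrows()}
    return Landmarks(points=points, frame_shape=frame_shape)


def measurements_to_frame(measurements: list) -> pd.DataFrame:
    """Tidy table of measurements (one row per direction) with provenance."""
    rows = []
    for m in measurements:
        if m is None:
            continue
        rows.append(
            {
                "direction": m.direction.value,
                "position": m.position.value,
                "end_insp_mm": m.end_insp_mm,
                "end_exp_mm": m.end_exp_mm,
                "expansion_mm": m.expansion_mm,
                "t_end_insp": m.t_end_insp,
                "t_end_exp": m.t_end_exp,
                "axis_coordinate": m.axis_coordinate,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "direction", "position", "end_insp_mm", "end_exp_mm", "expansion_mm",
            "t_end_insp", "t_end_exp", "axis_coordinate",
        ],
    )
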