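"""Readers and writers: DICOM series, raw 4D binary, ROI files, map export.

Coordinate conventions (fixed across the package): indices are 0-based;
raw binary files store X fastest-varying (Fortran order over X-Y-Z-time);
masks and exported matrices are in display order (rows = Y, cols = X).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import DCESeries
from .fitting import ROI, ParameterMap
from .signal_model import AcquisitionParams

__all__ = [
    "read_raw_4d",
    "write_raw_4d",
    "read_dicom_series",
    "write_dicom_series",
    "save_roi",
    "load_roi",
    "export_map",
    "parse_map",
]

_DTYPES = {"uint8": "u1", "int16": "i2", "uint16": "u2",
           "int32": "i4", "float32": "f4", "float64": "f8"}


# ---------------------------------------------------------------------- raw

def write_raw_4d(series: DCESeries, path, dtype: str = "float32",
                 byteorder: str = "little") -> None:
    """Write the 4D array as raw binary (X fastest) plus a JSON sidecar."""
    path = Path(path)
    code = ("<" if byteorder == "little" else ">") + _DTYPES[dtype]
    series.data.astype(code).ravel(order="F").tofile(path)
    sidecar = {
        "dims": list(series.shape), "dtype": dtype, "byteorder": byteorder,
        "order": "x-fastest",
        "frame_interval": series.frame_interval,
        "acq": {"sequence_kind": series.acq.sequence_kind,
                "TR": series.acq.TR, "flip_angle": series.acq.flip_angle,
                "frame_interval": series.acq.frame_interval,
                "injection_frame": series.acq.injection_frame},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))


def read_raw_4d(path, dims=None, dtype: str = "float32",
                byteorder: str = "little",
                acq: AcquisitionParams | None = None) -> DCESeries:
    """Read raw 4D binary data.

    If a ``<path>.json`` sidecar exists it supplies dims/dtype/byteorder and
    acquisition parameters; explicit arguments override it.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        dims = dims or tuple(side["dims"])
        dtype = side.get("dtype", dtype)
        byteorder = side.get("byteorder", byteorder)
        if acq is None and "acq" in side:
            acq = AcquisitionParams(**side["acq"])
    if dims is None:
        raise ValueError("dims required (no sidecar found)")
    if acq is None:
        raise ValueError("acquisition parameters required (no sidecar found)")
    code = ("<" if byteorder == "little" else ">") + _DTYPES[dtype]
    expected = int(np.prod(dims)) * np.dtype(code).itemsize
    actual = path.stat().st_size
    if expected != actual:
        raise ValueError(f"size mismatch: expected {expected} bytes for "
                         f"dims {tuple(dims)} ({dtype}), file has {actual}")
    data = np.fromfile(path, dtype=code).reshape(dims, order="F")
    frame_times = np.arange(dims[3]) * acq.frame_interval
    return DCESeries(data.astype(float), frame_times, acq,
                     provenance=f"raw binary {path.name}")


# -------------------------------------------------------------------- dicom

def write_dicom_series(series: DCESeries, directory) -> list[Path]:
    """Write one DICOM file per (slice, frame).

    Pixel data is stored as uint16 with a per-file rescale slope/intercept,
    so the round trip is exact up to that quantization (~1.5e-5 of the
    per-frame range).  The injection frame is recorded in ImageComments.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    nx, ny, nz, nt = series.shape
    paths = []
    inst = 0
    for t in range(nt):
        for z in range(nz):
            inst += 1
            frame = series.data[:, :, z, t].T  # (Y, X) rows = Y
            vmin, vmax = float(frame.min()), float(frame.max())
            slope = (vmax - vmin) / 65535.0 if vmax > vmin else 1.0
            stored = np.round((frame - vmin) / slope).astype(np.uint16)

            meta = FileMetaDataset()
            meta.MediaStorageSOPClassUID = MRImageStorage
            meta.MediaStorageSOPInstanceUID = generate_uid()
            meta.TransferSyntaxUID = ExplicitVRLittleEndian

            ds = Dataset()
            ds.file_meta = meta
            ds.SOPClassUID = MRImageStorage
            ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
            ds.StudyInstanceUID = study_uid
            ds.SeriesInstanceUID = series_uid
            ds.Modality = "MR"
            ds.PatientName = "PHANTOM"
            ds.PatientID = "PHANTOM"
            ds.InstanceNumber = inst
            ds.TemporalPositionIdentifier = t + 1
            ds.NumberOfTemporalPositions = nt
            ds.ImagePositionPatient = [0.0, 0.0, float(z)]
            ds.SliceLocation = float(z)
            ds.RepetitionTime = series.acq.TR
            ds.FlipAngle = series.acq.flip_angle
            ds.TemporalResolution = series.acq.frame_interval * 1000.0  # ms
            ds.ImageComments = json.dumps(
                {"injection_frame": series.acq.injection_frame,
                 "sequence_kind": series.acq.sequence_kind})
            ds.Rows, ds.Columns = ny, nx
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.RescaleSlope = slope
            ds.RescaleIntercept = vmin
            ds.PixelData = stored.tobytes()
            p = directory / f"frame{t:05d}_slice{z:03d}.dcm"
            ds.save_as(p, enforce_file_format=True)
            paths.append(p)
    return paths


def read_dicom_series(directory) -> DCESeries:
    """Read a directory of single-frame DICOM files into a 4D series.

    Frames are ordered by temporal position (falling back to acquisition
    time, then instance number) and slice location; pixel values are
    rescaled by slope/intercept.  A directory mixing several series is
    rejected, listing the UIDs found.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.is_file() and not p.name.startswith("."))
    datasets = []
    for p in files:
        try:
            datasets.append((p, pydicom.dcmread(p)))
        except Exception:
            continue
    if not datasets:
        raise ValueError(f"no DICOM files found in {directory}")
    uids = sorted({str(ds.SeriesInstanceUID) for _, ds in datasets})
    if len(uids) > 1:
        raise ValueError("directory contains multiple series: " + ", ".join(uids))

    def temporal_key(ds):
        if "TemporalPositionIdentifier" in ds:
            return int(ds.TemporalPositionIdentifier)
        if "AcquisitionTime" in ds:
            return float(ds.AcquisitionTime)
        return int(ds.get("InstanceNumber", 0))

    def slice_key(ds):
        if "SliceLocation" in ds:
            return float(ds.SliceLocation)
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return 0.0

    t_vals = sorted({temporal_key(ds) for _, ds in datasets})
    z_vals = sorted({slice_key(ds) for _, ds in datasets})
    nt, nz = len(t_vals), len(z_vals)
    first = datasets[0][1]
    ny, nx = int(first.Rows), int(first.Columns)
    data = np.zeros((nx, ny, nz, nt))
    for _, ds in datasets:
        ti = t_vals.index(temporal_key(ds))
        zi = z_vals.index(slice_key(ds))
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        data[:, :, zi, ti] = (arr * slope + inter).T

    TR = float(getattr(first, "RepetitionTime", 1.0))
    flip = float(getattr(first, "FlipAngle", 90.0))
    dt = float(getattr(first, "TemporalResolution", 1000.0)) / 1000.0
    injection_frame, seq = 1, "spgr"
    if "ImageComments" in first:
        try:
            extra = json.loads(str(first.ImageComments))
            injection_frame = int(extra.get("injection_frame", 1))
            seq = extra.get("sequence_kind", "spgr")
        except (json.JSONDecodeError, TypeError):
            pass
    acq = AcquisitionParams(seq, TR=TR, flip_angle=flip, frame_interval=dt,
                            injection_frame=injection_frame)
    frame_times = np.arange(nt) * dt
    return DCESeries(data, frame_times, acq, provenance=f"DICOM {directory}")


# ---------------------------------------------------------------------- roi

ROI_FORMAT_VERSION = 1


def save_roi(roi: ROI, path) -> None:
    """Persist an ROI as versioned JSON with a run-length-encoded mask."""
    flat = roi.mask.ravel().astype(np.int8)
    # RLE starting with the count of leading zeros (may be 0)
    runs, current, count = [], 0, 0
    for v in flat:
        if v == current:
            count += 1
        else:
            runs.append(int(count))
            current, count = v, 1
    runs.append(int(count))
    doc = {"format": "dcepk-roi", "version": ROI_FORMAT_VERSION,
           "slice_index": roi.slice_index, "bin_factor": roi.bin_factor,
           "kind": roi.kind, "shape": list(roi.mask.shape), "rle": runs}
    Path(path).write_text(json.dumps(doc))


def load_roi(path) -> ROI:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "dcepk-roi":
        raise ValueError("not a dcepk ROI file")
    if doc.get("version") != ROI_FORMAT_VERSION:
        raise ValueError(f"unsupported ROI file version {doc.get('version')!r}")
    shape = tuple(doc["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos, val = 0, False
    for run in doc["rle"]:
        if val:
            flat[pos:pos + run] = True
        pos += run
        val = not val
    if pos != flat.size:
        raise ValueError("corrupt RLE mask")
    return ROI(doc["slice_index"], flat.reshape(shape),
               doc["bin_factor"], doc["kind"])


# ---------------------------------------------------------------------- maps

_FMT = "%.10g"


def _fmt(v: float) -> str:
    return "nan" if not np.isfinite(v) else _FMT % v


def export_map(pmap: ParameterMap, path,
               layout: str = "matrix") -> None:
    """Write a parameter map as text.

    Layouts: ``single_column`` (one value per line, row-major, one section
    per parameter), ``multi_column`` (x, y, then one column per parameter),
    ``matrix`` (one 2D block per parameter).  Missing cells are ``nan``.
    """
    gh, gw = pmap.grid_shape
    lines = [f"# dcepk map  model: {pmap.model}  layout: {layout}",
             f"# grid: {gh} {gw}",
             f"# parameters: {' '.join(pmap.param_names)}"]
    if layout == "single_column":
        for n in pmap.param_names:
            lines.append(f"# parameter: {n}  grid: {gh} {gw}")
            lines.extend(_fmt(v) for v in pmap.maps[n].ravel())
    elif layout == "multi_column":
        lines.append("# columns: x y " + " ".join(pmap.param_names))
        for i in range(gh):
            for j in range(gw):
                vals = " ".join(_fmt(pmap.maps[n][i, j]) for n in pmap.param_names)
                lines.append(f"{j} {i} {vals}")
    elif layout == "matrix":
        for n in pmap.param_names:
            lines.append(f"# parameter: {n}")
            for i in range(gh):
                lines.append(" ".join(_fmt(v) for v in pmap.maps[n][i]))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_map(path) -> dict[str, np.ndarray]:
    """Parse any layout written by :func:`export_map` back to arrays."""
    text = Path(path).read_text().splitlines()
    header = [l for l in text if l.startswith("#")]
    layout = None
    gh = gw = None
    names: list[str] = []
    for l in header:
        if "layout:" in l:
            layout = l.split("layout:")[1].strip()
        if l.startswith("# grid:"):
            gh, gw = (int(v) for v in l.split(":")[1].split())
        if l.startswith("# parameters:"):
            names = l.split(":")[1].split()
    if layout is None or gh is None:
        raise ValueError("not a dcepk map file")

    out = {n: np.full((gh, gw), np.nan) for n in names}
    if layout == "single_column":
        current, vals = None, []
        for l in text:
            if l.startswith("# parameter:"):
                if current is not None:
                    out[current] = np.array(vals).reshape(gh, gw)
                current, vals = l.split(":")[1].split()[0], []
            elif not l.startswith("#") and l.strip():
                vals.append(float(l))
        if current is not None:
            out[current] = np.array(vals).reshape(gh, gw)
    elif layout == "multi_column":
        for l in text:
            if l.startswith("#") or not l.strip():
                continue
            toks = l.split()
            x, y = int(toks[0]), int(toks[1])
            for n, v in zip(names, toks[2:]):
                out[n][y, x] = float(v)
    elif layout == "matrix":
        current, rows = None, []
        for l in text:
            if l.startswith("# parameter:"):
                if current is not None:
                    out[current] = np.array(rows)
                current, rows = l.split(":")[1].strip(), []
            elif not l.startswith("#") and l.strip():
                rows.append([float(v) for v in l.split()])
        if current is not None:
            out[current] = np.array(rows)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return out
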