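"""Image-stack I/O and ROI-mean fluorescence extraction.

Turns a multi-page TIFF stack plus region-of-interest definitions (ImageJ
``.roi``/``.zip`` files or JSON polygon lists) into per-region fluorescence
traces, and provides ΔF/F computation and 0–1 normalization.

Conventions: pixel coordinates are 0-based ``(row, col)``; a pixel belongs
to a polygon ROI if its center lies inside under the even-odd rule (the
ImageJ-compatible convention); times are seconds from recording start;
intervals are half-open.
"""

from __future__ import annotations

import json
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from slicephys.trace import FluorescenceTrace, TraceError


class RoiError(ValueError):
    """Invalid ROI definition."""


@dataclass
class Roi:
    """One region of interest: a polygon (vertices as ``(row, col)``
    floats) or an explicit boolean mask."""

    label: str
    polygon: Optional[np.ndarray] = None   # (n, 2) of (row, col)
    mask: Optional[np.ndarray] = None      # 2-D bool

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.mask is None):
            raise RoiError(f"ROI {self.label!r}: give exactly one of polygon or mask")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, dtype=np.float64)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or self.polygon.shape[0] < 3:
                raise RoiError(f"ROI {self.label!r}: polygon needs >= 3 (row, col) vertices")
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise RoiError(f"ROI {self.label!r}: mask has no true pixels")

    def to_mask(self, frame_shape: Tuple[int, int]) -> np.ndarray:
        """Rasterize to a boolean mask of ``frame_shape``."""
        if self.mask is not None:
            if self.mask.shape != tuple(frame_shape):
                raise RoiError(
                    f"ROI {self.label!r}: mask shape {self.mask.shape} does "
                    f"not match frame shape {tuple(frame_shape)}")
            return self.mask
        rows, cols = frame_shape
        if (self.polygon[:, 0].min() < 0 or self.polygon[:, 1].min() < 0
                or self.polygon[:, 0].max() > rows or self.polygon[:, 1].max() > cols):
            raise RoiError(f"ROI {self.label!r}: polygon extends outside the frame")
        mask = rasterize_polygon(self.polygon, frame_shape)
        if not mask.any():
            raise RoiError(f"ROI {self.label!r}: polygon covers no pixel centers")
        return mask


def rasterize_polygon(polygon: np.ndarray, frame_shape: Tuple[int, int]) -> np.ndarray:
    """Even-odd (crossing-number) polygon rasterization.

    A pixel ``(r, c)`` is inside if its center ``(r + 0.5, c + 0.5)`` in
    vertex coordinates is crossed an odd number of times by a ray — the
    same convention ImageJ uses for polygon ROIs.
    """
    rows, cols = frame_shape
    poly = np.asarray(polygon, dtype=np.float64)
    r0 = max(int(np.floor(poly[:, 0].min())), 0)
    r1 = min(int(np.ceil(poly[:, 0].max())) + 1, rows)
    c0 = max(int(np.floor(poly[:, 1].min())), 0)
    c1 = min(int(np.ceil(poly[:, 1].max())) + 1, cols)
    mask = np.zeros(frame_shape, dtype=bool)
    if r0 >= r1 or c0 >= c1:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1) + 0.5, np.arange(c0, c1) + 0.5,
                         indexing="ij")
    inside = np.zeros(rr.shape, dtype=bool)
    n = poly.shape[0]
    for i in range(n):
        ra, ca = poly[i]
        rb, cb = poly[(i + 1) % n]
        if ra == rb:
            continue
        crosses = ((ra > rr) != (rb > rr))
        with np.errstate(divide="ignore", invalid="ignore"):
            c_at = ca + (rr - ra) * (cb - ca) / (rb - ra)
        inside ^= crosses & (cc < c_at)
    mask[r0:r1, c0:c1] = inside
    return mask


@dataclass
class RoiSet:
    """A labelled collection of ROIs tied to a frame shape."""

    rois: List[Roi]
    frame_shape: Tuple[int, int]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise RoiError("ROI labels must be unique")

    def masks(self) -> List[np.ndarray]:
        return [r.to_mask(self.frame_shape) for r in self.rois]


# --------------------------------------------------------------------------
# Trace extraction and normalization
# --------------------------------------------------------------------------

def extract_roi_traces(
    stack: Union[np.ndarray, str, Path],
    rois: RoiSet,
    frame_rate: float = 10.0,
    drug_onset: Optional[float] = None,
) -> List[FluorescenceTrace]:
    """Mean-over-ROI fluorescence trace for every ROI, in ROI order.

    ``stack`` is a ``(frames, rows, cols)`` array or a path to a
    multi-page TIFF.  Dropped frames (all-NaN pixels within the ROI)
    propagate as NaN samples.
    """
    if isinstance(stack, (str, Path)):
        import tifffile

        stack = tifffile.imread(str(stack))
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise TraceError("stack must be a non-empty (frames, rows, cols) array")
    if stack.shape[1:] != tuple(rois.frame_shape):
        raise RoiError(
            f"stack frames {stack.shape[1:]} do not match ROI frame shape "
            f"{tuple(rois.frame_shape)}")
    traces = []
    for roi in rois.rois:
        mask = roi.to_mask(rois.frame_shape)
        pix = stack[:, mask]
        values = pix.mean(axis=1)
        traces.append(FluorescenceTrace(
            values=values, frame_rate=frame_rate, kind="raw",
            region=roi.label, drug_onset=drug_onset, trace_id=roi.label))
    return traces


def compute_dff(
    trace: FluorescenceTrace,
    baseline_window: Tuple[float, float] = (0.0, 600.0),
) -> FluorescenceTrace:
    """ΔF/F: ``(F − F0)/F0`` with F0 the mean over the baseline window.

    The default window is the 10-min pre-drug baseline period.  Dropped
    frames are excluded from F0.
    """
    if trace.kind != "raw":
        raise TraceError(f"compute_dff expects a raw trace, got kind={trace.kind!r}")
    t = trace.times
    sel = (t >= baseline_window[0]) & (t < baseline_window[1])
    window_values = trace.values[sel]
    window_values = window_values[np.isfinite(window_values)]
    if window_values.size == 0:
        raise TraceError("baseline window contains no valid samples")
    f0 = float(window_values.mean())
    if f0 <= 0:
        raise TraceError(f"baseline fluorescence F0={f0:.3g} must be positive")
    return trace.with_values((trace.values - f0) / f0, kind="dff")


def normalize_unit(trace: FluorescenceTrace) -> FluorescenceTrace:
    """Affine map of the trace onto [0, 1] (min → 0, max → 1).

    Dropped frames are excluded from the min/max and stay NaN.  Long runs
    of dropped frames are an error; a constant trace has no range to map
    and is rejected.
    """
    trace.check_dropped_frames()
    finite = trace.values[np.isfinite(trace.values)]
    if finite.size < 2:
        raise TraceError("need at least 2 valid samples to normalize")
    vmin, vmax = float(finite.min()), float(finite.max())
    if vmax == vmin:
        raise TraceError("constant trace has no range to normalize")
    return trace.with_values((trace.values - vmin) / (vmax - vmin),
                             kind="normalized")


# --------------------------------------------------------------------------
# ROI file formats
# --------------------------------------------------------------------------
# ImageJ .roi is a small binary format: magic "Iout", a 64-byte header
# with the ROI type and bounding box, then int16 x- and y-offsets of the
# polygon vertices relative to the bounding box.  Only the polygon-like
# types (polygon, freehand, traced) and rectangles are supported here;
# JSON polygon lists are the text-based alternative.

_IJ_POLYGON_TYPES = {0: "polygon", 7: "freehand", 8: "traced"}
_IJ_RECT = 1


def read_imagej_roi(source: Union[bytes, str, Path], label: Optional[str] = None) -> Roi:
    """Parse a single ImageJ ``.roi`` file (or its bytes) into a :class:`Roi`."""
    if isinstance(source, (str, Path)):
        data = Path(source).read_bytes()
        if label is None:
            label = Path(source).stem
    else:
        data = source
        if label is None:
            label = "roi"
    if data[:4] != b"Iout":
        raise RoiError("not an ImageJ ROI file (missing 'Iout' magic)")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    if roi_type == _IJ_RECT:
        poly = np.array([[top, left], [top, right],
                         [bottom, right], [bottom, left]], dtype=float)
        return Roi(label=label, polygon=poly)
    if roi_type not in _IJ_POLYGON_TYPES:
        raise RoiError(f"unsupported ImageJ ROI type {roi_type}")
    (n,) = struct.unpack(">h", data[16:18])
    if n < 3:
        raise RoiError(f"ImageJ ROI has only {n} vertices")
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    return Roi(label=label, polygon=np.column_stack([ys, xs]))


def write_imagej_roi(roi: Roi) -> bytes:
    """Serialize a polygon :class:`Roi` as a minimal ImageJ ``.roi`` blob
    (round-trips through :func:`read_imagej_roi`)."""
    if roi.polygon is None:
        raise RoiError("only polygon ROIs can be written in ImageJ format")
    ys = np.round(roi.polygon[:, 0]).astype(int)
    xs = np.round(roi.polygon[:, 1]).astype(int)
    top, left = int(ys.min()), int(xs.min())
    bottom, right = int(ys.max()), int(xs.max())
    n = xs.size
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 228)    # format version
    header[6] = 0                              # polygon
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    body = (xs - left).astype(">i2").tobytes() + (ys - top).astype(">i2").tobytes()
    return bytes(header) + body


def read_imagej_zip(path: Union[str, Path], frame_shape: Tuple[int, int]) -> RoiSet:
    """Read an ImageJ ROI-set ``.zip`` archive into a :class:`RoiSet`."""
    rois = []
    with zipfile.ZipFile(str(path)) as zf:
        for name in sorted(zf.namelist()):
            if not name.lower().endswith(".roi"):
                continue
            rois.append(read_imagej_roi(zf.read(name), label=Path(name).stem))
    if not rois:
        raise RoiError(f"no .roi entries found in {path}")
    return RoiSet(rois=rois, frame_shape=frame_shape)


def read_roi_json(path: Union[str, Path], frame_shape: Optional[Tuple[int, int]] = None) -> RoiSet:
    """Read a JSON ROI list:
    ``{"frame_shape": [rows, cols], "rois": [{"label": ..., "polygon":
    [[row, col], ...]}, ...]}``."""
    with open(path) as fh:
        doc = json.load(fh)
    shape = tuple(doc.get("frame_shape") or frame_shape or ())
    if len(shape) != 2:
        raise RoiError("frame_shape missing from JSON and not supplied")
    rois = [Roi(label=str(r["label"]), polygon=np.asarray(r["polygon"], dtype=float))
            for r in doc["rois"]]
    return RoiSet(rois=rois, frame_shape=shape)


def write_roi_json(path: Union[str, Path], rois: RoiSet) -> None:
    doc = {
        "frame_shape": list(rois.frame_shape),
        "rois": [{"label": r.label, "polygon": np.asarray(r.polygon).tolist()}
                 for r in rois.rois],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
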