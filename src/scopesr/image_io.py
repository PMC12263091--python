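"""Reading, writing and decomposing n-dimensional grayscale TIFF stacks.

The carrier type is :class:`ImageStack`: a non-negative numeric array
with labelled axes drawn from ``{T, C, Z, Y, X}`` and a declared dynamic
range.  All pixel math elsewhere in the package runs on floating-point
values normalized to [0, 1]; integer bit depths exist only at the file
boundary.

Coordinate convention: 0-based indices, (row, col) = (Y, X), origin at
the top-left corner of the image.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_image", "write_image", "normalize", "to_frames"]

VALID_AXES = ("T", "C", "Z", "Y", "X")

#: Bit depth used when persisting floating-point stacks to TIFF.
FLOAT_STORAGE_BITS = 16


@dataclass
class ImageStack:
    """An n-dimensional grayscale image with labelled axes.

    Parameters
    ----------
    data
        Non-negative numeric array.
    axes
        One label per array dimension, drawn from ``{T, C, Z, Y, X}``;
        must contain ``Y`` and ``X`` exactly once each.
    value_range
        Declared dynamic range ``(lo, hi)``, e.g. ``(0, 255)`` for 8-bit
        data or ``(0.0, 1.0)`` for normalized data.
    """

    data: np.ndarray
    axes: tuple[str, ...]
    value_range: tuple[float, float]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.axes = tuple(self.axes)
        if self.data.size == 0:
            raise ValueError("empty image array")
        if len(self.axes) != self.data.ndim:
            raise ValueError(
                f"{len(self.axes)} axis labels for a {self.data.ndim}-D array")
        if len(set(self.axes)) != len(self.axes):
            raise ValueError(f"duplicate axis labels in {self.axes}")
        for ax in self.axes:
            if ax not in VALID_AXES:
                raise ValueError(f"unknown axis label {ax!r}")
        if "Y" not in self.axes or "X" not in self.axes:
            raise ValueError(f"axes {self.axes} must contain Y and X")
        lo, hi = self.value_range
        if not hi > lo:
            raise ValueError(f"degenerate value_range {self.value_range}")
        dmin, dmax = float(self.data.min()), float(self.data.max())
        if dmin < lo or dmax > hi:
            raise ValueError(
                f"data range [{dmin}, {dmax}] outside declared {self.value_range}")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return (self.data.shape[self.axes.index("Y")],
                self.data.shape[self.axes.index("X")])


def _default_axes(ndim: int) -> tuple[str, ...]:
    """Axis labels when TIFF metadata is silent: right-to-left X, Y, then
    T for the first leading axis (the common timelapse layout), with Z and
    C for any further leading dimensions."""
    if ndim < 2:
        raise ValueError("1-D arrays are not images")
    leading = {2: (), 3: ("T",), 4: ("T", "Z"), 5: ("T", "C", "Z")}.get(ndim)
    if leading is None:
        raise ValueError(f"cannot infer axes for a {ndim}-D array")
    return leading + ("Y", "X")


def _range_for_dtype(dtype: np.dtype) -> tuple[float, float]:
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        return (float(info.min), float(info.max))
    return (0.0, 1.0)


def read_image(path: str | Path, axes: str | None = None) -> ImageStack:
    """Read a grayscale TIFF into an :class:`ImageStack`.

    Axes are taken from TIFF metadata when present; otherwise they are
    assigned right-to-left as ``(..., Y, X)``.  ``axes`` overrides both.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        data = series.asarray()
        meta_axes = series.axes  # tifffile axis string, e.g. "YX", "TYX"
    if data.ndim >= 3 and data.shape[-1] in (3, 4) and meta_axes.endswith("S"):
        raise ValueError(f"color (RGB/RGBA) TIFF not supported: sample axis "
                         f"in {path.name}")
    if not np.issubdtype(data.dtype, np.integer) and \
            not np.issubdtype(data.dtype, np.floating):
        raise ValueError(f"unsupported sample format {data.dtype} in {path.name}")
    if axes is not None:
        labels = tuple(axes.upper())
    elif meta_axes and all(a in VALID_AXES for a in meta_axes) and \
            len(meta_axes) == data.ndim:
        labels = tuple(meta_axes)
    else:
        # tifffile pads unknown leading axes with Q/I; fall back to default
        labels = _default_axes(data.ndim)
    return ImageStack(data=data, axes=labels,
                      value_range=_range_for_dtype(data.dtype))


def write_image(stack: ImageStack, path: str | Path) -> None:
    """Write a stack to TIFF, losslessly for integer data.

    Floating-point stacks (declared range [0, 1]) are quantized to
    unsigned 16-bit; the round-trip error is bounded by 1/(2^16 - 1).
    """
    path = Path(path)
    data = stack.data
    lo, hi = stack.value_range
    if np.issubdtype(data.dtype, np.floating):
        if lo != 0.0 or hi != 1.0:
            raise ValueError("float stacks must declare value_range (0, 1)")
        scale = 2 ** FLOAT_STORAGE_BITS - 1
        data = np.round(np.clip(data, 0.0, 1.0) * scale).astype(np.uint16)
    else:
        dmin, dmax = float(data.min()), float(data.max())
        info = np.iinfo(data.dtype)
        if dmin < info.min or dmax > info.max:  # pragma: no cover - defensive
            raise ValueError("values outside representable range")
    tifffile.imwrite(path, data, photometric="minisblack",
                     metadata={"axes": "".join(stack.axes)})


def normalize(stack: ImageStack, mode: str = "to_unit",
              value_range: tuple[float, float] | None = None) -> ImageStack:
    """Linear rescaling between the declared range and the unit interval.

    ``to_unit`` maps ``stack.value_range`` onto [0, 1]; ``to_dtype_max``
    maps [0, 1] data onto ``value_range`` (the target integer scale).
    The two modes compose to the identity up to floating-point error.
    """
    lo, hi = stack.value_range
    if mode == "to_unit":
        data = (stack.data.astype(np.float64) - lo) / (hi - lo)
        return ImageStack(data=data, axes=stack.axes, value_range=(0.0, 1.0))
    if mode == "to_dtype_max":
        if value_range is None:
            raise ValueError("to_dtype_max requires the target value_range")
        tlo, thi = value_range
        if not thi > tlo:
            raise ValueError(f"degenerate target range {value_range}")
        unit = (stack.data.astype(np.float64) - lo) / (hi - lo)
        return ImageStack(data=unit * (thi - tlo) + tlo, axes=stack.axes,
                          value_range=value_range)
    raise ValueError(f"unknown normalize mode {mode!r}")


def to_frames(stack: ImageStack, frame_axes: set[str] | tuple[str, ...] = ()
              ) -> list[tuple[tuple[int, ...], np.ndarray]]:
    """Split a stack into 2-D (or lower-rank) frames along `frame_axes`.

    Returns one ``(frame_index, sub_image)`` entry per index combination
    over the frame axes, in row-major order of those axes (as they appear
    in ``stack.axes``).  Concatenating the frames reconstructs the stack.
    """
    frame_axes = set(frame_axes)
    if frame_axes & {"Y", "X"}:
        raise ValueError("frame_axes may not contain the spatial axes Y/X")
    unknown = frame_axes - set(stack.axes)
    if unknown:
        raise ValueError(f"frame_axes {sorted(unknown)} not present in stack")
    ordered = [ax for ax in stack.axes if ax in frame_axes]
    if not ordered:
        return [((), stack.data)]
    dims = [stack.data.shape[stack.axes.index(ax)] for ax in ordered]
    frames = []
    for idx in itertools.product(*(range(d) for d in dims)):
        sl = [slice(None)] * stack.data.ndim
        for ax, i in zip(ordered, idx):
            sl[stack.axes.index(ax)] = i
        frames.append((idx, stack.data[tuple(sl)]))
    return frames
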