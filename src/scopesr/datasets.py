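"""Datasets: tiling, leakage-free tile-level splits, and runtime
crappification.

A *tile* is a spatial window in a mosaic; a *frame* is one slice of the
non-spatial axes (time, depth, channel) at that tile.  Training and
validation sets are split by tile, never by frame, because frames of the
same tile can be nearly identical — splitting them apart would leak
training content into validation.

Training samples are crappified at access time with a fresh intensity
draw, so one HR tile yields a different LR image every epoch while the
HR target stays fixed.  Validation samples use the midpoint of the
intensity interval so the validation loss is comparable across epochs.
Benchmark samples are real HR/LR pairs loaded from disk; no crappifier
runs anywhere on that path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .crappifiers import CrappifierSpec, crappify
from .image_io import ImageStack, normalize, read_image, to_frames

logger = logging.getLogger(__name__)

__all__ = ["TileRecord", "DatasetSpec", "PairedSample", "enumerate_tiles",
           "split_by_tile", "TiledDataset", "stitch", "load_dir"]


@dataclass(frozen=True, order=True)
class TileRecord:
    """Address of one training/prediction unit within a source image."""

    source_id: str
    frame: int
    row: int
    col: int

    @property
    def tile_key(self) -> tuple[str, int, int]:
        """Identity of the spatial tile, shared by all its frames."""
        return (self.source_id, self.row, self.col)


@dataclass(frozen=True)
class DatasetSpec:
    """Configuration of a dataset: mode, tile geometry and split policy."""

    mode: str = "train"
    hr_size: int = 512
    scale: int = 4
    stride: int | None = None
    val_fraction: float = 0.0
    split_seed: int = 0
    crappifier: CrappifierSpec | None = None

    def __post_init__(self):
        if self.mode not in ("train", "predict", "benchmark"):
            raise ValueError(f"unknown dataset mode {self.mode!r}")
        if self.hr_size < 1 or self.scale < 1:
            raise ValueError("hr_size and scale must be positive")
        if self.hr_size % self.scale:
            raise ValueError(
                f"hr_size {self.hr_size} not divisible by scale {self.scale}")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError(
                f"val_fraction must lie in [0, 1), got {self.val_fraction}")
        if self.mode == "train" and self.crappifier is None:
            raise ValueError("train mode requires a crappifier")
        if self.mode == "benchmark" and self.crappifier is not None:
            raise ValueError("benchmark mode uses real pairs, no crappifier")

    @property
    def lr_size(self) -> int:
        return self.hr_size // self.scale

    @property
    def effective_stride(self) -> int:
        return self.stride if self.stride is not None else self.hr_size


@dataclass
class PairedSample:
    """One sample: LR input, optional HR target, and its tile address."""

    lr: np.ndarray
    record: TileRecord
    hr: np.ndarray | None = None
    intensity_used: float | None = None


def enumerate_tiles(stack: ImageStack, hr_size: int, stride: int,
                    frame_axes: set[str] | tuple[str, ...] = (),
                    source_id: str = "image") -> list[TileRecord]:
    """Row-major grid of tile anchors at multiples of ``stride``.

    Only tiles fitting fully inside the image are emitted; remainder
    pixels beyond the last full tile are dropped (with a logged count).
    One record is produced per (tile, frame) combination.
    """
    h, w = stack.spatial_shape
    if hr_size > h or hr_size > w:
        dim = "Y" if hr_size > h else "X"
        raise ValueError(
            f"tile size {hr_size} exceeds image extent along {dim} "
            f"({h if dim == 'Y' else w} px)")
    n_rows = (h - hr_size) // stride + 1
    n_cols = (w - hr_size) // stride + 1
    rem_y = h - ((n_rows - 1) * stride + hr_size)
    rem_x = w - ((n_cols - 1) * stride + hr_size)
    if rem_y or rem_x:
        logger.info("dropping %d remainder rows and %d remainder cols of %s",
                    rem_y, rem_x, source_id)
    n_frames = len(to_frames(stack, frame_axes))
    records = [TileRecord(source_id=source_id, frame=f, row=r, col=c)
               for f in range(n_frames)
               for r in range(n_rows)
               for c in range(n_cols)]
    return sorted(records)


def split_by_tile(records: list[TileRecord], val_fraction: float,
                  split_seed: int) -> tuple[list[TileRecord], list[TileRecord]]:
    """Random train/validation split at tile granularity.

    The unique tile keys are shuffled with ``split_seed`` and
    ``ceil(val_fraction * n_tiles)`` tiles go to validation; every frame
    of a tile lands on the same side, so near-duplicate frames can never
    straddle the split.
    """
    if not 0.0 <= val_fraction < 1.0:
        raise ValueError(f"val_fraction must lie in [0, 1), got {val_fraction}")
    keys = sorted({r.tile_key for r in records})
    rng = np.random.default_rng(split_seed)
    rng.shuffle(keys)
    n_val = math.ceil(val_fraction * len(keys)) if val_fraction > 0 else 0
    val_keys = set(map(tuple, keys[:n_val]))
    train = [r for r in records if r.tile_key not in val_keys]
    val = [r for r in records if r.tile_key in val_keys]
    return train, val


def load_dir(directory: str | Path) -> dict[str, ImageStack]:
    """Load every TIFF in a directory, keyed by basename (without suffix),
    normalized to the [0, 1] internal scale."""
    directory = Path(directory)
    stacks = {}
    for path in sorted(directory.glob("*.tif*")):
        stacks[path.stem] = normalize(read_image(path), "to_unit")
    if not stacks:
        raise FileNotFoundError(f"no TIFF files found in {directory}")
    return stacks


class TiledDataset:
    """Indexed access to tiles of one or more image stacks.

    Parameters
    ----------
    spec
        Dataset configuration (mode, geometry, crappifier, split policy).
    hr_stacks
        Mapping source_id -> HR ImageStack ([0, 1] scale).  Required for
        train and benchmark modes.
    lr_stacks
        Mapping source_id -> LR ImageStack.  Required for predict and
        benchmark modes; benchmark pairs files by identical basename.
    frame_axes
        Non-spatial axes to unroll into frames.
    """

    def __init__(self, spec: DatasetSpec,
                 hr_stacks: dict[str, ImageStack] | None = None,
                 lr_stacks: dict[str, ImageStack] | None = None,
                 frame_axes: set[str] | tuple[str, ...] = ()):
        self.spec = spec
        self.hr_stacks = hr_stacks or {}
        self.lr_stacks = lr_stacks or {}
        self.frame_axes = tuple(frame_axes)
        if spec.mode in ("train", "benchmark") and not self.hr_stacks:
            raise ValueError(f"{spec.mode} mode requires HR images")
        if spec.mode in ("predict", "benchmark") and not self.lr_stacks:
            raise ValueError(f"{spec.mode} mode requires LR images")
        if spec.mode == "benchmark":
            self._check_pairing()
        self.records = self._enumerate_all()
        self._frames: dict[tuple[str, str], list[np.ndarray]] = {}

    # -- record enumeration ---------------------------------------------------

    def _enumerate_all(self) -> list[TileRecord]:
        records: list[TileRecord] = []
        if self.spec.mode == "predict":
            stride = self.spec.effective_stride // self.spec.scale
            for sid, stack in sorted(self.lr_stacks.items()):
                records += enumerate_tiles(stack, self.spec.lr_size, stride,
                                           self.frame_axes, source_id=sid)
        else:
            for sid, stack in sorted(self.hr_stacks.items()):
                records += enumerate_tiles(stack, self.spec.hr_size,
                                           self.spec.effective_stride,
                                           self.frame_axes, source_id=sid)
        return sorted(records)

    def _check_pairing(self) -> None:
        for sid, hr in sorted(self.hr_stacks.items()):
            if sid not in self.lr_stacks:
                raise ValueError(f"HR image {sid!r} has no LR counterpart")
            hy, hx = hr.spatial_shape
            ly, lx = self.lr_stacks[sid].spatial_shape
            if hy != ly * self.spec.scale or hx != lx * self.spec.scale:
                raise ValueError(
                    f"pair {sid!r}: HR {hy}x{hx} is not {self.spec.scale}x "
                    f"the LR {ly}x{lx}")
        for sid in self.lr_stacks:
            if sid not in self.hr_stacks:
                raise ValueError(f"LR image {sid!r} has no HR counterpart")

    def split(self) -> tuple[list[TileRecord], list[TileRecord]]:
        return split_by_tile(self.records, self.spec.val_fraction,
                             self.spec.split_seed)

    # -- frame extraction -----------------------------------------------------

    def _frame(self, kind: str, source_id: str, frame: int) -> np.ndarray:
        key = (kind, source_id)
        if key not in self._frames:
            stacks = self.hr_stacks if kind == "hr" else self.lr_stacks
            if source_id not in stacks:
                raise KeyError(f"unknown source_id {source_id!r}")
            self._frames[key] = [f for _, f in
                                 to_frames(stacks[source_id], self.frame_axes)]
        frames = self._frames[key]
        if not 0 <= frame < len(frames):
            raise IndexError(f"frame {frame} out of range for {source_id!r}")
        return frames[frame]

    def _tile(self, kind: str, record: TileRecord, size: int,
              stride: int) -> np.ndarray:
        img = self._frame(kind, record.source_id, record.frame)
        y, x = record.row * stride, record.col * stride
        if y + size > img.shape[0] or x + size > img.shape[1]:
            raise IndexError(f"record {record} outside the tile grid")
        return np.asarray(img[y:y + size, x:x + size], dtype=np.float64)

    # -- sample accessors -----------------------------------------------------

    def get_train_sample(self, record: TileRecord,
                         rng: np.random.Generator,
                         validation: bool = False) -> PairedSample:
        """HR tile plus a freshly crappified LR input.

        Every call draws a new noise intensity and noise realization from
        ``rng``, so the same record yields distinct LR images across
        epochs while the HR target is fixed.  Validation samples pin the
        intensity to the interval midpoint.
        """
        if self.spec.mode != "train":
            raise ValueError(f"get_train_sample in {self.spec.mode!r} mode")
        hr = self._tile("hr", record, self.spec.hr_size,
                        self.spec.effective_stride)
        intensity = self.spec.crappifier.midpoint_intensity if validation else None
        result = crappify(hr, self.spec.crappifier, self.spec.scale, rng,
                          intensity=intensity)
        return PairedSample(lr=result.lr_image, hr=hr, record=record,
                            intensity_used=result.intensity_used)

    def get_predict_sample(self, record: TileRecord) -> PairedSample:
        """LR tile only; ``hr`` is None by contract in predict mode."""
        if self.spec.mode != "predict":
            raise ValueError(f"get_predict_sample in {self.spec.mode!r} mode")
        lr = self._tile("lr", record, self.spec.lr_size,
                        self.spec.effective_stride // self.spec.scale)
        return PairedSample(lr=lr, hr=None, record=record)

    def get_benchmark_pair(self, record: TileRecord) -> PairedSample:
        """Real HR/LR pair from disk; no crappification on this path."""
        if self.spec.mode != "benchmark":
            raise ValueError(f"get_benchmark_pair in {self.spec.mode!r} mode")
        hr = self._tile("hr", record, self.spec.hr_size,
                        self.spec.effective_stride)
        lr = self._tile("lr", record, self.spec.lr_size,
                        self.spec.effective_stride // self.spec.scale)
        return PairedSample(lr=lr, hr=hr, record=record)

    def __len__(self) -> int:
        return len(self.records)


def stitch(tiles: list[tuple[TileRecord, np.ndarray]],
           out_shape: tuple[int, int], stride: int) -> np.ndarray:
    """Reassemble tiles into a full image (inverse of tile enumeration).

    Anchors are ``(row * stride, col * stride)``.  Overlapping tiles are
    averaged per pixel.  Every pixel of ``out_shape`` must be covered by
    at least one tile, else a coverage error is raised.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    acc = np.zeros(out_shape, dtype=np.float64)
    weight = np.zeros(out_shape, dtype=np.float64)
    for record, tile in tiles:
        tile = np.asarray(tile, dtype=np.float64)
        y, x = record.row * stride, record.col * stride
        th, tw = tile.shape
        if y + th > out_shape[0] or x + tw > out_shape[1]:
            raise ValueError(f"tile {record} extends beyond {out_shape}")
        acc[y:y + th, x:x + tw] += tile
        weight[y:y + th, x:x + tw] += 1.0
    if (weight == 0).any():
        n_missing = int((weight == 0).sum())
        raise ValueError(
            f"incomplete tiling: {n_missing} of {acc.size} pixels uncovered")
    return acc / weight
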