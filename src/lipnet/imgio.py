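"""Multi-channel image data model and file I/O.

Images are dictionaries of named 2-D grayscale planes of identical shape,
stored as unsigned 8- or 16-bit integers.  On disk they are multi-page
grayscale TIFFs, one page per channel in declared order; quantification
never passes through lossy RGB composites.  Binary masks travel as 8-bit
0/255 TIFFs.  All coordinates in the package are (row, col), 0-based,
origin at the top-left pixel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import (
    ChannelCountMismatchError,
    InvalidImageError,
    UnknownFormatError,
    UnsupportedSampleFormatError,
)

_ALLOWED_DTYPES = (np.uint8, np.uint16)


@dataclass
class MultiChannelImage:
    """Named 2-D intensity planes sharing one shape.

    Parameters
    ----------
    channels:
        Ordered mapping from channel name to a 2-D ``uint8``/``uint16``
        array.  Order is preserved through I/O.
    pixel_size_um:
        Optional physical pixel spacing in micrometers.  No default is
        assumed; metrics stay in pixel units unless this is provided.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise InvalidImageError("image must contain at least one channel")
        shapes = set()
        for name, plane in self.channels.items():
            if not isinstance(name, str) or not name:
                raise InvalidImageError(f"invalid channel name: {name!r}")
            plane = np.asarray(plane)
            if plane.ndim != 2:
                raise InvalidImageError(f"channel {name!r} is not 2-D")
            if plane.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
                raise UnsupportedSampleFormatError(
                    f"channel {name!r} has dtype {plane.dtype}; expected uint8 or uint16"
                )
            self.channels[name] = plane
            shapes.add(plane.shape)
        if len(shapes) != 1:
            raise InvalidImageError(f"channel shapes differ: {sorted(shapes)}")

    @property
    def height(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def plane(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not in image (have {self.channel_names})"
            )
        return self.channels[name]


@dataclass
class MetricsTable:
    """Ordered list of (name, scope, value) metric rows.

    ``value`` may be ``None`` for explicitly undefined metrics (e.g. a
    correlation over a constant region); ``None`` survives serialization as
    a JSON ``null`` / empty CSV cell rather than drifting into ``NaN`` text.
    """

    records: list[tuple[str, str, float | None]] = field(default_factory=list)

    def add(self, name: str, scope: str, value: float | None) -> None:
        if any(n == name and s == scope for n, s, _ in self.records):
            raise ValueError(f"duplicate metric {name!r} in scope {scope!r}")
        if value is not None and not math.isfinite(value):
            raise ValueError(
                f"metric {name!r} is non-finite; use None to flag undefined values"
            )
        self.records.append((name, scope, None if value is None else float(value)))


def read_image(path: str | Path, channel_names: list[str]) -> MultiChannelImage:
    """Read a multi-page grayscale TIFF into a :class:`MultiChannelImage`.

    The page count must equal ``len(channel_names)``; pages are assigned to
    names in order and the bit depth is preserved exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    data = tifffile.imread(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise UnsupportedSampleFormatError(
            f"{path}: expected 2-D pages, got array of shape {data.shape}"
        )
    if data.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise UnsupportedSampleFormatError(
            f"{path}: dtype {data.dtype} is not uint8/uint16"
        )
    if len(channel_names) != data.shape[0]:
        raise ChannelCountMismatchError(
            f"{path}: {data.shape[0]} pages but {len(channel_names)} channel names"
        )
    return MultiChannelImage(
        channels={name: data[i].copy() for i, name in enumerate(channel_names)}
    )


def write_image(img: MultiChannelImage, path: str | Path) -> None:
    """Write one grayscale TIFF page per channel, order and bit depth preserved."""
    path = Path(path)
    stack = np.stack([img.channels[name] for name in img.channel_names])
    # one grayscale page per channel; never let 3-page stacks masquerade as RGB
    tifffile.imwrite(path, stack, photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-page 0/255 TIFF as a boolean mask."""
    img = read_image(path, ["mask"])
    return img.channels["mask"] > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask, dtype=bool)
    tifffile.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def validate_label_map(plane: np.ndarray) -> int:
    """Check the 1..n gap-free labeling convention; return n_labels."""
    plane = np.asarray(plane)
    if plane.ndim != 2 or not np.issubdtype(plane.dtype, np.integer):
        raise InvalidImageError("label map must be a 2-D integer array")
    if plane.min() < 0:
        raise InvalidImageError("label map contains negative labels")
    labels = np.unique(plane)
    labels = labels[labels > 0]
    n = int(labels.size)
    if n and not np.array_equal(labels, np.arange(1, n + 1)):
        raise InvalidImageError("labels must be 1..n with no gaps")
    return n


def write_metrics(table: MetricsTable, path: str | Path, format: str = "csv") -> None:
    """Serialize a metrics table to CSV or JSON.

    CSV columns are ``scope,name,value`` with row order preserved.  JSON is a
    list of ``{"scope": ..., "metrics": {name: value-or-null}}`` objects, one
    per scope, in first-appearance order.
    """
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(table.records, columns=["name", "scope", "value"])
        df = df[["scope", "name", "value"]]
        df.to_csv(path, index=False)
    elif format == "json":
        scopes: dict[str, dict[str, float | None]] = {}
        for name, scope, value in table.records:
            scopes.setdefault(scope, {})[name] = value
        payload = [{"scope": s, "metrics": m} for s, m in scopes.items()]
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise UnknownFormatError(f"unknown metrics format: {format!r}")


def read_metrics(path: str | Path, format: str = "csv") -> MetricsTable:
    """Inverse of :func:`write_metrics` (used for round-trip verification)."""
    path = Path(path)
    table = MetricsTable()
    if format == "csv":
        df = pd.read_csv(path)
        for _, row in df.iterrows():
            v = row["value"]
            table.add(row["name"], row["scope"], None if pd.isna(v) else float(v))
    elif format == "json":
        for block in json.loads(path.read_text()):
            for name, value in block["metrics"].items():
                table.add(name, block["scope"], value)
    else:
        raise UnknownFormatError(f"unknown metrics format: {format!r}")
    return table
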