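"""Rasterizing averaged ERP segments into waveform-plot images.

A z-scored segment X(t), t = 0..L-1, is drawn as a binary image::

    I(z1, z2) = 255  if (z1, z2) = (floor(gamma_w * t), floor(gamma_h * X(t) + Z))
              = 0    otherwise

with zero line Z = Hy/2, image height Hy = floor(2 * gamma_h * |max X - min X|)
and width Wx = gamma_w * L.  The origin is the top-left corner and z2 grows
downward, so the trace is drawn exactly as printed on screen.  Consecutive
sample points are joined with Bresenham's line algorithm so the trace forms a
single connected stroke.  For a signal symmetric about zero the construction
leaves blank margins of 25% of the image height above and below the trace.

The binary plot is then rescaled with bilinear interpolation to a square
150 x 150 grayscale image (interpolation introduces intermediate values; no
re-thresholding is applied), and the eight per-channel plots of one segment
may be bundled into a single 150 x 150 x 8 multichannel image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .erp import AveragedERP
from .recording import ValidationError

DEFAULT_GAMMA_W = 2
DEFAULT_GAMMA_H = 30
DEFAULT_IMAGE_SIZE = 150
WHITE = 255


@dataclass
class WaveformImage:
    """A plotted signal trace: white (255) stroke on a black (0) background."""

    pixels: np.ndarray  # (Hy, Wx); {0,255} before rescale, grayscale after
    gamma_w: int
    gamma_h: int
    zero_line: float  # Z = Hy / 2, in pixel rows from the top
    channel: str | int | None = None
    rescaled: bool = False

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class MultichannelImage:
    """Eight rescaled per-channel plots of one segment, stacked depth-wise."""

    pixels: np.ndarray  # (size, size, 8)
    channel_labels: tuple[str, ...]


def bresenham_line(
    p1: tuple[int, int], p2: tuple[int, int]
) -> list[tuple[int, int]]:
    """Integer pixel coordinates of the Bresenham line from p1 to p2, inclusive."""
    x0, y0 = (int(v) for v in p1)
    x1, y1 = (int(v) for v in p2)
    dx = abs(x1 - x0)
    dy = -abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx + dy
    points = []
    while True:
        points.append((x0, y0))
        if x0 == x1 and y0 == y1:
            return points
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x0 += sx
        if e2 <= dx:
            err += dx
            y0 += sy


def _draw_segment(img: np.ndarray, x0: int, y0: int, x1: int, y1: int) -> None:
    """Vectorized Bresenham segment: identical pixels to :func:`bresenham_line`.

    Uses the closed-form midpoint expression for the minor axis, which
    reproduces the incremental error recurrence exactly (verified
    exhaustively over all octants in the test suite).
    """
    dx, dy = abs(x1 - x0), abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    if dx >= dy:
        i = np.arange(dx + 1)
        xs = x0 + sx * i
        ys = y0 + sy * ((2 * i * dy + dx) // (2 * dx)) if dx else np.array([y0])
    else:
        i = np.arange(dy + 1)
        ys = y0 + sy * i
        xs = x0 + sx * ((2 * i * dx + dy) // (2 * dy))
    img[ys, xs] = WHITE


def bresenham_connect(
    image: np.ndarray, p1: tuple[int, int], p2: tuple[int, int]
) -> np.ndarray:
    """Set every pixel on the Bresenham line from p1 to p2 to white, in place.

    Points are (x, y) = (column, row); both must lie inside the image.
    """
    h, w = image.shape
    for x, y in (p1, p2):
        if not (0 <= x < w and 0 <= y < h):
            raise ValidationError(
                f"point ({x}, {y}) outside image bounds {w}x{h}"
            )
    for x, y in bresenham_line(p1, p2):
        image[y, x] = WHITE
    return image


def render_plot(
    signal: np.ndarray | AveragedERP,
    gamma_w: int = DEFAULT_GAMMA_W,
    gamma_h: int = DEFAULT_GAMMA_H,
    channel: str | int | None = None,
) -> WaveformImage:
    """Rasterize one z-scored channel into its binary waveform plot.

    ``signal`` is a 1-D array (or a single-channel :class:`AveragedERP`).
    """
    if isinstance(signal, AveragedERP):
        if signal.n_channels != 1:
            raise ValidationError(
                "render_plot draws one channel; use render_channels for several"
            )
        x = np.asarray(signal.data[0], dtype=float)
    else:
        x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("signal must be 1-D with at least 2 samples")
    if gamma_w < 1 or gamma_h < 1:
        raise ValidationError("scale factors gamma_w, gamma_h must be >= 1")
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValidationError("flat signal cannot be plotted (image height 0)")
    L = x.size
    Hy = math.floor(2 * gamma_h * (hi - lo))
    Wx = gamma_w * L
    Z = Hy / 2.0
    img = np.zeros((Hy, Wx), dtype=np.uint8)
    cols = np.floor(gamma_w * np.arange(L)).astype(int)
    rows = np.floor(gamma_h * x + Z).astype(int)
    np.clip(rows, 0, Hy - 1, out=rows)
    img[rows[0], cols[0]] = WHITE
    for t in range(1, L):
        _draw_segment(img, cols[t - 1], rows[t - 1], cols[t], rows[t])
    return WaveformImage(
        pixels=img, gamma_w=gamma_w, gamma_h=gamma_h, zero_line=Z, channel=channel
    )


def rescale_image(
    img: WaveformImage, size: int = DEFAULT_IMAGE_SIZE
) -> WaveformImage:
    """Bilinear resample to a square ``size`` x ``size`` grayscale image."""
    if img.pixels.size == 0:
        raise ValidationError("cannot rescale an empty image")
    out = _sk_resize(
        img.pixels.astype(np.float64),
        (size, size),
        order=1,  # bilinear
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    out = np.clip(out, 0.0, 255.0).astype(np.float32)
    return replace(img, pixels=out, rescaled=True)


def render_channels(
    erp: AveragedERP,
    gamma_w: int = DEFAULT_GAMMA_W,
    gamma_h: int = DEFAULT_GAMMA_H,
    size: int = DEFAULT_IMAGE_SIZE,
) -> list[WaveformImage]:
    """Rescaled waveform plot of every channel of an averaged segment."""
    labels = (
        list(erp.channel_labels)
        if erp.channel_labels is not None
        else list(range(erp.n_channels))
    )
    return [
        rescale_image(render_plot(erp.data[c], gamma_w, gamma_h, channel=labels[c]), size)
        for c in range(erp.n_channels)
    ]


def bundle_channels(images: Sequence[WaveformImage]) -> MultichannelImage:
    """Stack 8 rescaled per-channel plots into one multichannel image.

    Plane order follows the input order, which must be the recording montage
    order; each channel acts as an independent color plane for the CNN.
    """
    if len(images) != 8:
        raise ValidationError(f"expected 8 channel images, got {len(images)}")
    shapes = {im.pixels.shape for im in images}
    if len(shapes) != 1:
        raise ValidationError(f"channel images have mismatched sizes: {sorted(shapes)}")
    if not all(im.rescaled for im in images):
        raise ValidationError("bundle_channels requires rescaled (square) images")
    stack = np.stack([im.pixels for im in images], axis=-1)
    labels = tuple(str(im.channel) for im in images)
    return MultichannelImage(pixels=stack, channel_labels=labels)


def save_png(img: WaveformImage, path) -> None:
    """Write a plot as an 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(np.round(img.pixels).astype(np.uint8), mode="L").save(path)
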