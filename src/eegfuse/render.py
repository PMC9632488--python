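"""Multi-channel fusion (MCF): rasterize a segment into one fixed-size RGB image.

Each channel of a segment is drawn as a line plot inside its own horizontal
band (bands stacked top-to-bottom in channel order), producing the fused
"EEG visualization" image the CNN consumes.  The rasterizer is a
self-contained integer polyline renderer (Bresenham) rather than a plotting
toolkit: plot-library output depends on DPI, fonts and library version,
whereas classifier inputs must be bit-identical across runs and platforms.

Conventions (all deterministic):

* row 0 is the top of the image; larger signal values map to smaller row
  indices (standard plot orientation);
* each channel is min-max scaled to its band (per segment); a constant
  channel draws at the band midline;
* the X samples are mapped to the image width by linear index scaling and
  consecutive points are connected with 1-px (configurable) dark lines on a
  light background, replicated across the 3 RGB planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from eegfuse.clipping import Segment, round_half_up
from eegfuse.types import MultichannelRecord


@dataclass(frozen=True)
class RenderConfig:
    """Rasterization parameters.

    ``height`` is divided into ``n_channels`` equal bands of
    ``floor(height / n_channels)`` rows; the last band absorbs the remainder.
    ``normalization`` is "per-channel" (each channel min-max scaled to its own
    band; amplitude-invariant) or "global" (one min-max over all channels of
    the segment; preserves relative channel amplitudes).
    """

    width: int = 224
    height: int = 224
    layout: str = "stacked"
    normalization: str = "per-channel"
    line_value: int = 0
    background_value: int = 255
    line_thickness: int = 1

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("width and height must be >= 8")
        if self.layout != "stacked":
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.normalization not in ("per-channel", "global"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for v in (self.line_value, self.background_value):
            if not 0 <= v <= 255:
                raise ValueError("intensities must be in [0, 255]")
        if self.line_thickness < 1:
            raise ValueError("line_thickness must be >= 1")


@dataclass
class ImageSample:
    """Rendered H x W x 3 uint8 image with its label and provenance."""

    pixels: np.ndarray
    label: int
    provenance: tuple[str, int, int]  # (subject_id, part, start)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")

    @property
    def subject_id(self) -> str:
        return self.provenance[0]


def _draw_line(canvas: np.ndarray, x0: int, y0: int, x1: int, y1: int, value: int) -> None:
    """Bresenham line on a 2-D canvas (in place). Endpoints inclusive."""
    if x0 == x1:  # vertical runs dominate when X >> width
        lo, hi = (y0, y1) if y0 <= y1 else (y1, y0)
        canvas[lo : hi + 1, x0] = value
        return
    dx = abs(x1 - x0)
    dy = -abs(y1 - y0)
    sx = 1 if x0 < x1 else -1
    sy = 1 if y0 < y1 else -1
    err = dx + dy
    x, y = x0, y0
    while True:
        canvas[y, x] = value
        if x == x1 and y == y1:
            break
        e2 = 2 * err
        if e2 >= dy:
            err += dy
            x += sx
        if e2 <= dx:
            err += dx
            y += sy


def _band_rows(values: np.ndarray, band_top: int, band_height: int) -> np.ndarray:
    """Map normalized values in [0, 1] to row indices inside a band."""
    rows = band_top + (band_height - 1) - np.floor(values * (band_height - 1) + 0.5).astype(int)
    return np.clip(rows, band_top, band_top + band_height - 1)


def band_extents(height: int, n_channels: int) -> list[tuple[int, int]]:
    """(top_row, band_height) per channel; last band absorbs the remainder."""
    base = height // n_channels
    extents = [(c * base, base) for c in range(n_channels)]
    top, h = extents[-1]
    extents[-1] = (top, height - top)
    return extents


def render_image(
    segment_data: np.ndarray,
    config: RenderConfig = RenderConfig(),
    label: int = 0,
    provenance: tuple[str, int, int] = ("", 1, 1),
) -> ImageSample:
    """Rasterize a (n_channels x X) segment into one image.

    Pure function of ``(segment_data, config)``: identical inputs yield
    bit-identical pixel buffers.
    """
    data = np.asarray(segment_data, dtype=np.float64)
    if data.ndim == 1:
        data = data[None, :]
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"segment data must be (n_channels, X>=2), got {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError("segment data contains NaN or infinite values")
    n_channels, n_points = data.shape
    if n_channels < 1 or n_channels > config.height:
        raise ValueError(f"{n_channels} channels cannot fit in height {config.height}")

    if config.normalization == "global":
        gmin, gmax = data.min(), data.max()

    canvas = np.full((config.height, config.width), config.background_value, dtype=np.uint8)
    cols = np.floor(np.arange(n_points) * (config.width - 1) / (n_points - 1) + 0.5).astype(int)

    for ch, (band_top, band_h) in enumerate(band_extents(config.height, n_channels)):
        if config.normalization == "per-channel":
            lo, hi = data[ch].min(), data[ch].max()
        else:
            lo, hi = gmin, gmax
        if hi > lo:
            norm = (data[ch] - lo) / (hi - lo)
        else:
            norm = np.full(n_points, 0.5)  # constant channel -> band midline
        rows = _band_rows(norm, band_top, band_h)
        # thickness extends downward, clipped to the band
        for t in range(config.line_thickness):
            rows_t = np.minimum(rows + t, band_top + band_h - 1)
            for i in range(n_points - 1):
                _draw_line(
                    canvas, cols[i], rows_t[i], cols[i + 1], rows_t[i + 1], config.line_value
                )

    pixels = np.repeat(canvas[:, :, None], 3, axis=2)
    return ImageSample(pixels=pixels, label=label, provenance=provenance)


def render_dataset(
    records: list[MultichannelRecord],
    segments: list[Segment],
    config: RenderConfig = RenderConfig(),
    channel_subset: list[str] | None = None,
) -> list[ImageSample]:
    """Render one image per segment, optionally restricted to a channel subset.

    ``channel_subset`` (ordered) supports the 1/2/3-channel fusion comparison:
    fewer channels mean fewer, taller bands per image.
    """
    if channel_subset is not None and len(channel_subset) == 0:
        raise ValueError("channel_subset must not be empty")
    by_id = {}
    for rec in records:
        by_id[rec.subject_id] = (
            rec if channel_subset is None else rec.channel_subset(channel_subset)
        )
    images = []
    for seg in segments:
        if seg.record_ref not in by_id:
            raise KeyError(f"segment references unknown record {seg.record_ref!r}")
        rec = by_id[seg.record_ref]
        images.append(
            render_image(
                seg.slice(rec),
                config,
                label=seg.label,
                provenance=(seg.record_ref, seg.part, seg.start),
            )
        )
    return images
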