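"""Coordinate conventions shared by all modules.

Image coordinates are center-origin, x rightward, y upward, expressed in
percent of the stimulus span (the full frame width is 100% of span; by
convention 100% of span corresponds to 8.4 degrees of visual angle).
Pixel grids are 0-based row-major with row 0 at the top.  These helpers are
the single authority for converting between the two frames.
"""

from __future__ import annotations

import numpy as np

#: Visual span represented by a full frame, in degrees.
DEFAULT_SPAN_DEGREES = 8.4


def pixel_centers(resolution: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (x, y) coordinates of pixel centers in % of span.

    Both outputs have shape ``(resolution, resolution)`` and are indexed
    ``[row, col]``.  x increases with column index, y decreases with row
    index (row 0 is the top of the frame).
    """
    step = 100.0 / resolution
    cols = np.arange(resolution) * step + step / 2.0 - 50.0
    rows = 50.0 - (np.arange(resolution) * step + step / 2.0)
    x = np.broadcast_to(cols[None, :], (resolution, resolution)).copy()
    y = np.broadcast_to(rows[:, None], (resolution, resolution)).copy()
    return x, y


def percent_to_pixel(x: float, y: float, resolution: int) -> tuple[float, float]:
    """Convert center-origin %-of-span coordinates to fractional (row, col)."""
    step = 100.0 / resolution
    col = (x + 50.0) / step - 0.5
    row = (50.0 - y) / step - 0.5
    return row, col


def pixel_to_percent(row: float, col: float, resolution: int) -> tuple[float, float]:
    """Convert fractional (row, col) pixel coordinates to %-of-span (x, y)."""
    step = 100.0 / resolution
    x = (col + 0.5) * step - 50.0
    y = 50.0 - (row + 0.5) * step
    return x, y


def percent_to_degrees(value: float | np.ndarray,
                       span_degrees: float = DEFAULT_SPAN_DEGREES):
    """Convert a length in % of span to degrees of visual angle."""
    return np.asarray(value) / 100.0 * span_degrees
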