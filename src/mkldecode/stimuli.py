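"""Stimulus picture metrics and threat-rating aggregation.

Standardisation metrics for visual stimuli, so threat and neutral
picture sets can be matched on low-level physical properties:

* brightness — the mean RGB value of each pixel, averaged over pixels;
* contrast — the standard deviation, across image columns, of each
  column's mean RGB value;
* spatial frequency — the median FFT power computed for each row and
  each column (zero-frequency term excluded), averaged.

Plus the behavioural aggregate: the threat-perception index, the sum of
four 1-9 ratings (threat magnitude, proximity, inescapability,
impossibility of hiding), ranging over 4-36.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "brightness",
    "contrast",
    "spatial_frequency",
    "threat_perception_index",
    "metrics_table",
    "load_image",
]


def _as_rgb(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an RGB image (H x W x 3)")
    if arr.size == 0:
        raise ValueError("empty image")
    return arr


def _gray(image: np.ndarray) -> np.ndarray:
    """Per-pixel mean of the three channels."""
    return _as_rgb(image).mean(axis=2)


def brightness(image: np.ndarray) -> float:
    """Mean RGB value per pixel, averaged across all pixels (0-255)."""
    return float(_gray(image).mean())


def contrast(image: np.ndarray) -> float:
    """SD across columns of the per-column mean RGB value.

    Sample standard deviation (ddof = 1), as returned by the usual
    ``std`` of column means.
    """
    g = _gray(image)
    if g.shape[1] < 2:
        raise ValueError("contrast needs at least two columns")
    col_means = g.mean(axis=0)
    return float(col_means.std(ddof=1))


def spatial_frequency(image: np.ndarray) -> float:
    """Median non-DC FFT power per row and per column, averaged.

    For every row the power spectrum |FFT|^2 is computed and its median
    taken over the non-zero frequencies; row medians are averaged, the
    same is done column-wise, and the two averages are averaged.  The
    DC term is excluded so the metric is invariant to constant offsets.
    """
    g = _gray(image)
    if g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("spatial frequency needs at least 2 rows and columns")

    def _median_power(lines: np.ndarray) -> float:
        power = np.abs(np.fft.rfft(lines, axis=1)) ** 2
        return float(np.median(power[:, 1:], axis=1).mean())

    return 0.5 * (_median_power(g) + _median_power(g.T))


def threat_perception_index(ratings) -> int:
    """Sum of the four 1-9 threat-dimension ratings (index in [4, 36])."""
    vals = [int(r) for r in ratings]
    if len(vals) != 4:
        raise ValueError("expected exactly four ratings")
    if any(r < 1 or r > 9 for r in vals):
        raise ValueError("each rating must lie in [1, 9]")
    return sum(vals)


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG picture as an RGB array."""
    from PIL import Image

    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def metrics_table(images: dict[str, np.ndarray]) -> pd.DataFrame:
    """Picture-metric table (image_id, brightness, contrast,
    spatial_frequency), one row per picture."""
    rows = [{"image_id": image_id,
             "brightness": brightness(img),
             "contrast": contrast(img),
             "spatial_frequency": spatial_frequency(img)}
            for image_id, img in images.items()]
    return pd.DataFrame(rows)
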