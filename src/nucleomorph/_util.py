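"""Small numeric helpers shared across the pipeline."""

from __future__ import annotations

import numpy as np


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero.

    Used for every pixel-dimension computation so that output rasters are
    bit-reproducible across platforms (``round`` uses banker's rounding).
    """
    if x >= 0:
        return int(np.floor(x + 0.5))
    return int(np.ceil(x - 0.5))


def gaussian_kernel(n: int = 5, sigma: float = 10.0) -> np.ndarray:
    """Normalized n-by-n Gaussian kernel.

    With sigma much larger than n the kernel is nearly uniform, i.e. a mean
    filter over the n x n window; that is the smoothing used on masks here.
    """
    half = (n - 1) / 2.0
    ax = np.arange(n) - half
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight bounding box (r0, c0, r1, c1), half-open, of a nonempty mask."""
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    return int(r0), int(c0), int(r1) + 1, int(c1) + 1


def crop_to_bbox(mask: np.ndarray) -> np.ndarray:
    r0, c0, r1, c1 = tight_bbox(mask)
    return mask[r0:r1, c0:c1]
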