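"""Boundary extraction from binary masks.

Traces the ordered boundary-pixel loop of the largest connected
foreground component with Moore-neighbor tracing, and canonicalizes the
traversal direction to counterclockwise so that downstream Fourier
coefficients have a fixed handedness.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage import measure

from .efd import ContourSequence

logger = logging.getLogger(__name__)

__all__ = ["NoObjectFoundError", "trace_contour"]


class NoObjectFoundError(ValueError):
    """Raised when a mask has no foreground component of sufficient area."""


# 8-neighborhood in clockwise order, starting from West, in (row, col) offsets
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
_OFFSET_INDEX = {off: i for i, off in enumerate(_MOORE)}


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Ordered boundary pixels (row, col) of the single component in mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise NoObjectFoundError("no object found")
    # first foreground pixel in row-major scan; its West neighbor is background
    first = np.argmin(rows * mask.shape[1] + cols)
    start = (int(rows[first]), int(cols[first]))

    padded = np.pad(mask.astype(bool), 1)
    cur = (start[0] + 1, start[1] + 1)
    backtrack_dir = 0  # came from the West
    boundary = [cur]
    initial_state = (cur, backtrack_dir)
    max_steps = 4 * mask.size + 8

    for _ in range(max_steps):
        found = False
        for k in range(8):
            idx = (backtrack_dir + k) % 8
            dr, dc = _MOORE[idx]
            cand = (cur[0] + dr, cur[1] + dc)
            if padded[cand]:
                prev_idx = (idx - 1) % 8
                pdr, pdc = _MOORE[prev_idx]
                # new backtrack: direction from cand back toward the last
                # background pixel visited before entering cand
                back = (cur[0] + pdr - cand[0], cur[1] + pdc - cand[1])
                backtrack_dir = _OFFSET_INDEX[back]
                cur = cand
                found = True
                break
        if not found:  # isolated pixel
            break
        if (cur, backtrack_dir) == initial_state:
            break
        boundary.append(cur)
    else:
        raise RuntimeError("boundary tracing failed to terminate")

    return np.array(boundary, dtype=float) - 1.0  # undo padding


def trace_contour(mask: np.ndarray, min_area: int = 1) -> ContourSequence:
    """Trace the boundary-pixel loop of the largest component of a mask.

    Parameters
    ----------
    mask : array of bool or int
        Binary image; nonzero pixels are foreground.
    min_area : int
        Smallest component area (pixel count) considered an object.

    Returns
    -------
    ContourSequence
        Counterclockwise loop of boundary pixel centres in (x, y) =
        (column, row) coordinates.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    binary = mask != 0
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        raise NoObjectFoundError("no object found in mask")
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < min_area:
        raise NoObjectFoundError(
            f"no object found: largest component has area {areas[best - 1]} "
            f"< min_area {min_area}"
        )
    rc = _moore_trace(labels == best)
    if rc.shape[0] < 3:
        raise NoObjectFoundError(
            "largest component too small to form a closed contour"
        )
    xy = rc[:, ::-1]  # (x, y) = (col, row)
    return ContourSequence(points=xy).canonicalized()
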