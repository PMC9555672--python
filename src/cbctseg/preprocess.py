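"""Scan normalization and ground-truth canonicalization.

CBCT scans arrive with scanner-dependent intensity ranges and contrast.
Normalization clamps intensities between two percentiles of the
cumulative histogram — computed while ignoring the background, which in
head CBCT is the near-constant air surrounding the patient and dominates
the histogram — and rescales to [0, 1].  Ground-truth segmentations
arrive with arbitrary label values and sometimes hollow (shell-only)
masks; canonicalization binarizes to {0, 1} and fills internal cavities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_geometry import LabelMap, VolumeImage

__all__ = [
    "ContrastParams",
    "DegenerateContrastError",
    "EmptyLabelError",
    "contrast_adjust",
    "canonicalize_label",
]

# 6-connectivity (face adjacency) for the background when detecting
# cavities; the stricter background adjacency fills more aggressively,
# yielding solid bone masks.
_FILL_STRUCTURE = ndimage.generate_binary_structure(3, 1)


class DegenerateContrastError(ValueError):
    """Image has no usable intensity range for contrast adjustment."""


class EmptyLabelError(ValueError):
    """Segmentation contains no foreground voxels."""


@dataclass(frozen=True)
class ContrastParams:
    """Cumulative-histogram percentiles bounding the intensity window.

    Defaults keep the data between 1% and 99% of the cumulative graph.
    """

    x_min_pct: float = 1.0
    x_max_pct: float = 99.0
    n_bins: int = 1024

    def __post_init__(self):
        if not (0.0 <= self.x_min_pct < self.x_max_pct <= 100.0):
            raise ValueError(
                f"need 0 <= x_min_pct < x_max_pct <= 100, got "
                f"({self.x_min_pct}, {self.x_max_pct})"
            )
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def _percentile_bounds(values: np.ndarray, params: ContrastParams) -> tuple[float, float]:
    """New (min, max) from the cumulative histogram of non-background voxels.

    The background is taken to be the modal intensity (air dominates a head
    scan's histogram and is near-constant).  When the image has few distinct
    values the histogram is exact over those values; otherwise ``n_bins``
    uniform bins are used and the percentile lookup returns bin right-edges.
    """
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size < 2:
        raise DegenerateContrastError("constant image has no contrast to adjust")
    if uniq.size <= params.n_bins:
        levels, counts = uniq, counts.astype(float)
    else:
        hist, edges = np.histogram(values, bins=params.n_bins)
        levels, counts = edges[1:], hist.astype(float)
    counts = counts.copy()
    counts[np.argmax(counts)] = 0.0  # drop the background mode
    total = counts.sum()
    if total == 0:
        raise DegenerateContrastError("image is a single intensity plus background")
    cum = np.cumsum(counts) / total
    # At the 0% endpoint every intensity already satisfies the cumulative
    # condition, so the window opens at the global minimum; this makes a
    # second (0, 100) application an exact no-op.
    if params.x_min_pct == 0.0:
        lo = float(values.min())
    else:
        lo = float(levels[np.searchsorted(cum, params.x_min_pct / 100.0 - 1e-12)])
    hi = float(levels[np.searchsorted(cum, params.x_max_pct / 100.0 - 1e-12)])
    return lo, hi


def contrast_adjust(img: VolumeImage, params: ContrastParams | None = None) -> VolumeImage:
    """Percentile-window the intensities and rescale to [0, 1].

    Builds the intensity histogram excluding the background (modal)
    intensity, picks new bounds where the cumulative fraction reaches
    ``x_min_pct`` and ``x_max_pct``, clamps to those bounds and rescales
    affinely to [0, 1].  Geometry is unchanged.

    Raises
    ------
    DegenerateContrastError
        If the image is constant or the two bounds coincide.
    """
    if params is None:
        params = ContrastParams()
    lo, hi = _percentile_bounds(img.voxels.ravel(), params)
    if not hi > lo:
        raise DegenerateContrastError(
            f"degenerate contrast window: new min {lo} == new max {hi}"
        )
    out = np.clip(img.voxels.astype(np.float32), lo, hi)
    out -= lo
    out /= hi - lo
    return img.with_voxels(out)


def canonicalize_label(label: LabelMap) -> LabelMap:
    """Binarize a segmentation to {0, 1} and fill internal cavities.

    Any nonzero value becomes 1; background pockets with no 6-connected
    path to the grid border become foreground.  Idempotent, and never
    decreases the foreground voxel count.

    Raises
    ------
    EmptyLabelError
        If the label has no foreground voxels.
    """
    fg = label.voxels != 0
    if not fg.any():
        raise EmptyLabelError("segmentation has no foreground voxels")
    filled = ndimage.binary_fill_holes(fg, structure=_FILL_STRUCTURE)
    return LabelMap(
        voxels=filled.astype(np.uint8),
        spacing=label.spacing,
        origin=label.origin,
        direction=label.direction,
    )
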