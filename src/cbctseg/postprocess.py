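"""Cleaning raw segmentations and the end-to-end prediction pipeline.

A raw argmax segmentation can carry disconnected artifacts and internal
holes.  Post-processing keeps the largest connected component
(26-connected foreground), fills cavities (6-connected background), and
resamples the cleaned mask back onto the original scan geometry so the
output overlays the input voxel for voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .infer import SlidingWindowSpec, argmax_segment, sliding_window_predict
from .io_geometry import (
    GeometryError,
    LabelMap,
    VolumeImage,
    resample_to_reference,
    resample_to_spacing,
)
from .preprocess import ContrastParams, canonicalize_label, contrast_adjust

__all__ = [
    "ComponentReport",
    "component_report",
    "largest_component",
    "postprocess_segmentation",
    "predict_pipeline",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class ComponentReport:
    """Connected-component census of a binary label map."""

    n_components: int
    voxel_counts: tuple[int, ...]


def _labeled(label: LabelMap, connectivity: int):
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    fg = label.voxels != 0
    comp, n = ndimage.label(fg, structure=_STRUCTURES[connectivity])
    return comp, n


def component_report(label: LabelMap, connectivity: int = 26) -> ComponentReport:
    comp, n = _labeled(label, connectivity)
    counts = np.bincount(comp.ravel(), minlength=n + 1)[1:]
    return ComponentReport(n_components=int(n), voxel_counts=tuple(int(c) for c in counts))


def largest_component(label: LabelMap, connectivity: int = 26) -> LabelMap:
    """Keep only the largest connected foreground component.

    On ties the component whose first voxel comes earliest in scan order
    (smallest lexicographic corner) wins; an empty input passes through
    empty.
    """
    comp, n = _labeled(label, connectivity)
    if n <= 1:
        return label.with_voxels((label.voxels != 0).astype(np.uint8))
    counts = np.bincount(comp.ravel())
    counts[0] = 0
    # scipy numbers components in scan order, so argmax's first-maximum
    # rule implements the lexicographic tie-break
    keep = int(np.argmax(counts))
    return label.with_voxels((comp == keep).astype(np.uint8))


def postprocess_segmentation(
    raw: LabelMap, original: VolumeImage, connectivity: int = 26
) -> LabelMap:
    """largest component -> fill holes -> resample onto the original grid.

    Hole filling runs on the working-resolution grid, where the
    morphology is scale-consistent; the output geometry equals the
    original's exactly.  An empty input stays empty.
    """
    cleaned = largest_component(raw, connectivity)
    if cleaned.voxels.any():
        cleaned = canonicalize_label(cleaned)
    return resample_to_reference(cleaned, original)


def predict_pipeline(
    model,
    raw_scan: VolumeImage,
    contrast: ContrastParams | None = None,
    spec: SlidingWindowSpec | None = None,
    target_spacing: float = 0.4,
    return_probs: bool = False,
):
    """End-to-end segmentation of an unseen scan.

    The input is preserved; a working copy is resampled to the working
    spacing (if it differs), contrast-adjusted, segmented with sliding
    windows, argmaxed, cleaned and resampled back to the input geometry.

    Returns the final :class:`LabelMap` (and, with ``return_probs=True``,
    the working-resolution class-probability grid plus its geometry).
    """
    if contrast is None:
        contrast = ContrastParams()
    if spec is None:
        spec = SlidingWindowSpec()
    if np.any(np.asarray(raw_scan.spacing) <= 0):
        raise GeometryError("degenerate scan geometry")
    work = raw_scan
    tsp = (target_spacing,) * 3
    if target_spacing is not None and not np.allclose(work.spacing, tsp, atol=1e-6):
        work = resample_to_spacing(work, tsp, mode="linear")
    work = contrast_adjust(work, contrast)
    probs = sliding_window_predict(model, work, spec)
    raw_label = argmax_segment(probs, like=work)
    final = postprocess_segmentation(raw_label, raw_scan)
    if return_probs:
        return final, probs, work
    return final
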