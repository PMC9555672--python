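"""Synthetic CBCT-like phantoms with paired ground truth.

Real craniofacial CBCT datasets are rarely shareable, so every stage of
the pipeline — including a small end-to-end training run — is exercised
on procedurally generated phantoms that mimic the statistical structure
the pipeline assumes: a dominant near-constant air background, a bright
ellipsoidal "bone" shell that may enclose a dark cavity (for hole
filling), optional small disconnected bright satellites that are *not*
part of the ground truth (so largest-component filtering measurably
helps), anisotropic voxel spacing, speckle noise, and center-dependent
intensity offsets and gamma.  The ground truth is the solid
(cavity-filled) shell without satellites; at the default geometry it
occupies roughly 5-10% of the volume, matching the class imbalance of
skull structures in head scans.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .io_geometry import LabelMap, VolumeImage, write_volume

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "phantom_masks",
    "generate_dataset",
    "load_manifest",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator.

    Intensities are in arbitrary scanner-like units: air around
    ``background_level``, bone around ``bone_level``, Gaussian speckle of
    ``noise_sd`` on top.  ``radius_fraction_range`` bounds the outer
    ellipsoid semi-axes as fractions of the half-grid (drawn per axis, so
    phantoms are anisotropic in shape as well as spacing).
    """

    grid_size: int = 64
    spacing_range: tuple[float, float] = (0.16, 0.5)
    shell_thickness: float = 2.5
    cavity: bool = True
    n_satellites: int = 2
    noise_sd: float = 40.0
    intensity_gamma_range: tuple[float, float] = (0.8, 1.25)
    background_level: float = 100.0
    bone_level: float = 1000.0
    radius_fraction_range: tuple[float, float] = (0.45, 0.58)
    satellite_radius: float = 2.5
    center_offset: float = 120.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        lo, hi = self.spacing_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError(f"spacing_range must lie in (0, 1], got {self.spacing_range}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.shell_thickness * 2 >= self.grid_size * self.radius_fraction_range[0]:
            raise ValueError("shell thicker than the smallest allowed ellipsoid")


def _ellipsoid(grid: int, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    ax = np.arange(grid, dtype=np.float32)
    dx = ((ax - center[0]) / semi[0]) ** 2
    dy = ((ax - center[1]) / semi[1]) ** 2
    dz = ((ax - center[2]) / semi[2]) ** 2
    return dx[:, None, None] + dy[None, :, None] + dz[None, None, :] <= 1.0


def phantom_masks(spec: PhantomSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw the geometry: shell, solid, cavity and satellite masks.

    Consumes the same random stream as :func:`generate_phantom`, which
    calls it first.
    """
    n = spec.grid_size
    semi = rng.uniform(*spec.radius_fraction_range, size=3) * (n / 2.0)
    center = n / 2.0 + rng.uniform(-0.05, 0.05, size=3) * n
    solid = _ellipsoid(n, center, semi)
    inner = np.zeros_like(solid)
    if spec.cavity:
        inner = _ellipsoid(n, center, np.maximum(semi - spec.shell_thickness, 1.0))
    shell = solid & ~inner
    satellites = np.zeros_like(solid)
    placed = 0
    attempts = 0
    while placed < spec.n_satellites and attempts < 200:
        attempts += 1
        pos = rng.uniform(0.12 * n, 0.88 * n, size=3)
        # keep satellites clearly off the shell so they stay disconnected
        if (((pos - center) / (semi + spec.satellite_radius + 2.0)) ** 2).sum() <= 1.0:
            continue
        r = spec.satellite_radius * rng.uniform(0.8, 1.3)
        satellites |= _ellipsoid(n, pos, np.full(3, max(r, 1.0)))
        placed += 1
    satellites &= ~solid
    return {"solid": solid, "shell": shell, "cavity": inner, "satellites": satellites}


def generate_phantom(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    intensity_offset: float = 0.0,
) -> tuple[VolumeImage, LabelMap]:
    """One phantom: a noisy CBCT-like volume and its ground-truth label.

    The image shows the bright shell (dark inside the cavity) plus any
    satellites on a noisy air background, passed through a random gamma;
    the ground truth is the solid shell without satellites.  Image and
    label share a random anisotropic spacing drawn from
    ``spacing_range``.  Deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    masks = phantom_masks(spec, rng)
    n = spec.grid_size
    img = np.full((n, n, n), spec.background_level, dtype=np.float32)
    bright = masks["shell"] | masks["satellites"]
    img[bright] = spec.bone_level
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
    gamma = rng.uniform(*spec.intensity_gamma_range)
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        img = ((img - lo) / (hi - lo)) ** gamma * (hi - lo) + lo
    img += intensity_offset
    spacing = rng.uniform(*spec.spacing_range, size=3)
    image = VolumeImage(voxels=img, spacing=spacing)
    label = LabelMap(voxels=masks["solid"].astype(np.uint8), spacing=spacing)
    return image, label


def generate_dataset(
    n_per_center: int,
    n_centers: int,
    spec: PhantomSpec,
    out_dir: str | os.PathLike,
    seed: int = 0,
) -> dict:
    """Write a pseudo-multi-center phantom dataset to disk.

    One folder per pseudo-center; center ``c`` gets a systematic
    intensity offset of ``c * spec.center_offset`` on top of the
    per-phantom randomness, emulating scanner/protocol differences.
    Returns the manifest (also written as ``manifest.json``) mapping
    center names to image/label path pairs.
    """
    if n_per_center < 1 or n_centers < 1:
        raise ValueError("counts must be >= 1")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "centers": {}}
    for c in range(n_centers):
        name = f"center_{c:02d}"
        cdir = os.path.join(out_dir, name)
        os.makedirs(cdir, exist_ok=True)
        entries = []
        for i in range(n_per_center):
            img, lab = generate_phantom(spec, rng, intensity_offset=c * spec.center_offset)
            ipath = os.path.join(cdir, f"phantom_{i:03d}_img.nii.gz")
            lpath = os.path.join(cdir, f"phantom_{i:03d}_seg.nii.gz")
            write_volume(img, ipath)
            write_volume(lab, lpath)
            entries.append({"image": ipath, "label": lpath})
        manifest["centers"][name] = entries
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_manifest(path: str | os.PathLike) -> dict[str, list[tuple[str, str]]]:
    """Read a dataset manifest into the center -> [(image, label)] map
    expected by :func:`cbctseg.train.split_dataset`."""
    with open(path) as fh:
        manifest = json.load(fh)
    return {
        center: [(e["image"], e["label"]) for e in entries]
        for center, entries in manifest["centers"].items()
    }
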