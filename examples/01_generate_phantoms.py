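"""Generate a small multi-center phantom dataset and inspect it.

Writes image/label NIfTI pairs for two pseudo-centers and prints the
foreground prevalence and spacing of each phantom — the class imbalance
(a few percent) and anisotropic voxel sizes are what make these useful
stand-ins for clinical head scans.
"""

import numpy as np

from cbctseg import PhantomSpec, generate_dataset, load_manifest, read_volume

out_dir = "scratch_phantoms"
manifest = generate_dataset(n_per_center=3, n_centers=2, spec=PhantomSpec(), out_dir=out_dir, seed=7)

centers = load_manifest(f"{out_dir}/manifest.json")
for center, pairs in centers.items():
    for image_path, label_path in pairs:
        img = read_volume(image_path)
        lab = read_volume(label_path, as_label=True)
        print(
            f"{center}  {image_path.split('/')[-1]}  "
            f"spacing={np.round(img.spacing, 2)} mm  "
            f"mean intensity={img.voxels.mean():7.1f}  "
            f"bone fraction={lab.voxels.mean():.3f}"
        )
print(
    "\nBone occupies only a few percent of each volume (heavy class imbalance),\n"
    "and the second center is systematically brighter — the scanner-offset effect\n"
    "the per-center dataset split guards against."
)
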