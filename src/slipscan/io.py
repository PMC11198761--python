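"""NIfTI volume I/O and phantom dataset (de)serialization.

Conventions: 0-based voxel indices, axial slices along the third array
axis, (row, col) = (first, second) axis. Affines are passed through
untouched — nothing here re-orients data.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .noss import PhaseSeries, DIRECTION_ORDER
from .phantom import PhantomDataset

#: filename-safe tokens for the six encoding directions
DIRECTION_TOKENS = ("px", "mx", "py", "my", "pz", "mz")


def load_volume(path, reference_shape=None):
    """Load a NIfTI volume. Returns (data, voxel_spacing_mm, affine).

    ``reference_shape`` (optional) is checked against the spatial grid
    and a mismatch raises a descriptive error.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"cannot read NIfTI volume at {path}: {exc}") from exc
    data = np.asarray(img.get_fdata())
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if reference_shape is not None and tuple(data.shape[:3]) != tuple(reference_shape):
        raise ValueError(
            f"grid mismatch for {path}: volume is {data.shape[:3]}, "
            f"reference is {tuple(reference_shape)}"
        )
    return data, spacing, img.affine


def save_volume(path, data, voxel_spacing_mm, affine=None, dtype=None):
    """Write a NIfTI volume; the default affine is diag(spacing)."""
    data = np.asarray(data)
    if dtype is not None:
        data = data.astype(dtype)
    if affine is None:
        affine = np.diag(list(voxel_spacing_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(tuple(voxel_spacing_mm) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def save_phase_series(outdir, phase: PhaseSeries, affine=None) -> list[Path]:
    """One NIfTI per encoding direction, 4th dimension = 8 offsets."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tok in enumerate(DIRECTION_TOKENS):
        p = outdir / f"phase_{tok}.nii.gz"
        # (offsets, x, y, z) -> (x, y, z, offsets)
        save_volume(p, np.moveaxis(phase.data[i], 0, -1), phase.voxel_spacing_mm, affine)
        paths.append(p)
    return paths


def load_phase_series(indir) -> PhaseSeries:
    indir = Path(indir)
    vols, spacing = [], None
    for tok, name in zip(DIRECTION_TOKENS, DIRECTION_ORDER):
        p = indir / f"phase_{tok}.nii.gz"
        if not p.exists():
            p = indir / f"phase_{tok}.nii"
        if not p.exists():
            raise ValueError(f"missing phase volume for direction {name}: {p}")
        data, sp, _ = load_volume(p)
        spacing = spacing or sp
        vols.append(np.moveaxis(data, -1, 0))
    return PhaseSeries(data=np.stack(vols), voxel_spacing_mm=spacing)


def save_phantom_dataset(outdir, ds: PhantomDataset) -> None:
    """Write a phantom as the pipeline would consume it: phase NIfTIs,
    uint8 masks, and a JSON truth record (labels + realized fraction +
    full spec)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_phase_series(outdir, ds.phase)
    sp = ds.phase.voxel_spacing_mm
    save_volume(outdir / "tumor_mask.nii.gz", ds.tumor_mask, sp, dtype=np.uint8)
    save_volume(outdir / "brain_mask.nii.gz", ds.brain_mask, sp, dtype=np.uint8)
    save_volume(outdir / "slip_labels.nii.gz", ds.slip_label_truth, sp, dtype=np.uint8)
    truth = {
        "true_slip_fraction": ds.true_slip_fraction,
        "n_surface_voxels": int(ds.surface_mask.sum()),
        "n_slip_voxels": int(ds.slip_label_truth.sum()),
        "spec": ds.spec.to_dict(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
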