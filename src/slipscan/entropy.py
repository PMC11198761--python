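"""Boundary-entropy adhesion metric (reconstruction).

An earlier adhesion measure summarizes the NOSS contrast across the
tumor boundary: at each boundary point, NOSS is sampled a few voxels
outward and inward along the local boundary normal, the outside-minus-
inside difference (delta-NOSS) is formed, and the Shannon entropy of
the distribution of these differences over the whole boundary is the
tumor-level score. A slip interface gives a wide, multi-modal
delta-NOSS distribution (high entropy); a fully adherent interface
gives a narrow one.

The published description leaves the sampling depth, histogram binning
and logarithm base unspecified, so this module is an explicit,
configurable reconstruction of the idea rather than a replication of
any particular implementation; its role here is to serve as the
comparison metric in phantom experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .noss import ScalarMap
from .sir import BoundaryPath, RPImage, SIRParams, trace_boundary, extract_rp, standardize_rp


@dataclass
class EntropyParams:
    """normal_depth_vox: sampling depth on each side of the boundary
    along the normal (voxels). n_bins / bin_range: histogram on the
    standardized delta-NOSS values. Entropy is reported in bits."""

    normal_depth_vox: int = 2
    n_bins: int = 32
    bin_range: tuple[float, float] = (-1.0, 1.0)

    def __post_init__(self) -> None:
        if self.normal_depth_vox < 1:
            raise ValueError("normal_depth_vox must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def boundary_normals(path: BoundaryPath, roi_slice: np.ndarray) -> np.ndarray:
    """Outward unit normal at each point of a closed boundary path.

    The tangent at point i is the central difference of points i-1 and
    i+1 (cyclic); the normal is its unit perpendicular, oriented so a
    one-pixel step along it leaves the ROI (outward). Reversing the
    path orientation leaves the outward normals unchanged.
    """
    pts = np.asarray(path.points, dtype=float)
    if len(pts) < 3:
        raise ValueError("path must have at least 3 points")
    roi = np.asarray(roi_slice).astype(bool)
    tangent = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norms = np.linalg.norm(tangent, axis=1)
    norms[norms == 0] = 1.0
    tangent /= norms[:, None]
    normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)  # perpendicular

    def inside(p):
        r, c = int(round(p[0])), int(round(p[1]))
        return 0 <= r < roi.shape[0] and 0 <= c < roi.shape[1] and roi[r, c]

    for i in range(len(pts)):
        probe_out = pts[i] + normal[i]
        probe_in = pts[i] - normal[i]
        if inside(probe_out) and not inside(probe_in):
            normal[i] = -normal[i]
    return normal


def delta_noss_bdy(
    rp: RPImage,
    path: BoundaryPath,
    normals: np.ndarray,
    params: EntropyParams | None = None,
) -> np.ndarray:
    """Outside-minus-inside NOSS difference at each boundary point.

    Samples nearest-voxel NOSS at +1..+depth steps along the outward
    normal and -1..-depth steps inward (RP coordinates); samples that
    leave the RP or hit masked voxels are dropped, and a point is
    dropped entirely if either side ends up empty.
    """
    params = params or EntropyParams()
    if not rp.standardized:
        raise ValueError("RP must be standardized")
    vals = rp.intensities
    out = []
    for (r, c), n in zip(path.points, normals):
        sides = []
        for sign in (+1, -1):
            samples = []
            for k in range(1, params.normal_depth_vox + 1):
                rr = int(round(r + sign * k * n[0]))
                cc = int(round(c + sign * k * n[1]))
                if 0 <= rr < vals.shape[0] and 0 <= cc < vals.shape[1]:
                    v = vals[rr, cc]
                    if np.isfinite(v):
                        samples.append(v)
            sides.append(samples)
        if sides[0] and sides[1]:
            out.append(float(np.mean(sides[0]) - np.mean(sides[1])))
    return np.asarray(out)


def entropy_delta_noss(values: np.ndarray, params: EntropyParams | None = None) -> float:
    """Shannon entropy (bits) of the delta-NOSS histogram."""
    params = params or EntropyParams()
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 delta-NOSS values")
    counts, _ = np.histogram(values, bins=params.n_bins, range=params.bin_range)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def run_entropy(
    noss: ScalarMap | np.ndarray,
    tumor_mask: np.ndarray,
    params: EntropyParams | None = None,
    sir_params: SIRParams | None = None,
) -> float:
    """Tumor-level boundary entropy, pooled over all analyzable slices."""
    params = params or EntropyParams()
    sir_params = sir_params or SIRParams()
    vol = noss.values if isinstance(noss, ScalarMap) else np.asarray(noss, dtype=float)
    mask = np.asarray(tumor_mask).astype(bool)
    if vol.shape != mask.shape:
        raise ValueError("NOSS grid does not match mask grid")
    deltas = []
    for z in range(vol.shape[2]):
        roi = mask[:, :, z]
        if roi.sum() < sir_params.min_roi_pixels_per_slice:
            continue
        paths = trace_boundary(roi, min_area=sir_params.min_roi_pixels_per_slice)
        if not paths:
            continue
        rp = standardize_rp(extract_rp(vol[:, :, z], roi, pad=sir_params.rp_pad_vox))
        r0, c0 = rp.origin
        for path in paths:
            if len(path.points) < 3:
                continue
            local = BoundaryPath(
                slice_index=z,
                points=[(r - r0, c - c0) for (r, c) in path.points],
                component_id=path.component_id,
            )
            roi_local = roi[r0 : r0 + rp.intensities.shape[0], c0 : c0 + rp.intensities.shape[1]]
            normals = boundary_normals(local, roi_local)
            deltas.extend(delta_noss_bdy(rp, local, normals, params))
    if len(deltas) < 2:
        raise ValueError("no analyzable boundary")
    return entropy_delta_noss(np.asarray(deltas), params)
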