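"""From encoded MRE phase to the NOSS map.

The processing chain implemented here is

    phase (6 encoding directions x 8 offsets)
      -> displacement (3 components x 8 offsets)      phase_to_displacement
      -> strain tensor per offset                     strain_tensor
      -> octahedral shear strain (OSS) per offset     octahedral_shear_strain
      -> OSS averaged over the 8 offsets              mean_oss
      -> first-harmonic motion amplitude              first_harmonic_amplitude
      -> NOSS = mean OSS / combined amplitude         noss_map

OSS is a rotation-invariant scalar summary of the shear part of the
strain tensor; dividing by the local first-harmonic motion amplitude
makes the resulting NOSS map independent of the overall vibration
amplitude, so slip interfaces (where shear is concentrated relative to
the local motion) light up consistently across subjects.

Masked (undefined) voxels are represented as NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Encoding-direction order used for the first axis of PhaseSeries.data.
DIRECTION_ORDER = ("+x", "-x", "+y", "-y", "+z", "-z")

N_OFFSETS = 8


@dataclass
class PhaseSeries:
    """Motion-encoded MR phase.

    ``data`` has shape (6, 8, nx, ny, nz): 6 encoding directions in
    :data:`DIRECTION_ORDER`, 8 phase offsets over one vibration period,
    then the spatial grid. Values are radians (assumed unwrapped).
    """

    data: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 5 or self.data.shape[0] != 6 or self.data.shape[1] != N_OFFSETS:
            raise ValueError(
                f"PhaseSeries.data must have shape (6, {N_OFFSETS}, nx, ny, nz); "
                f"got {self.data.shape}"
            )
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]


@dataclass
class DisplacementField:
    """Harmonic displacement, shape (3, 8, nx, ny, nz): components x, y, z
    by 8 phase offsets. Units are arbitrary unless a physical
    motion-encoding sensitivity was supplied at decode time."""

    u: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 5 or self.u.shape[0] != 3 or self.u.shape[1] != N_OFFSETS:
            raise ValueError(
                f"DisplacementField.u must have shape (3, {N_OFFSETS}, nx, ny, nz); "
                f"got {self.u.shape}"
            )
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape[2:]


@dataclass
class StrainField:
    """Symmetric strain tensor at one phase offset: the six unique
    components, each a 3D grid."""

    exx: np.ndarray
    eyy: np.ndarray
    ezz: np.ndarray
    exy: np.ndarray
    exz: np.ndarray
    eyz: np.ndarray


@dataclass
class ScalarMap:
    """One value per voxel; NaN marks undefined (masked) voxels.

    ``kind`` is one of ``{"OSS", "OSS_mean", "amplitude", "NOSS"}``.
    """

    values: np.ndarray
    kind: str
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def phase_to_displacement(phase: PhaseSeries, sensitivity: float = 1.0) -> DisplacementField:
    """Decode displacement from paired-polarity phase images.

    For each axis d, the two polarities encode +u_d and -u_d plus any
    common-mode phase, so the half-difference

        u_d(t) = (phi_{+d}(t) - phi_{-d}(t)) / (2 * sensitivity)

    rejects the common mode and recovers the displacement component.

    Parameters
    ----------
    phase
        Unwrapped phase series.
    sensitivity
        Motion-encoding sensitivity in radians per displacement unit.
        The default 1.0 yields displacement on the encoding scale; NOSS
        is invariant to this choice.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    bad = ~np.isfinite(phase.data)
    if bad.any():
        raise ValueError(
            f"phase contains {int(bad.any(axis=(0, 1)).sum())} voxels with "
            "non-finite values; phase must be finite (and unwrapped)"
        )
    u = (phase.data[0::2] - phase.data[1::2]) / (2.0 * sensitivity)
    return DisplacementField(u=u, voxel_spacing_mm=phase.voxel_spacing_mm)


def strain_tensor(u_at_offset: np.ndarray, spacing_mm: tuple[float, float, float]) -> StrainField:
    """Small-strain tensor of a single-offset displacement field.

    eps_ij = (d u_i / d x_j + d u_j / d x_i) / 2, with derivatives taken
    per millimetre: central differences in the interior, one-sided at
    the grid edges (numpy.gradient's scheme).

    ``u_at_offset`` has shape (3, nx, ny, nz).
    """
    u = np.asarray(u_at_offset, dtype=float)
    if u.ndim != 4 or u.shape[0] != 3:
        raise ValueError(f"expected displacement of shape (3, nx, ny, nz); got {u.shape}")
    if min(u.shape[1:]) < 3:
        raise ValueError("grid must be at least 3 voxels along every axis")
    sx, sy, sz = spacing_mm
    # grad[i][j] = d u_i / d x_j
    grad = [np.gradient(u[i], sx, sy, sz) for i in range(3)]
    return StrainField(
        exx=grad[0][0],
        eyy=grad[1][1],
        ezz=grad[2][2],
        exy=0.5 * (grad[0][1] + grad[1][0]),
        exz=0.5 * (grad[0][2] + grad[2][0]),
        eyz=0.5 * (grad[1][2] + grad[2][1]),
    )


def octahedral_shear_strain(eps: StrainField) -> np.ndarray:
    """Octahedral shear strain of a strain tensor field.

    OSS = (2/3) * sqrt( (e_xx - e_yy)^2 + (e_yy - e_zz)^2 + (e_zz - e_xx)^2
                        + 6 * (e_xy^2 + e_xz^2 + e_yz^2) )

    Equal to (2/3) * sqrt(sum of squared principal-strain differences),
    hence invariant under rotation of the coordinate frame.
    """
    return (2.0 / 3.0) * np.sqrt(
        (eps.exx - eps.eyy) ** 2
        + (eps.eyy - eps.ezz) ** 2
        + (eps.ezz - eps.exx) ** 2
        + 6.0 * (eps.exy**2 + eps.exz**2 + eps.eyz**2)
    )


def mean_oss(oss_per_offset: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Voxelwise arithmetic mean of the 8 per-offset OSS maps."""
    stack = np.asarray(oss_per_offset, dtype=float)
    if stack.shape[0] != N_OFFSETS:
        raise ValueError(f"expected {N_OFFSETS} OSS maps, got {stack.shape[0]}")
    return stack.mean(axis=0)


def first_harmonic_amplitude(u: DisplacementField) -> ScalarMap:
    """Combined first-harmonic motion amplitude.

    Per voxel and component c, the DFT bin k=1 of the 8-sample series is
    X1 = sum_t u_c(t) exp(-2*pi*i*t/8); the single-sided amplitude is
    A_c = 2|X1|/8, and the combined amplitude is the root sum of squares
    A = sqrt(A_x^2 + A_y^2 + A_z^2).
    """
    t = np.arange(N_OFFSETS)
    w = np.exp(-2j * np.pi * t / N_OFFSETS)
    # X1 over the offsets axis for all 3 components at once
    x1 = np.tensordot(w, np.moveaxis(u.u, 1, 0), axes=(0, 0))  # (3, nx, ny, nz)
    amp = (2.0 / N_OFFSETS) * np.abs(x1)
    combined = np.sqrt((amp**2).sum(axis=0))
    return ScalarMap(values=combined, kind="amplitude", voxel_spacing_mm=u.voxel_spacing_mm)


def noss_map(mean_oss_map: ScalarMap, amplitude: ScalarMap, eps_amp: float) -> ScalarMap:
    """Normalize mean OSS by the combined first-harmonic amplitude.

    Voxels whose amplitude falls below ``eps_amp`` are masked (NaN) and
    stay excluded from every downstream maximum/minimum; without this
    guard near-nodes of the wave field would blow up the quotient. A
    dataset with no valid voxel at all is the in-silico analogue of a
    technically failed exam with too little wave amplitude.
    """
    if eps_amp <= 0:
        raise ValueError("eps_amp must be positive")
    if mean_oss_map.values.shape != amplitude.values.shape:
        raise ValueError("mean OSS and amplitude grids differ")
    ok = np.isfinite(amplitude.values) & (amplitude.values >= eps_amp)
    ok &= np.isfinite(mean_oss_map.values)
    if not ok.any():
        raise ValueError("no valid wave amplitude")
    out = np.full(mean_oss_map.values.shape, np.nan)
    out[ok] = mean_oss_map.values[ok] / amplitude.values[ok]
    return ScalarMap(values=out, kind="NOSS", voxel_spacing_mm=mean_oss_map.voxel_spacing_mm)


def default_eps_amp(amplitude: ScalarMap, brain_mask: np.ndarray | None = None) -> float:
    """Scale-free amplitude guard: 1e-3 x median amplitude over the
    brain mask (whole grid if no mask)."""
    vals = amplitude.values if brain_mask is None else amplitude.values[brain_mask.astype(bool)]
    med = float(np.nanmedian(vals))
    if not np.isfinite(med) or med <= 0:
        raise ValueError("no valid wave amplitude")
    return 1e-3 * med


def compute_noss(
    phase: PhaseSeries,
    sensitivity: float = 1.0,
    brain_mask: np.ndarray | None = None,
    eps_amp: float | None = None,
    smooth_sigma_mm: float = 0.0,
) -> dict[str, ScalarMap]:
    """Full phase-to-NOSS pipeline.

    Returns a dict with keys ``"noss"``, ``"amplitude"``, ``"oss_mean"``.
    ``smooth_sigma_mm`` > 0 applies an optional Gaussian pre-filter (per
    component and offset, sigma in mm) to the displacement before
    differentiation; default off.
    """
    disp = phase_to_displacement(phase, sensitivity)
    u = disp.u
    if smooth_sigma_mm > 0:
        from scipy.ndimage import gaussian_filter

        sig_vox = [smooth_sigma_mm / s for s in disp.voxel_spacing_mm]
        u = np.stack(
            [
                np.stack([gaussian_filter(u[c, t], sig_vox) for t in range(N_OFFSETS)])
                for c in range(3)
            ]
        )
        disp = DisplacementField(u=u, voxel_spacing_mm=disp.voxel_spacing_mm)
    oss = [
        octahedral_shear_strain(strain_tensor(disp.u[:, t], disp.voxel_spacing_mm))
        for t in range(N_OFFSETS)
    ]
    oss_mean = ScalarMap(mean_oss(oss), "OSS_mean", disp.voxel_spacing_mm)
    amp = first_harmonic_amplitude(disp)
    if brain_mask is not None:
        outside = ~brain_mask.astype(bool)
        oss_mean.values[outside] = np.nan
        amp.values[outside] = np.nan
    if eps_amp is None:
        eps_amp = default_eps_amp(amp, brain_mask)
    noss = noss_map(oss_mean, amp, eps_amp)
    return {"noss": noss, "amplitude": amp, "oss_mean": oss_mean}
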