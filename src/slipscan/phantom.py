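"""Synthetic shear-wave phantom with a slip-surface ground truth.

A spherical tumor inclusion sits in a background medium carrying a
single transverse plane wave at the vibration frequency. The interior
of the inclusion oscillates with its own amplitude and phase lag underneath the *slip*
part of the surface — a spherical-cap sector around a chosen axis,
sized so its area fraction matches the requested slip fraction — which
leaves a sharp displacement discontinuity across the boundary there,
the mechanism that concentrates shear strain and produces the
hyper-intense NOSS rim of a slip interface. Underneath the *adherent*
part the interior follows the exterior wave, so the boundary carries no
strain concentration and NOSS stays flat, as at a real adherent
interface. A narrow angular ramp joins the two interior regimes.

This is an idealized forward model built to exercise the downstream
NOSS + SIR pipeline with known labels, not a mechanical model of brain
tissue: no attenuation, reflections, viscoelasticity, or scanner
artifacts (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import binary_erosion

from .noss import PhaseSeries, DisplacementField, N_OFFSETS

_UNIT_TOL = 1e-9


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,) or abs(np.linalg.norm(v) - 1.0) > _UNIT_TOL:
        raise ValueError(f"{name} must be a unit 3-vector")
    return v


@dataclass
class WaveSpec:
    """Transverse plane wave: displacement along ``polarization``,
    propagating along ``direction`` with the given wavelength and a
    fixed phase offset."""

    amplitude_um: float = 10.0
    wavelength_mm: float = 30.0
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    polarization: tuple[float, float, float] = (1.0, 0.0, 0.0)
    phase_rad: float = 0.0


@dataclass
class TumorWaveSpec:
    """Interior oscillation: same polarization as the background wave,
    its own amplitude and a phase lag relative to the exterior field."""

    amplitude_um: float = 10.0
    phase_lag_rad: float = np.pi / 2


@dataclass
class PhantomSpec:
    """Complete description of one synthetic acquisition.

    Defaults mirror a typical brain MRE protocol: 24 cm field of view
    reconstructed at 128 in-plane (1.875 mm), 3 mm slices, 8 phase
    offsets over one 60 Hz period, ~30 mm shear wavelength. The grid is
    a 64x64x32 crop of that resolution, enough to hold a centimetre-
    scale tumor with margin.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_spacing_mm: tuple[float, float, float] = (1.875, 1.875, 3.0)
    tumor_center_vox: tuple[float, float, float] | None = None  # default: grid center
    tumor_radius_mm: float = 12.0
    slip_fraction: float = 0.5
    slip_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    background_wave: WaveSpec = field(default_factory=WaveSpec)
    secondary_wave: WaveSpec | None = field(
        default_factory=lambda: WaveSpec(
            amplitude_um=5.0,
            wavelength_mm=24.0,
            direction=(0.0, 1.0, 0.0),
            polarization=(1.0, 0.0, 0.0),
            phase_rad=1.2,
        )
    )
    tumor_wave: TumorWaveSpec = field(default_factory=TumorWaveSpec)
    blend_width_vox: float = 2.0
    encoding_sensitivity_rad_per_um: float = 1.0
    phase_noise_sd_rad: float = 0.02
    n_offsets: int = N_OFFSETS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_center_vox is None:
            self.tumor_center_vox = tuple((n - 1) / 2.0 for n in self.grid_shape)
        _check_unit(self.slip_axis, "slip_axis")
        waves = [("background_wave", self.background_wave)]
        if self.secondary_wave is not None:
            waves.append(("secondary_wave", self.secondary_wave))
        for name, w in waves:
            d = _check_unit(w.direction, f"{name}.direction")
            p = _check_unit(w.polarization, f"{name}.polarization")
            if abs(float(d @ p)) > _UNIT_TOL:
                raise ValueError(f"{name}: polarization must be orthogonal to direction")
        if not (0.0 <= self.slip_fraction <= 1.0):
            raise ValueError("slip_fraction must lie in [0, 1]")
        if self.blend_width_vox <= 0:
            raise ValueError("blend_width_vox must be positive")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor_radius_mm must be positive")
        if self.phase_noise_sd_rad < 0:
            raise ValueError("phase_noise_sd_rad must be non-negative")
        if self.encoding_sensitivity_rad_per_um <= 0:
            raise ValueError("encoding sensitivity must be positive")
        if self.n_offsets != N_OFFSETS:
            raise ValueError(f"n_offsets must be {N_OFFSETS}")
        # the sphere must fit with >= 6 voxels margin on every side
        for ax in range(3):
            r_vox = self.tumor_radius_mm / self.voxel_spacing_mm[ax]
            c = self.tumor_center_vox[ax]
            if c - r_vox < 6 or c + r_vox > self.grid_shape[ax] - 1 - 6:
                raise ValueError(
                    "tumor sphere must fit inside the grid with >= 6 voxels margin "
                    f"(axis {ax}: center {c}, radius {r_vox:.1f} vox, "
                    f"extent {self.grid_shape[ax]})"
                )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomDataset:
    """Everything the downstream pipeline consumes, plus ground truth."""

    phase: PhaseSeries
    displacement_truth: DisplacementField
    tumor_mask: np.ndarray
    brain_mask: np.ndarray
    surface_mask: np.ndarray  # surface voxels of tumor_mask (face-neighbor def.)
    slip_label_truth: np.ndarray  # True on surface voxels in the slip sector
    true_slip_fraction: float
    spec: PhantomSpec


def _physical_coords(grid_shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(grid_shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")  # x, y, z in mm


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` with at least one face-neighbor outside it."""
    mask = mask.astype(bool)
    interior = binary_erosion(
        mask, structure=np.array(
            [[[0, 0, 0], [0, 1, 0], [0, 0, 0]],
             [[0, 1, 0], [1, 1, 1], [0, 1, 0]],
             [[0, 0, 0], [0, 1, 0], [0, 0, 0]]], dtype=bool),
        border_value=0,
    )
    return mask & ~interior


def slip_surface_labels(
    tumor_mask: np.ndarray,
    slip_axis,
    slip_fraction: float,
    center_vox,
    voxel_spacing_mm=(1.0, 1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Label the slip sector of the tumor surface.

    A surface voxel v is labeled slip iff the angle between (v - center)
    (in physical mm) and ``slip_axis`` is below the spherical-cap
    half-angle theta* solving (1 - cos theta*)/2 = slip_fraction, so the
    cap's area fraction on an ideal sphere equals the requested
    fraction.

    Returns ``(surface_mask, slip_labels, realized_fraction)`` where
    ``realized_fraction`` is the labeled-to-total surface voxel ratio.
    """
    tumor_mask = np.asarray(tumor_mask).astype(bool)
    if not tumor_mask.any():
        raise ValueError("empty ROI")
    if not (0.0 <= slip_fraction <= 1.0):
        raise ValueError("slip_fraction must lie in [0, 1]")
    axis = _check_unit(slip_axis, "slip_axis")
    surf = surface_voxels(tumor_mask)
    idx = np.argwhere(surf)
    rel = (idx - np.asarray(center_vox)) * np.asarray(voxel_spacing_mm)
    norms = np.linalg.norm(rel, axis=1)
    norms[norms == 0] = 1.0
    cos_angle = (rel @ axis) / norms
    if slip_fraction >= 1.0:
        labeled = np.ones(len(idx), dtype=bool)
    elif slip_fraction <= 0.0:
        labeled = np.zeros(len(idx), dtype=bool)
    else:
        cos_star = 1.0 - 2.0 * slip_fraction
        labeled = cos_angle >= cos_star
    labels = np.zeros(tumor_mask.shape, dtype=bool)
    labels[tuple(idx[labeled].T)] = True
    realized = float(labeled.sum() / len(idx))
    return surf, labels, realized


def synthesize_displacement(spec: PhantomSpec) -> DisplacementField:
    """Analytic displacement field of the phantom at the 8 phase offsets.

    Outside the tumor the field is a superposition of transverse plane
    waves (the primary ``background_wave`` plus, by default, a weaker
    ``secondary_wave``): u(r, t) = sum_w p_w A_w cos(k_w . r - theta_t
    + phi_w), theta_t = 2*pi*t/8. The interference of the two waves
    gives the background a smoothly varying OSS, amplitude and NOSS, as
    in real tissue; a single plane wave would make NOSS spatially
    constant and the per-RP standardization downstream degenerate.

    In the slip sector the interior carries the same superposition
    phase-lagged by ``tumor_wave.phase_lag_rad`` and rescaled to
    ``tumor_wave.amplitude_um`` (relative to the primary amplitude), so
    with zero lag and equal amplitude the interior equals the exterior
    field identically. Under the adherent sector the interior
    follows the exterior wave exactly, so displacement is continuous
    across the boundary there and the adherent interface is strain-free
    up to the wave's own strain; in the slip cap no continuity is
    imposed, leaving a sharp discontinuity across the boundary. The two
    interior regimes are joined by a linear angular ramp whose arc
    width at the tumor surface is ``blend_width_vox`` voxels (mean
    spacing), so the seam itself does not produce a spurious strain
    sheet inside the tumor.
    """
    gx, gy, gz = _physical_coords(spec.grid_shape, spec.voxel_spacing_mm)
    center_mm = np.asarray(spec.tumor_center_vox) * np.asarray(spec.voxel_spacing_mm)
    rel = np.stack([gx - center_mm[0], gy - center_mm[1], gz - center_mm[2]])
    dist = np.sqrt((rel**2).sum(axis=0))

    tw = spec.tumor_wave
    waves = [spec.background_wave]
    if spec.secondary_wave is not None:
        waves.append(spec.secondary_wave)
    wave_terms = []  # (polarization, amplitude, k.r + phase)
    for w in waves:
        k = 2 * np.pi / w.wavelength_mm
        khat = np.asarray(w.direction, dtype=float)
        kr = k * (khat[0] * gx + khat[1] * gy + khat[2] * gz) + w.phase_rad
        wave_terms.append((np.asarray(w.polarization, dtype=float), w.amplitude_um, kr))
    tumor_scale = tw.amplitude_um / spec.background_wave.amplitude_um

    inside = dist <= spec.tumor_radius_mm
    # slip weight s: 1 in the cap around slip_axis, 0 in the adherent
    # sector, linear ramp over the seam arc
    axis = np.asarray(spec.slip_axis, dtype=float)
    norms = np.where(dist == 0, 1.0, dist)
    cos_angle = (rel[0] * axis[0] + rel[1] * axis[1] + rel[2] * axis[2]) / norms
    w_mm = spec.blend_width_vox * float(np.mean(spec.voxel_spacing_mm))
    if spec.slip_fraction >= 1.0:
        s = np.ones_like(dist)
    elif spec.slip_fraction <= 0.0:
        s = np.zeros_like(dist)
    else:
        theta_star = np.arccos(1.0 - 2.0 * spec.slip_fraction)
        dtheta = w_mm / spec.tumor_radius_mm  # seam arc width in radians
        angle = np.arccos(np.clip(cos_angle, -1.0, 1.0))
        # ramp centered on the cap edge, so the labeled cap fraction is unbiased
        s = np.clip((theta_star - angle) / dtheta + 0.5, 0.0, 1.0)

    theta = 2 * np.pi * np.arange(N_OFFSETS) / N_OFFSETS
    u = np.zeros((3, N_OFFSETS) + tuple(spec.grid_shape))
    weight = np.where(inside, s, 0.0)  # slip-interior mixing weight
    for t, th in enumerate(theta):
        for pol, amp, kr in wave_terms:
            u_out = amp * np.cos(kr - th)
            u_tum = tumor_scale * amp * np.cos(kr - th + tw.phase_lag_rad)
            scalar = u_out + weight * (u_tum - u_out)
            for c in range(3):
                if pol[c] != 0.0:
                    u[c, t] += pol[c] * scalar
    return DisplacementField(u=u, voxel_spacing_mm=spec.voxel_spacing_mm)


def encode_phase(
    displacement: DisplacementField,
    sensitivity: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhaseSeries:
    """Encode displacement into paired-polarity MR phase.

    phi_{+d} = +sensitivity * u_d + eta,  phi_{-d} = -sensitivity * u_d + eta'
    with eta, eta' i.i.d. Gaussian(0, noise_sd) per voxel and offset.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be positive")
    rng = np.random.default_rng(seed)
    u = displacement.u
    data = np.empty((6,) + u.shape[1:])
    for d in range(3):
        clean = sensitivity * u[d]
        data[2 * d] = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean.copy()
        data[2 * d + 1] = -clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else -clean
    return PhaseSeries(data=data, voxel_spacing_mm=displacement.voxel_spacing_mm)


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Build the full synthetic dataset for one spec."""
    gx, gy, gz = np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij")
    spacing = np.asarray(spec.voxel_spacing_mm)
    center = np.asarray(spec.tumor_center_vox)
    dist = np.sqrt(
        ((gx - center[0]) * spacing[0]) ** 2
        + ((gy - center[1]) * spacing[1]) ** 2
        + ((gz - center[2]) * spacing[2]) ** 2
    )
    tumor_mask = dist <= spec.tumor_radius_mm

    brain_mask = np.zeros(spec.grid_shape, dtype=bool)
    brain_mask[2:-2, 2:-2, 2:-2] = True

    surf, labels, realized = slip_surface_labels(
        tumor_mask, spec.slip_axis, spec.slip_fraction, center, spec.voxel_spacing_mm
    )
    disp = synthesize_displacement(spec)
    phase = encode_phase(
        disp,
        sensitivity=spec.encoding_sensitivity_rad_per_um,
        noise_sd=spec.phase_noise_sd_rad,
        seed=spec.seed,
    )
    return PhantomDataset(
        phase=phase,
        displacement_truth=disp,
        tumor_mask=tumor_mask,
        brain_mask=brain_mask,
        surface_mask=surf,
        slip_label_truth=labels,
        true_slip_fraction=realized,
        spec=spec,
    )
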