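"""Slip interface recognition (SIR).

Classifies every point on the traced tumor-boundary contour of each
axial slice as adherent or non-adherent from the local NOSS pattern,
and aggregates the labels into a tumor-level non-adhesion percentage.

Per slice the algorithm: (1) crops a rectangular partial (RP) NOSS
image around the tumor ROI bounding box with a small pad, (2)
standardizes the RP so its maximum intensity is 1, (3) traces the ROI
boundary (Moore neighbor tracing, clockwise), and (4) for each boundary
point evaluates three conditions on the point intensity I(a) and an
adaptive 3x3 / 5x5 neighborhood patch:

  I.   I(a) lies outside [cond1_min_frac * RP_min, cond1_max_frac * RP_max]
       — a distinct bright (or, with ROI misalignment, dark) rim.
  II.  |I(a) - patch mean| > tau, tau = cond2_tau_frac * (patch range)
       — a traceable intensity step at the boundary.
  III. |I(a) - patch mean| <= tau and patch range > cond3_range_frac * I(a)
       — large local variation with faint point contrast.

A point is non-adherent if any condition holds; the non-adhesion
percentage is the pooled fraction of non-adherent boundary points over
all slices (point count standing in for interface length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .noss import ScalarMap


@dataclass
class SIRParams:
    """All thresholds of the SIR decision function.

    Defaults are the published operating point: patch escalation below
    0.065, the 85% / 115% RP-extremum bounds for Condition I, tau at
    20% of the patch range for Condition II, and the 80% range-to-point
    factor for Condition III. They are plain attributes so limiting
    configurations (e.g. a disabled condition) can be explored.
    """

    rp_pad_vox: int = 3
    patch_size_default: int = 3
    patch_size_large: int = 5
    patch_escalation_threshold: float = 0.065
    cond1_max_frac: float = 0.85
    cond1_min_frac: float = 1.15
    cond2_tau_frac: float = 0.20
    cond3_range_frac: float = 0.80
    min_roi_pixels_per_slice: int = 5

    def __post_init__(self) -> None:
        for name in ("patch_size_default", "patch_size_large"):
            k = getattr(self, name)
            if k not in (3, 5) or k % 2 == 0:
                raise ValueError(f"{name} must be 3 or 5")
        if self.rp_pad_vox < 0:
            raise ValueError("rp_pad_vox must be non-negative")
        for name in (
            "patch_escalation_threshold",
            "cond1_max_frac",
            "cond1_min_frac",
            "cond2_tau_frac",
            "cond3_range_frac",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class BoundaryPath:
    """Ordered, closed boundary contour of one 8-connected ROI component
    on one slice. Points are 0-based (row, col) pixel coordinates."""

    slice_index: int
    points: list[tuple[int, int]]
    component_id: int


@dataclass
class RPImage:
    """Rectangular partial NOSS image: ROI bounding box plus pad,
    clipped at the slice edges. NaN entries are masked."""

    intensities: np.ndarray
    origin: tuple[int, int]
    standardized: bool = False
    degenerate: bool = False  # set if standardization found max <= 0


@dataclass
class Patch:
    center: tuple[int, int]
    size: int
    values: np.ndarray
    p_min: float
    p_max: float
    p_mean: float


@dataclass
class PointLabel:
    point: tuple[int, int, int]  # (slice, row, col)
    non_adherent: bool
    fired_condition: str  # "I" | "II" | "III" | "none"


@dataclass
class AdhesionResult:
    per_slice: list[tuple[int, int, int]]  # (slice_index, n_points, n_non_adherent)
    non_adhesion_pct: float
    adhesion_pct: float
    condition_counts: dict[str, int]
    n_points: int = 0
    n_unanalyzable: int = 0

    def to_dict(self) -> dict:
        return {
            "non_adhesion_pct": self.non_adhesion_pct,
            "adhesion_pct": self.adhesion_pct,
            "n_points": self.n_points,
            "n_unanalyzable": self.n_unanalyzable,
            "condition_counts": dict(self.condition_counts),
            "per_slice": [
                {"slice": s, "n_points": n, "n_non_adherent": m}
                for s, n, m in self.per_slice
            ],
        }


# 8-connectivity for component labeling
_CONN8 = np.ones((3, 3), dtype=bool)
# Moore neighborhood in clockwise order starting from "up"
_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def face_boundary_pixels(roi_slice: np.ndarray) -> np.ndarray:
    """ROI pixels with at least one 4-neighbor outside the ROI."""
    roi = roi_slice.astype(bool)
    interior = ndimage.binary_erosion(
        roi, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool), border_value=0
    )
    return roi & ~interior


def _moore_trace(component: np.ndarray) -> list[tuple[int, int]]:
    """Clockwise Moore-neighbor boundary trace of one 8-connected
    component, starting at the lexicographically smallest boundary pixel
    and stopping on re-entering the start pixel from the initial
    direction (Jacob's criterion)."""
    pixels = np.argwhere(component)
    start = tuple(pixels[np.lexsort((pixels[:, 1], pixels[:, 0]))][0])
    shape = component.shape

    def inside(p):
        return 0 <= p[0] < shape[0] and 0 <= p[1] < shape[1] and component[p]

    path = [start]
    # entered the start pixel while scanning left-to-right: backtrack is to its left
    backtrack = (start[0], start[1] - 1)
    current = start
    first_move: tuple | None = None
    max_steps = 4 * (component.sum() + 4) * 8
    steps = 0
    while steps < max_steps:
        steps += 1
        # index of the backtrack direction in the Moore order
        db = (backtrack[0] - current[0], backtrack[1] - current[1])
        bi = _MOORE.index(db)
        nxt = None
        for j in range(1, 9):
            d = _MOORE[(bi + j) % 8]
            cand = (current[0] + d[0], current[1] + d[1])
            if inside(cand):
                nxt = cand
                prev = _MOORE[(bi + j - 1) % 8]
                new_backtrack = (current[0] + prev[0], current[1] + prev[1])
                break
        if nxt is None:  # isolated pixel
            break
        move = (nxt[0] - current[0], nxt[1] - current[1])
        if nxt == start:
            if first_move is None or move == first_move:
                break
        if current == start and first_move is None:
            first_move = move
        current, backtrack = nxt, new_backtrack
        path.append(current)
    # a trace of a 1-pixel-wide arm revisits pixels; keep first occurrences
    seen: set = set()
    deduped = []
    for p in path:
        if p not in seen:
            seen.add(p)
            deduped.append(p)
    return deduped


def trace_boundary(roi_slice: np.ndarray, min_area: int = 5) -> list[BoundaryPath]:
    """Trace the boundary of every 8-connected ROI component on a slice.

    Components smaller than ``min_area`` pixels are skipped. The path
    holds the ROI pixels with a face-neighbor outside the ROI, ordered
    by a clockwise Moore trace from the top-left boundary pixel.
    """
    roi = np.asarray(roi_slice).astype(bool)
    if not roi.any():
        return []
    lab, n = ndimage.label(roi, structure=_CONN8)
    boundary = face_boundary_pixels(roi)
    paths = []
    for cid in range(1, n + 1):
        comp = lab == cid
        if comp.sum() < min_area:
            continue
        traced = _moore_trace(comp)
        pts = [p for p in traced if boundary[p]]
        if pts:
            paths.append(BoundaryPath(slice_index=-1, points=pts, component_id=cid))
    return paths


def extract_rp(noss_slice: np.ndarray, roi_slice: np.ndarray, pad: int = 3) -> RPImage:
    """Crop the RP: ROI bounding box extended by ``pad`` pixels in both
    directions, clipped at the slice edges."""
    roi = np.asarray(roi_slice).astype(bool)
    if not roi.any():
        raise ValueError("empty ROI on slice")
    rows = np.any(roi, axis=1).nonzero()[0]
    cols = np.any(roi, axis=0).nonzero()[0]
    r0 = max(int(rows[0]) - pad, 0)
    r1 = min(int(rows[-1]) + pad, roi.shape[0] - 1)
    c0 = max(int(cols[0]) - pad, 0)
    c1 = min(int(cols[-1]) + pad, roi.shape[1] - 1)
    return RPImage(
        intensities=np.asarray(noss_slice, dtype=float)[r0 : r1 + 1, c0 : c1 + 1].copy(),
        origin=(r0, c0),
    )


def standardize_rp(rp: RPImage) -> RPImage:
    """Scale the RP so its maximum valid intensity is 1.

    An all-masked or all-zero RP is returned unchanged with the
    ``degenerate`` flag set.
    """
    if rp.standardized:
        raise ValueError("RP already standardized")
    vals = rp.intensities
    finite = np.isfinite(vals)
    vmax = np.max(vals[finite]) if finite.any() else 0.0
    if vmax <= 0:
        return RPImage(intensities=vals.copy(), origin=rp.origin, standardized=True, degenerate=True)
    return RPImage(intensities=vals / vmax, origin=rp.origin, standardized=True)


def _replicated_patch(vals: np.ndarray, r: int, c: int, size: int) -> np.ndarray:
    h = size // 2
    rows = np.clip(np.arange(r - h, r + h + 1), 0, vals.shape[0] - 1)
    cols = np.clip(np.arange(c - h, c + h + 1), 0, vals.shape[1] - 1)
    return vals[np.ix_(rows, cols)]


def _patch_from_values(point, size, values) -> Patch:
    finite = np.isfinite(values)
    if finite.any():
        v = values[finite]
        return Patch(point, size, values, float(v.min()), float(v.max()), float(v.mean()))
    return Patch(point, size, values, np.nan, np.nan, np.nan)


def select_patch(rp: RPImage, point: tuple[int, int], params: SIRParams) -> Patch:
    """Adaptive neighborhood patch at a boundary point (RP coordinates).

    The default 3x3 patch (center included) is kept unless its mean is
    within ``patch_escalation_threshold`` of the point intensity — too
    little boundary contrast — in which case the patch grows to 5x5.
    Entries overhanging the RP border are filled by edge replication;
    masked entries are excluded from the patch statistics.
    """
    if not rp.standardized:
        raise ValueError("RP must be standardized before patch selection")
    r, c = point
    vals = rp.intensities
    if not (0 <= r < vals.shape[0] and 0 <= c < vals.shape[1]):
        raise ValueError(f"point {point} outside RP of shape {vals.shape}")
    small = _patch_from_values(point, params.patch_size_default,
                               _replicated_patch(vals, r, c, params.patch_size_default))
    i_a = vals[r, c]
    if not np.isfinite(small.p_mean) or not np.isfinite(i_a) or (
        abs(small.p_mean - i_a) < params.patch_escalation_threshold
    ):
        return _patch_from_values(point, params.patch_size_large,
                                  _replicated_patch(vals, r, c, params.patch_size_large))
    return small


def classify_point(
    i_a: float,
    patch: Patch,
    rp_max: float,
    rp_min: float,
    params: SIRParams,
) -> tuple[bool, str]:
    """Evaluate the three non-adhesion conditions at one boundary point.

    Returns ``(non_adherent, fired_condition)`` with ``fired_condition``
    the first condition satisfied in the order I, II, III ("none" if
    adherent). Strict inequalities as stated; the boundary case
    |I(a) - patch mean| == tau falls to Condition III's gate.
    """
    if i_a > params.cond1_max_frac * rp_max or i_a < params.cond1_min_frac * rp_min:
        return True, "I"
    tau = params.cond2_tau_frac * (patch.p_max - patch.p_min)
    diff = abs(i_a - patch.p_mean)
    if diff > tau:
        return True, "II"
    if (patch.p_max - patch.p_min) > params.cond3_range_frac * i_a:
        return True, "III"
    return False, "none"


def adhesion_percentages(labels: list[PointLabel], n_unanalyzable: int = 0) -> AdhesionResult:
    """Pool point labels over all slices into the adhesion summary.

    The non-adhesion percentage is 100 * (# non-adherent points) /
    (# analyzable points), pooled across slices — not the mean of the
    per-slice percentages.
    """
    if not labels:
        raise ValueError("no analyzable boundary")
    per_slice: dict[int, list[int]] = {}
    cond_counts = {"I": 0, "II": 0, "III": 0}
    n_na = 0
    for lab in labels:
        s = lab.point[0]
        tally = per_slice.setdefault(s, [0, 0])
        tally[0] += 1
        if lab.non_adherent:
            tally[1] += 1
            n_na += 1
            cond_counts[lab.fired_condition] += 1
    n = len(labels)
    pct = 100.0 * n_na / n
    return AdhesionResult(
        per_slice=[(s, t[0], t[1]) for s, t in sorted(per_slice.items())],
        non_adhesion_pct=pct,
        adhesion_pct=100.0 - pct,
        condition_counts=cond_counts,
        n_points=n,
        n_unanalyzable=n_unanalyzable,
    )


def classify_slice(
    noss_slice: np.ndarray,
    roi_slice: np.ndarray,
    params: SIRParams | None = None,
) -> tuple[list[tuple[tuple[int, int], bool, str]], int]:
    """Classify every boundary point of one slice.

    Runs extract_rp -> standardize_rp -> trace_boundary, then
    select_patch + classify_point per boundary point. Returns
    ``(labels, n_unanalyzable)`` with labels as ((row, col),
    non_adherent, fired_condition) in trace order; points whose own
    NOSS is masked (or whose whole patch is) are counted unanalyzable.
    """
    params = params or SIRParams()
    paths = trace_boundary(roi_slice, min_area=params.min_roi_pixels_per_slice)
    if not paths:
        return [], 0
    rp = standardize_rp(extract_rp(noss_slice, roi_slice, pad=params.rp_pad_vox))
    finite = np.isfinite(rp.intensities)
    if not finite.any():
        return [], sum(len(p.points) for p in paths)
    rp_max = float(np.max(rp.intensities[finite]))
    rp_min = float(np.min(rp.intensities[finite]))
    r0, c0 = rp.origin
    labels: list[tuple[tuple[int, int], bool, str]] = []
    n_unanalyzable = 0
    for path in paths:
        for (r, c) in path.points:
            pr, pc = r - r0, c - c0
            i_a = rp.intensities[pr, pc]
            if not np.isfinite(i_a):
                n_unanalyzable += 1
                continue
            patch = select_patch(rp, (pr, pc), params)
            if not np.isfinite(patch.p_mean):
                n_unanalyzable += 1
                continue
            na, fired = classify_point(i_a, patch, rp_max, rp_min, params)
            labels.append(((r, c), na, fired))
    return labels, n_unanalyzable


def run_sir(
    noss: ScalarMap | np.ndarray,
    tumor_mask: np.ndarray,
    params: SIRParams | None = None,
) -> tuple[AdhesionResult, list[PointLabel], np.ndarray]:
    """Run SIR over every axial slice of a tumor.

    For each slice whose ROI area passes ``min_roi_pixels_per_slice``:
    extract and standardize the RP, trace the boundary, and classify
    every boundary point. Returns the pooled :class:`AdhesionResult`,
    the per-point labels, and a label volume for overlay rendering
    (0 = non-boundary, 1 = adherent, 2 = non-adherent).
    """
    params = params or SIRParams()
    vol = noss.values if isinstance(noss, ScalarMap) else np.asarray(noss, dtype=float)
    mask = np.asarray(tumor_mask).astype(bool)
    if vol.shape != mask.shape:
        raise ValueError(f"NOSS grid {vol.shape} does not match mask grid {mask.shape}")
    labels: list[PointLabel] = []
    label_volume = np.zeros(vol.shape, dtype=np.uint8)
    n_unanalyzable = 0
    any_slice = False
    for z in range(vol.shape[2]):
        roi = mask[:, :, z]
        if roi.sum() < params.min_roi_pixels_per_slice:
            continue
        slice_labels, n_bad = classify_slice(vol[:, :, z], roi, params)
        n_unanalyzable += n_bad
        if slice_labels or n_bad:
            any_slice = True
        for (r, c), na, fired in slice_labels:
            labels.append(PointLabel(point=(z, r, c), non_adherent=na, fired_condition=fired))
            label_volume[r, c, z] = 2 if na else 1
    if not any_slice:
        raise ValueError("no slice passes the ROI area filter")
    if not labels:
        raise ValueError("no analyzable boundary")
    return adhesion_percentages(labels, n_unanalyzable), labels, label_volume
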