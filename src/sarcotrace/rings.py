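"""Larval M-band ring quantification.

During larval muscle growth, M-bands open into Y-shaped branches that
appear as elliptical "rings" in single slices.  Each ring is annotated by
four manual landmarks: the two junctions where the ring rejoins the
M-band above and below, and the two lateral outermost points.  The ring
diameter is the projection of the lateral–lateral segment onto the
direction perpendicular to the junction–junction line.  Sallimus and
Obscurin content is measured by 2 μm line scans along the lateral line —
centered at the two lateral points and their midpoint — each averaged over
parallel scans spanning an effective thickness of 50% (Sls) or 25%
(Obscurin) of the ring height, minimum-subtracted, and normalized by the
mean of four reference scans across bands outside the ring.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

#: effective scan thickness as a fraction of ring height, per channel
THICKNESS_FRACTION = {"sls": 0.50, "obscurin": 0.25}

#: scan length in μm
SCAN_LENGTH_UM = 2.0


@dataclass
class RingLandmarks:
    """Four manual landmarks of one ring, (x, y) in μm."""

    junction_top: tuple[float, float]
    junction_bottom: tuple[float, float]
    lateral_left: tuple[float, float]
    lateral_right: tuple[float, float]

    def __post_init__(self):
        pts = [tuple(map(float, p)) for p in
               (self.junction_top, self.junction_bottom,
                self.lateral_left, self.lateral_right)]
        (self.junction_top, self.junction_bottom,
         self.lateral_left, self.lateral_right) = pts
        if len(set(pts)) != 4:
            raise ValueError("ring landmarks must be four distinct points")

    @property
    def height(self) -> float:
        """Junction-to-junction distance, used as the ring height."""
        return float(np.linalg.norm(np.subtract(self.junction_top, self.junction_bottom)))


@dataclass
class ReferenceScan:
    """A reference band scan: center point, optional direction and thickness.

    ``direction=None`` uses the measured scans' direction (along the
    lateral–lateral line); ``thickness_um=None`` uses the measured scans'
    thickness.
    """

    center: tuple[float, float]
    direction: tuple[float, float] | None = None
    thickness_um: float | None = None


def ring_diameter(landmarks: RingLandmarks) -> float:
    """Diameter = |projection of (lateral_right - lateral_left) ⊥ junction axis|."""
    j = np.subtract(landmarks.junction_top, landmarks.junction_bottom)
    norm = np.linalg.norm(j)
    if norm == 0:
        raise ValueError("coincident junctions: perpendicular direction undefined")
    perp = np.array([-j[1], j[0]]) / norm
    lat = np.subtract(landmarks.lateral_right, landmarks.lateral_left)
    return float(abs(np.dot(lat, perp)))


def _scan_total(
    image: np.ndarray,
    center: np.ndarray,
    direction: np.ndarray,
    thickness_um: float,
    pitch: float,
    length_um: float = SCAN_LENGTH_UM,
) -> float:
    """Minimum-subtracted total of one averaged multi-line scan.

    The scan runs ``length_um`` along ``direction`` centered at ``center``;
    parallel scans offset along the perpendicular span ``thickness_um`` and
    are averaged into a single profile before the per-scan minimum is
    subtracted and the profile summed.
    """
    u = direction / np.linalg.norm(direction)
    nvec = np.array([-u[1], u[0]])
    n_along = max(2, int(round(length_um / pitch)) + 1)
    s = (np.linspace(0.0, length_um, n_along) - length_um / 2.0)
    n_par = max(1, int(round(thickness_um / pitch)))
    offsets = (np.arange(n_par) - (n_par - 1) / 2.0) * pitch
    ny, nx = image.shape
    acc = np.zeros(n_along)
    for off in offsets:
        pts = center[None, :] + s[:, None] * u[None, :] + off * nvec[None, :]
        rows = np.clip(pts[:, 1] / pitch, 0, ny - 1)
        cols = np.clip(pts[:, 0] / pitch, 0, nx - 1)
        acc += map_coordinates(image, np.stack([rows, cols]), order=1, mode="nearest")
    profile = acc / n_par
    profile = profile - profile.min()
    return float(profile.sum())


def ring_normalized_intensity(
    image: np.ndarray,
    landmarks: RingLandmarks,
    channel: str,
    reference_scans: list[ReferenceScan],
    pitch: float,
) -> tuple[float, float, float]:
    """Normalized (left, center, right) band intensities of one ring.

    Three 2 μm scans along the lateral–lateral line, centered at the left
    lateral point, the midpoint, and the right lateral point, are each
    minimum-subtracted and totalled, then divided by the mean total of the
    four reference scans.  Minimum subtraction makes the result invariant
    to constant offsets; the ratio removes global intensity scale.
    """
    if channel not in THICKNESS_FRACTION:
        raise ValueError(f"channel must be one of {sorted(THICKNESS_FRACTION)}")
    if len(reference_scans) != 4:
        raise ValueError("exactly four reference scans are required")
    ll = np.asarray(landmarks.lateral_left)
    lr = np.asarray(landmarks.lateral_right)
    u = lr - ll
    if np.linalg.norm(u) == 0:
        raise ValueError("coincident lateral points")
    thickness = THICKNESS_FRACTION[channel] * landmarks.height
    centers = [ll, 0.5 * (ll + lr), lr]
    totals = [_scan_total(image, c, u, thickness, pitch) for c in centers]

    ref_totals = []
    for ref in reference_scans:
        d = np.asarray(ref.direction, dtype=float) if ref.direction is not None else u
        th = ref.thickness_um if ref.thickness_um is not None else thickness
        ref_totals.append(_scan_total(image, np.asarray(ref.center, dtype=float), d, th, pitch))
    ref_mean = float(np.mean(ref_totals))
    if ref_mean <= 0:
        raise ValueError("reference scans have zero total intensity")
    left, center, right = (t / ref_mean for t in totals)
    return left, center, right


def bin_rings(diameters: list[float]) -> dict[str, int]:
    """Count rings in the diameter bins small < 4 μm, medium 4–6 μm, large > 6 μm.

    Boundary convention follows the printed labels: [0, 4), [4, 6], (6, ∞).
    """
    counts = {"small": 0, "medium": 0, "large": 0}
    for d in diameters:
        if d < 0:
            raise ValueError("diameters must be non-negative")
        if d < 4.0:
            counts["small"] += 1
        elif d <= 6.0:
            counts["medium"] += 1
        else:
            counts["large"] += 1
    return counts


def ring_bin_label(diameter: float) -> str:
    """Bin label of a single ring diameter (same convention as bin_rings)."""
    if diameter < 4.0:
        return "small"
    return "medium" if diameter <= 6.0 else "large"
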