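"""Synthetic microscopy inputs with known ground truth.

Every pipeline stage can be exercised without any real data: this module
renders multichannel flight-muscle z-stacks with parallel myofibrils,
dividing-sarcomere intensity profiles built from two rigid daughter
blocks, exponential FRAP recovery series, Bernoulli-labeled line scans,
and larval M-band ring images — each together with the ground truth that
produced it.

Image formation model
---------------------
Myofibrils run along x and are offset laterally by ≥ 1 μm.  Per channel the
axial intensity is: Gaussian bands at the Z-discs (Sls and actin, the actin
additionally carries a plateau across the sarcomere), a boxcar A-band
(Mhc) with a central Gaussian M-band (Obscurin).  Dividing sarcomeres are
rendered as two rigid daughter blocks — (Z1, M1, S1) and (Z2, M2, S2) —
whose internal spacings are fixed while their mutual separation grows
one-to-one with sarcomere length, with nascent Sls bands at S1/S2.  The
axial profile is multiplied by a radial Gaussian cross-section, blurred
with an anisotropic Gaussian PSF (default σxy = 0.1 μm, σz = 0.3 μm), and,
for noise_sd > 0, degraded with Poisson shot noise plus additive Gaussian
noise; the Sls channel can carry a planted integer pixel shift emulating
chromatic aberration.

Randomness
----------
All draws flow from one explicit seed through a documented splitting
scheme: ``default_rng([seed, k])`` with k = 0 for the division Bernoulli
draws, k = 1 for division geometry (separation / asymmetry), k = 2 for
noise.  Identical seeds and parameters give bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ._util import gauss, shift2d
from .dynamics import FrapSeries, frap_model
from .pairstats import LineScanLabels
from .rings import ReferenceScan, RingLandmarks
from .stack import CHANNELS, FLIGHT_PITCH, LARVAL_PITCH, VoxelStack

# -- geometry defaults (μm) -------------------------------------------------
Z_SIGMA = 0.08           # axial σ of the Z-disc band
RADIAL_SIGMA = 0.25      # myofibril cross-section σ
OBS_SIGMA = 0.08         # axial σ of the Obscurin M-band
I_BAND_HALF = 0.35       # Z-disc to A-band edge distance in a regular sarcomere
ACTIN_PLATEAU = 0.35     # actin amplitude across the sarcomere
NEW_Z_AMP = 0.55         # amplitude of the nascent Sls bands (S1/S2)
DEFAULT_PSF = (0.1, 0.3)  # (σxy, σz) μm


@dataclass
class DivisionState:
    dividing: bool
    separation: float = 0.0   # μm the daughter blocks have moved apart
    asymmetry: float = 0.5    # fraction of material in the smaller block


@dataclass
class GroundTruth:
    """Everything the generator knows about a synthetic dataset."""

    zdisc_positions: list[list[tuple[float, float, float]]]  # per myofibril, μm
    sarcomere_lengths: list[list[float]]
    division_states: list[list[DivisionState]]
    planted_shift: tuple[int, int] = (0, 0)
    frap_params: tuple[float, float] | None = None
    scan_labels: list[np.ndarray] | None = None

    def __post_init__(self):
        for chain in self.zdisc_positions:
            xs = [p[0] for p in chain]
            if any(b <= a for a, b in zip(xs[:-1], xs[1:])):
                raise ValueError("Z-disc positions must be strictly ordered along x")
        for chain in self.sarcomere_lengths:
            if any(l <= 0 for l in chain):
                raise ValueError("sarcomere lengths must be positive")
        self.planted_shift = (int(self.planted_shift[0]), int(self.planted_shift[1]))

    def all_zdiscs(self) -> np.ndarray:
        return np.array([p for chain in self.zdisc_positions for p in chain])

    def all_lengths(self) -> np.ndarray:
        return np.array([l for chain in self.sarcomere_lengths for l in chain])


@dataclass
class DivisionProfiles:
    """Replicate division profiles for one sarcomere length."""

    length: float
    s_grid: np.ndarray
    landmarks_um: dict[str, float]      # measured from the Z1 end
    replicates: list[dict[str, np.ndarray]]


def division_rngs(seed: int):
    """The documented seed-splitting scheme of :func:`make_flight_stack`."""
    return (np.random.default_rng([seed, 0]),   # division Bernoulli draws
            np.random.default_rng([seed, 1]),   # division geometry
            np.random.default_rng([seed, 2]))   # noise


def _dividing_block_geometry(base_length: float) -> tuple[float, float]:
    """(daughter A-band width, Z-to-M distance) for a mother of base_length."""
    a_width = base_length - 2 * I_BAND_HALF
    w = a_width / 2.0
    d_zm = I_BAND_HALF + w / 2.0
    return w, d_zm


def make_flight_stack(
    n_myofibrils: int = 3,
    n_sarcomeres: int = 10,
    sarcomere_length: float = 2.0,
    dividing_fraction: float = 0.0,
    psf_sigma: tuple[float, float] = DEFAULT_PSF,
    noise_sd: float = 0.0,
    planted_shift: tuple[int, int] = (0, 0),
    seed: int = 0,
    pitch: tuple[float, float, float] = FLIGHT_PITCH,
    lateral_spacing: float = 1.2,
    depth: float = 2.0,
    margin: float = 1.0,
    separation_range: tuple[float, float] = (0.5, 1.3),
    asymmetry_range: tuple[float, float] = (0.25, 0.5),
    photons: float = 500.0,
    division_spacing: float = 0.4,
) -> tuple[VoxelStack, GroundTruth]:
    """Render a four-channel flight-muscle stack with known ground truth.

    Dividing sarcomeres are drawn per sarcomere as Bernoulli(dividing_fraction)
    (rng ``[seed, 0]``); their block separations and asymmetries come from rng
    ``[seed, 1]``, noise from rng ``[seed, 2]``.  ``division_spacing`` is the
    fixed M-to-S distance within each rigid daughter block.  With
    noise_sd = 0 the output is noise-free (no shot noise either), so all
    rendered landmarks coincide with the ground truth up to the PSF blur.
    """
    if n_sarcomeres < 2:
        raise ValueError("need at least 2 sarcomeres per myofibril")
    if sarcomere_length <= 0 or depth <= 0 or margin <= 0:
        raise ValueError("geometry parameters must be positive")
    if not 0 <= dividing_fraction <= 1:
        raise ValueError("dividing_fraction must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if lateral_spacing < 1.0:
        raise ValueError("myofibrils must be offset by at least 1 μm")

    rng_div, rng_geom, rng_noise = division_rngs(seed)
    flags = rng_div.random((n_myofibrils, n_sarcomeres)) < dividing_fraction
    seps = rng_geom.uniform(*separation_range, (n_myofibrils, n_sarcomeres))
    asyms = rng_geom.uniform(*asymmetry_range, (n_myofibrils, n_sarcomeres))

    lengths = np.full((n_myofibrils, n_sarcomeres), float(sarcomere_length))
    lengths[flags] += seps[flags]

    dx, dy, dz = pitch
    x_total = 2 * margin + float(lengths.sum(axis=1).max())
    nx = int(np.ceil(x_total / dx)) + 1
    ny = int(np.ceil((2 * margin + (n_myofibrils - 1) * lateral_spacing) / dy)) + 1
    nz = int(np.round(depth / dz)) + 1
    x_grid = np.arange(nx) * dx
    y_grid = np.arange(ny) * dy
    z_grid = np.arange(nz) * dz
    z_center = (nz - 1) * dz / 2.0

    w_reg = sarcomere_length - 2 * I_BAND_HALF          # regular A-band width
    w_div, d_zm = _dividing_block_geometry(sarcomere_length)

    vol = np.zeros((len(CHANNELS), nz, ny, nx), dtype=np.float32)
    zdiscs_gt, lengths_gt, states_gt = [], [], []
    for m in range(n_myofibrils):
        y_m = margin + m * lateral_spacing
        axial = {ch: np.zeros(nx) for ch in CHANNELS}
        x0 = margin
        chain_z = [(x0, y_m, z_center)]
        chain_len, chain_state = [], []
        x_left = x0
        for j in range(n_sarcomeres):
            L = float(lengths[m, j])
            a, b = x_left, x_left + L
            axial["sls"] += gauss(x_grid, a, Z_SIGMA)
            axial["actin"] += gauss(x_grid, a, Z_SIGMA)
            axial["actin"] += ACTIN_PLATEAU * ((x_grid >= a) & (x_grid <= b))
            if not flags[m, j]:
                lo, hi = a + I_BAND_HALF, b - I_BAND_HALF
                axial["mhc"] += ((x_grid >= lo) & (x_grid <= hi)).astype(float)
                axial["obscurin"] += gauss(x_grid, (a + b) / 2.0, OBS_SIGMA)
                chain_state.append(DivisionState(dividing=False))
            else:
                asym = float(asyms[m, j])
                amp1, amp2 = 2 * (1 - asym), 2 * asym
                m1, m2 = a + d_zm, b - d_zm
                s1, s2 = m1 + division_spacing, m2 - division_spacing
                axial["mhc"] += amp1 * ((x_grid >= m1 - w_div / 2) & (x_grid <= m1 + w_div / 2))
                axial["mhc"] += amp2 * ((x_grid >= m2 - w_div / 2) & (x_grid <= m2 + w_div / 2))
                axial["obscurin"] += amp1 * gauss(x_grid, m1, OBS_SIGMA)
                axial["obscurin"] += amp2 * gauss(x_grid, m2, OBS_SIGMA)
                axial["sls"] += NEW_Z_AMP * amp1 * gauss(x_grid, s1, Z_SIGMA)
                axial["sls"] += NEW_Z_AMP * amp2 * gauss(x_grid, s2, Z_SIGMA)
                chain_state.append(DivisionState(dividing=True,
                                                 separation=float(seps[m, j]),
                                                 asymmetry=asym))
            chain_z.append((b, y_m, z_center))
            chain_len.append(L)
            x_left = b
        # terminal Z-disc of the chain
        axial["sls"] += gauss(x_grid, x_left, Z_SIGMA)
        axial["actin"] += gauss(x_grid, x_left, Z_SIGMA)

        wy = gauss(y_grid, y_m, RADIAL_SIGMA)
        wz = gauss(z_grid, z_center, RADIAL_SIGMA)
        radial = wz[:, None] * wy[None, :]
        for ci, ch in enumerate(CHANNELS):
            vol[ci] += (radial[:, :, None] * axial[ch][None, None, :]).astype(np.float32)
        zdiscs_gt.append(chain_z)
        lengths_gt.append(chain_len)
        states_gt.append(chain_state)

    sx, sy_, sz = psf_sigma[0] / dx, psf_sigma[0] / dy, psf_sigma[1] / dz
    for ci in range(len(CHANNELS)):
        vol[ci] = gaussian_filter(vol[ci], sigma=(sz, sy_, sx))

    if noise_sd > 0:
        noisy = rng_noise.poisson(np.clip(vol, 0, None) * photons) / photons
        noisy = noisy + rng_noise.normal(0.0, noise_sd, vol.shape)
        vol = np.clip(noisy, 0.0, None).astype(np.float32)

    shift = (int(planted_shift[0]), int(planted_shift[1]))
    if shift != (0, 0):
        ci = CHANNELS.index("sls")
        vol[ci] = np.stack([shift2d(vol[ci, iz], shift) for iz in range(nz)])

    stack = VoxelStack(intensities=vol, pitch=pitch, channel_names=CHANNELS)
    gt = GroundTruth(zdisc_positions=zdiscs_gt, sarcomere_lengths=lengths_gt,
                     division_states=states_gt, planted_shift=shift)
    return stack, gt


def make_division_profiles(
    length_grid: list[float],
    asymmetry: float = 0.35,
    intra_block_spacing: tuple[float, float] = (0.675, 0.4),
    n_samples: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
    resolution: int = 100,
    mhc_block_width: float = 0.65,
    recruitment: float = 0.0,
) -> list[DivisionProfiles]:
    """Rigid-block division profiles over s ∈ [0, 1] with true landmarks.

    For each length L the daughter blocks (Z1, M1, S1) and (Z2, M2, S2)
    keep the internal spacings ``intra_block_spacing = (Z-to-M, M-to-S)``
    fixed, so their mutual separation — e.g. the M1–S2 distance — grows
    exactly one-to-one with L.  ``asymmetry`` ∈ (0, 0.5] is the intensity
    share of the smaller daughter block; 0.5 renders a mirror-symmetric
    profile.  ``n_samples`` is the number of noisy replicate profiles per
    length; ``resolution`` the number of s samples per profile.
    ``recruitment`` scales all amplitudes by (1 + recruitment·(L − L_min)),
    emulating protein recruitment during division.  Lengths below 2.2 μm
    are rejected: no division geometry is defined there.
    """
    lengths = [float(L) for L in length_grid]
    if any(L < 2.2 for L in lengths):
        raise ValueError("division profiles are undefined below 2.2 μm")
    if not 0 < asymmetry <= 0.5:
        raise ValueError("asymmetry must lie in (0, 0.5]")
    d_zm, d_ms = (float(v) for v in intra_block_spacing)
    if min(lengths) <= 2 * (d_zm + d_ms):
        raise ValueError("intra-block spacing too large for the shortest length "
                         "(S1 and S2 would cross)")
    rng = np.random.default_rng([seed, 3])
    s = np.linspace(0.0, 1.0, resolution)
    amp1, amp2 = 2 * (1 - asymmetry), 2 * asymmetry
    l_min = min(lengths)
    out = []
    for L in lengths:
        scale = 1.0 + recruitment * (L - l_min)
        marks = {"Z1": 0.0, "M1": d_zm, "S1": d_zm + d_ms,
                 "S2": L - d_zm - d_ms, "M2": L - d_zm, "Z2": L}
        sig_z, sig_o = Z_SIGMA / L, OBS_SIGMA / L
        half_w = mhc_block_width / 2.0 / L
        pos = {k: v / L for k, v in marks.items()}
        sls = gauss(s, pos["Z1"], sig_z) + gauss(s, pos["Z2"], sig_z)
        sls += NEW_Z_AMP * (amp1 * gauss(s, pos["S1"], sig_z)
                            + amp2 * gauss(s, pos["S2"], sig_z))
        obs = amp1 * gauss(s, pos["M1"], sig_o) + amp2 * gauss(s, pos["M2"], sig_o)
        mhc = amp1 * ((s >= pos["M1"] - half_w) & (s <= pos["M1"] + half_w)).astype(float)
        mhc += amp2 * ((s >= pos["M2"] - half_w) & (s <= pos["M2"] + half_w)).astype(float)
        actin = ACTIN_PLATEAU + gauss(s, pos["Z1"], sig_z) + gauss(s, pos["Z2"], sig_z)
        actin += 0.3 * (amp1 * gauss(s, pos["S1"], sig_z) + amp2 * gauss(s, pos["S2"], sig_z))
        clean = {"actin": actin * scale, "sls": sls * scale,
                 "mhc": mhc * scale, "obscurin": obs * scale}
        reps = []
        for _ in range(max(1, int(n_samples))):
            reps.append({ch: np.clip(v + rng.normal(0.0, noise_sd, resolution), 0.0, None)
                         for ch, v in clean.items()})
        out.append(DivisionProfiles(length=L, s_grid=s.copy(),
                                    landmarks_um=marks, replicates=reps))
    return out


def make_frap_series(
    i_max: float = 0.55,
    t_half: float = 30.0,
    t_end: float = 120.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FrapSeries:
    """Exponential FRAP recovery series starting at t = 0."""
    if i_max <= 0 or t_half <= 0 or dt <= 0:
        raise ValueError("i_max, t_half and dt must be positive")
    if t_end < dt:
        raise ValueError("t_end must be at least dt")
    rng = np.random.default_rng([seed, 4])
    times = np.arange(0.0, t_end + dt / 2.0, dt)
    ratio = frap_model(times, i_max, t_half)
    if noise_sd > 0:
        ratio = ratio + rng.normal(0.0, noise_sd, len(times))
    outside = np.ones_like(times)
    return FrapSeries(times=times, inside=ratio * outside, outside=outside)


def make_label_scans(
    scan_lengths: tuple[int, ...],
    n_pronounced: int,
    seed: int = 0,
    spacing: float = 2.0,
) -> LineScanLabels:
    """Bernoulli-labeled line scans with exactly ``n_pronounced`` flags.

    Flags are placed uniformly at random without replacement across the
    concatenation of all scans.  Mhc max/total intensities are drawn so that
    pronounced sarcomeres exceed the rest in both quantities.
    """
    scan_lengths = tuple(int(n) for n in scan_lengths)
    if not scan_lengths:
        raise ValueError("at least one scan is required")
    total = sum(scan_lengths)
    if n_pronounced > total:
        raise ValueError("cannot place more pronounced flags than sarcomeres")
    rng = np.random.default_rng([seed, 5])
    flat = np.zeros(total, dtype=bool)
    flat[rng.choice(total, size=n_pronounced, replace=False)] = True
    # peak shape is stereotyped, so total ~ width x max with small shape
    # jitter; pronounced sarcomeres exceed the rest in both quantities
    mx = rng.uniform(0.2, 0.5, total) + flat * rng.uniform(0.8, 1.2, total)
    tot = mx * rng.uniform(3.9, 4.1, total)
    positions, maxima, totals, flags = [], [], [], []
    off = 0
    for n in scan_lengths:
        positions.append(np.arange(n) * spacing + spacing / 2.0)
        maxima.append(mx[off:off + n])
        totals.append(tot[off:off + n])
        flags.append(flat[off:off + n])
        off += n
    return LineScanLabels(positions=positions, mhc_max=maxima,
                          mhc_total=totals, pronounced=flags)


def render_scan_profiles(
    labels: LineScanLabels,
    spacing: float = 2.0,
    pitch: float = LARVAL_PITCH[0],
    peak_sigma: float = 0.15,
    margin: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Render label scans into Sls / Mhc intensity profiles.

    Sls peaks sit at the sarcomere boundaries (n + 1 peaks for n
    sarcomeres); each sarcomere contributes a central Mhc Gaussian whose
    amplitude is its ``mhc_max``.  Feeding the result through
    ``pairstats.detect_scan_sarcomeres`` recovers the sarcomere count.
    """
    rng = np.random.default_rng([seed, 6])
    sls_profiles, mhc_profiles = [], []
    for k, n in enumerate(labels.scan_lengths):
        length = 2 * margin + n * spacing
        x = np.arange(0.0, length, pitch)
        sls = np.zeros_like(x)
        mhc = np.zeros_like(x)
        for i in range(n + 1):
            sls += gauss(x, margin + i * spacing, peak_sigma)
        for i in range(n):
            center = margin + (i + 0.5) * spacing
            mhc += labels.mhc_max[k][i] * gauss(x, center, peak_sigma * 1.5)
        if noise_sd > 0:
            sls = np.clip(sls + rng.normal(0, noise_sd, len(x)), 0, None)
            mhc = np.clip(mhc + rng.normal(0, noise_sd, len(x)), 0, None)
        sls_profiles.append(sls)
        mhc_profiles.append(mhc)
    return sls_profiles, mhc_profiles


@dataclass
class RingFixture:
    """A synthetic two-channel ring image with landmarks and reference scans."""

    images: dict[str, np.ndarray]          # 'obscurin' and 'sls', (ny, nx)
    landmarks: RingLandmarks
    reference_scans: list[ReferenceScan]
    pitch: float
    center_sls_fraction: float


def make_ring_image(
    diameter: float,
    height: float = 2.0,
    band_intensity: float = 1.0,
    center_sls_fraction: float = 0.5,
    pitch: float = LARVAL_PITCH[0],
    noise_sd: float = 0.0,
    seed: int = 0,
    band_sigma: float = 0.1,
) -> RingFixture:
    """Render an elliptical M-band ring with vertical Sls/Obscurin bands.

    The ring (Obscurin channel) is an ellipse of the given diameter
    (horizontal) and height (vertical, junction to junction), continuing
    into vertical M-band stems above and below the junctions.  The Sls
    channel carries a central vertical band through the ring center whose
    intensity is ``center_sls_fraction`` of the reference bands.  Four
    uniform vertical reference bands flank the ring in both channels; the
    returned reference scans point at them.
    """
    if diameter <= 0 or height <= 0:
        raise ValueError("diameter and height must be positive")
    if center_sls_fraction < 0:
        raise ValueError("center_sls_fraction must be non-negative")
    a, b = diameter / 2.0, height / 2.0
    # reference bands spaced so a 2 μm scan sees exactly one band and the
    # lateral measurement scans (spanning ±1 μm around the laterals) see none
    ref_off = (a + 1.4, a + 2.8)
    half_w = ref_off[1] + 1.4
    half_h = b + 1.2
    nx = int(np.ceil(2 * half_w / pitch)) + 1
    ny = int(np.ceil(2 * half_h / pitch)) + 1
    xc, yc = (nx - 1) * pitch / 2.0, (ny - 1) * pitch / 2.0
    x = np.arange(nx) * pitch
    y = np.arange(ny) * pitch
    X, Y = np.meshgrid(x - xc, y - yc)

    # elliptical ring with a Gaussian wall profile (physical wall width)
    r_norm = np.sqrt((X / a) ** 2 + (Y / b) ** 2)
    wall_scale = min(a, b)
    ring = band_intensity * np.exp(-0.5 * ((r_norm - 1.0) * wall_scale / band_sigma) ** 2)
    stems = band_intensity * np.exp(-0.5 * (X / band_sigma) ** 2) * (np.abs(Y) >= b)
    obscurin = ring + stems

    def vertical_band(x_off, amp, y_mask=None):
        band = amp * np.exp(-0.5 * ((X - x_off) / band_sigma) ** 2)
        if y_mask is not None:
            band = band * y_mask
        return band

    sls = vertical_band(0.0, center_sls_fraction * band_intensity,
                        y_mask=(np.abs(Y) <= 0.9 * b))
    refs = []
    for sign in (-1, 1):
        for off in ref_off:
            sls = sls + vertical_band(sign * off, band_intensity)
            obscurin = obscurin + vertical_band(sign * off, band_intensity)
            refs.append(ReferenceScan(center=(xc + sign * off, yc)))

    if noise_sd > 0:
        rng = np.random.default_rng([seed, 7])
        sls = np.clip(sls + rng.normal(0, noise_sd, sls.shape), 0, None)
        obscurin = np.clip(obscurin + rng.normal(0, noise_sd, obscurin.shape), 0, None)

    landmarks = RingLandmarks(
        junction_top=(xc, yc + b),
        junction_bottom=(xc, yc - b),
        lateral_left=(xc - a, yc),
        lateral_right=(xc + a, yc),
    )
    return RingFixture(images={"obscurin": obscurin, "sls": sls},
                       landmarks=landmarks, reference_scans=refs,
                       pitch=pitch, center_sls_fraction=center_sls_fraction)
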