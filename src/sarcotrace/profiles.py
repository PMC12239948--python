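"""Per-sarcomere intensity profiles, length bins, and landmark analysis.

Each sarcomere is parameterized by a sarcomere coordinate s ∈ [0, 1] with
the bounding Z-discs at s = 0 and s = 1.  Raw per-channel profiles are
trilinear samples of the stack along the Z-disc–to–Z-disc segment; they are
normalized by the maximum of a smoothed copy (moving average, window 1/10
of the sarcomere length) and oriented so that the total Obscurin intensity
in the left half (s ≤ 1/2) is maximal.  Oriented, normalized profiles are
pooled into half-open length bins; per-bin mean profiles yield the six
landmarks Z1, S1, M1, M2, S2, Z2 of dividing sarcomeres, whose pairwise
distance trends against sarcomere length quantify rigid-block daughter
separation (M1–S2 and M2–S1 grow with slope ≈ 1 while Z1–M1 and Z2–M2 stay
constant).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from ._util import moving_average, parabolic_refine
from .stack import VoxelStack
from .trace import CandidateSarcomere, sample_channel
from .zdisc import ZDisc

#: default half-open length bin edges in μm; [1.8, 2.2) is the "regular" bin
DEFAULT_BIN_EDGES = (1.8, 2.2, 2.4, 2.6, 3.0, 3.4)

#: the six division landmarks in axial order after orientation
LANDMARK_NAMES = ("Z1", "S1", "M1", "M2", "S2", "Z2")

#: distance pairs whose trends against length are reported
TREND_PAIRS = ("Z1-M1", "Z2-M2", "M1-S2", "M2-S1", "M1-M2", "S1-S2")


@dataclass
class SarcomereProfile:
    s_grid: np.ndarray
    channels: dict[str, np.ndarray]
    length: float
    oriented: bool = False
    normalized: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class LandmarkPeaks:
    """Positions (μm from the Z1 end) and intensities of the six landmarks."""

    positions: dict[str, float]
    intensities: dict[str, float]
    length: float
    flags: list[str] = field(default_factory=list)

    def distance(self, pair: str) -> float:
        a, b = pair.split("-")
        return abs(self.positions[b] - self.positions[a])


@dataclass
class LengthBin:
    low: float
    high: float
    members: list[SarcomereProfile]

    @property
    def mean_length(self) -> float:
        return float(np.mean([m.length for m in self.members])) if self.members else np.nan


def extract_profile(
    sarcomere: CandidateSarcomere,
    stack: VoxelStack,
    zdiscs: list[ZDisc],
    n_samples: int = 100,
    channels: tuple[str, ...] | None = None,
) -> SarcomereProfile:
    """Raw per-channel profile by trilinear interpolation at n equidistant s."""
    by_id = {d.id: d for d in zdiscs}
    p0 = by_id[sarcomere.id_a].position
    p1 = by_id[sarcomere.id_b].position
    s = np.linspace(0.0, 1.0, n_samples)
    pts = p0[None, :] + s[:, None] * (p1 - p0)[None, :]
    names = channels if channels is not None else stack.channel_names
    out = {}
    flags = []
    for ch in names:
        vals, oob = sample_channel(stack, ch, pts)
        if oob and "out_of_bounds" not in flags:
            flags.append("out_of_bounds")
        out[ch] = np.asarray(vals, dtype=float)
    return SarcomereProfile(s_grid=s, channels=out, length=sarcomere.length, flags=flags)


def normalize_profile(profile: SarcomereProfile, window_fraction: float = 0.1) -> SarcomereProfile:
    """Divide each channel by the max of its moving-average-smoothed copy.

    The window is ``round(n_samples * window_fraction)`` samples (1/10 of the
    sarcomere length by default) and shrinks to valid samples at the ends.
    All-zero channels are left at zero and flagged.  The operation is
    idempotent up to the smoothing-max scale and invariant to rescaling the
    raw intensities.
    """
    n = len(profile.s_grid)
    window = max(1, round(n * window_fraction))
    channels = {}
    flags = list(profile.flags)
    for ch, raw in profile.channels.items():
        if np.any(raw < 0):
            raise ValueError("profiles must be non-negative")
        smooth_max = moving_average(raw, window).max()
        if smooth_max <= 0:
            channels[ch] = raw.copy()
            flags.append(f"all_zero:{ch}")
        else:
            channels[ch] = raw / smooth_max
    return SarcomereProfile(s_grid=profile.s_grid.copy(), channels=channels,
                            length=profile.length, oriented=profile.oriented,
                            normalized=True, flags=flags)


def orient_profile(profile: SarcomereProfile, channel: str = "obscurin") -> SarcomereProfile:
    """Reverse the profile iff the left half holds less Obscurin than the right.

    The left half is s ∈ [0, 1/2]; exact ties keep the input order, so the
    oriented output always satisfies left-half total ≥ right-half total.
    """
    if channel not in profile.channels:
        raise ValueError(f"orientation channel {channel!r} missing")
    obs = profile.channels[channel]
    left = float(obs[profile.s_grid <= 0.5].sum())
    right = float(obs[profile.s_grid > 0.5].sum())
    if left >= right:
        return SarcomereProfile(s_grid=profile.s_grid.copy(),
                                channels={c: v.copy() for c, v in profile.channels.items()},
                                length=profile.length, oriented=True,
                                normalized=profile.normalized, flags=list(profile.flags))
    return SarcomereProfile(s_grid=profile.s_grid.copy(),
                            channels={c: v[::-1].copy() for c, v in profile.channels.items()},
                            length=profile.length, oriented=True,
                            normalized=profile.normalized, flags=list(profile.flags))


def bin_by_length(
    profiles: list[SarcomereProfile],
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
) -> tuple[list[LengthBin], int]:
    """Sort profiles into half-open [low, high) length bins.

    Returns the bins and the number of profiles outside [edges[0], edges[-1]).
    """
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges[:-1], edges[1:])):
        raise ValueError("bin edges must be strictly ascending")
    bins = [LengthBin(low, high, []) for low, high in zip(edges[:-1], edges[1:])]
    excluded = 0
    for p in profiles:
        idx = np.searchsorted(edges, p.length, side="right") - 1
        if 0 <= idx < len(bins) and p.length < edges[-1]:
            bins[idx].members.append(p)
        else:
            excluded += 1
    return bins, excluded


def mean_profile(bin_: LengthBin) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pointwise mean and SD per channel over the bin members."""
    if not bin_.members:
        raise ValueError("cannot average an empty length bin")
    channels = bin_.members[0].channels.keys()
    out = {}
    for ch in channels:
        data = np.stack([m.channels[ch] for m in bin_.members])
        out[ch] = (data.mean(axis=0), data.std(axis=0))
    return out


def _top_two_peaks(y: np.ndarray, prominence_frac: float,
                   window: tuple[float, float] | None, s: np.ndarray):
    """Indices (ascending) of the two highest local maxima, optionally
    restricted to an s-window; returns fewer if not present."""
    peaks, _ = find_peaks(y, prominence=prominence_frac * max(y.max(), 1e-12))
    if window is not None:
        lo, hi = window
        peaks = peaks[(s[peaks] >= lo) & (s[peaks] <= hi)]
    if len(peaks) > 2:
        peaks = peaks[np.argsort(y[peaks])[-2:]]
    return np.sort(peaks)


def find_landmark_peaks(
    channels: dict[str, np.ndarray],
    length: float,
    prominence_frac: float = 0.1,
    interior_window: tuple[float, float] = (0.1, 0.9),
) -> LandmarkPeaks:
    """Extract the six landmarks from an oriented, normalized mean profile.

    Z1 and Z2 sit at s = 0 and s = 1.  M1 and M2 are the two highest
    Obscurin local maxima (M1 the left one — the larger daughter block after
    orientation); S1 and S2 are the two highest *interior* Sls maxima inside
    ``interior_window``, away from the Z-disc peaks.  Peak positions are
    refined to subsample precision with a three-point parabola and converted
    to μm via the sarcomere length.  Missing peaks leave landmarks absent
    and add a flag.
    """
    obs = np.asarray(channels["obscurin"], dtype=float)
    sls = np.asarray(channels["sls"], dtype=float)
    n = len(obs)
    s = np.linspace(0.0, 1.0, n)
    positions = {"Z1": 0.0, "Z2": float(length)}
    intensities = {"Z1": float(sls[0]), "Z2": float(sls[-1])}
    flags = []

    m_peaks = _top_two_peaks(obs, prominence_frac, None, s)
    if len(m_peaks) == 2:
        for name, idx in zip(("M1", "M2"), m_peaks):
            pos = parabolic_refine(obs, int(idx)) / (n - 1)
            positions[name] = float(pos * length)
            intensities[name] = float(obs[idx])
    elif len(m_peaks) == 1:
        flags.append("single_obscurin_peak")
        pos = parabolic_refine(obs, int(m_peaks[0])) / (n - 1)
        positions["M1"] = positions["M2"] = float(pos * length)
        intensities["M1"] = intensities["M2"] = float(obs[m_peaks[0]])
    else:
        flags.append("no_obscurin_peak")

    s_peaks = _top_two_peaks(sls, prominence_frac, interior_window, s)
    if len(s_peaks) == 2:
        for name, idx in zip(("S1", "S2"), s_peaks):
            pos = parabolic_refine(sls, int(idx)) / (n - 1)
            positions[name] = float(pos * length)
            intensities[name] = float(sls[idx])
    else:
        flags.append("missing_interior_sls_peaks")
        if len(s_peaks) == 1:
            pos = parabolic_refine(sls, int(s_peaks[0])) / (n - 1)
            positions["S1"] = float(pos * length)
            intensities["S1"] = float(sls[s_peaks[0]])

    return LandmarkPeaks(positions=positions, intensities=intensities,
                         length=float(length), flags=flags)


def interpeak_trends(
    peaks_by_bin: list[LandmarkPeaks],
    pairs: tuple[str, ...] = TREND_PAIRS,
) -> dict[str, float]:
    """OLS slope of each named interpeak distance against sarcomere length."""
    usable = [p for p in peaks_by_bin if not p.flags]
    if len(usable) < 3:
        raise ValueError("interpeak trends need at least 3 bins with clean landmarks")
    lengths = np.array([p.length for p in usable])
    slopes = {}
    for pair in pairs:
        try:
            d = np.array([p.distance(pair) for p in usable])
        except KeyError:
            continue
        slopes[pair] = float(np.polyfit(lengths, d, 1)[0])
    return slopes


def total_amount(raw_profile: SarcomereProfile, channel: str) -> float:
    """Integrated raw intensity × length — a proxy for total protein amount."""
    y = raw_profile.channels[channel]
    return float(np.trapezoid(y, raw_profile.s_grid) * raw_profile.length)


def neighbor_normalized_amount(
    sarcomere: SarcomereProfile,
    left: SarcomereProfile | None,
    right: SarcomereProfile | None,
    channel: str,
) -> float | None:
    """Total amount of the center sarcomere normalized to its two neighbors.

    Returns None when either neighbor is missing (such sarcomeres are
    excluded from the aggregate, which only uses sarcomeres with both
    neighbors detected).
    """
    if left is None or right is None:
        return None
    amounts = [total_amount(p, channel) for p in (left, right)]
    ref = float(np.mean(amounts))
    if ref <= 0:
        raise ValueError("neighbor amounts must be positive")
    return total_amount(sarcomere, channel) / ref
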