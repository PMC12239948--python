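"""Myofibril tracing: connect Z-discs into sarcomeres and chains.

Every pair of Z-discs within a search distance (default 3.5 μm) whose
separation vector lies within an angular cone around the fiber axis is a
candidate sarcomere.  Candidates are scored by the sum of the mean actin
and mean Obscurin intensities sampled along the connecting segment
(trilinear interpolation), and accepted greedily in descending score order
under the constraints that a Z-disc joins at most one sarcomere on each
side of the axis (hence degree ≤ 2) and no endpoint pair repeats.  Accepted
sarcomeres form chains (myofibrils) as connected components of the
resulting degree-≤2 graph.  Curation is file-driven: an accept/reject list
plus the 1.8 μm minimum-length filter for quantitative output.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .stack import VoxelStack
from .zdisc import ZDisc

#: minimum length (μm) of sarcomeres kept for quantitative analysis
MIN_QUANT_LENGTH = 1.8


@dataclass
class CandidateSarcomere:
    id_a: int                 # ZDisc id at the axis-negative end
    id_b: int                 # ZDisc id at the axis-positive end
    length: float             # μm
    axis_angle: float         # degrees from the fiber axis
    score: float | None = None
    flagged: bool = False     # segment partially out of stack bounds

    @property
    def key(self) -> tuple[int, int]:
        return (self.id_a, self.id_b)


@dataclass
class Myofibril:
    zdisc_ids: list[int]
    sarcomeres: list[CandidateSarcomere]


def fiber_axis(zdiscs: list[ZDisc]) -> np.ndarray:
    """Principal axis of the Z-disc point cloud, oriented toward +x."""
    pos = np.array([d.position for d in zdiscs])
    if len(pos) < 2:
        return np.array([1.0, 0.0, 0.0])
    centered = pos - pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if axis[0] < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def candidate_pairs(
    zdiscs: list[ZDisc],
    max_dist: float = 3.5,
    axis: np.ndarray | None = None,
    half_angle: float = 30.0,
) -> list[CandidateSarcomere]:
    """All Z-disc pairs within ``max_dist`` and ``half_angle`` of the axis."""
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    if not 0 < half_angle < 90:
        raise ValueError("half_angle must lie in (0, 90) degrees")
    if len(zdiscs) < 2:
        return []
    if axis is None:
        axis = fiber_axis(zdiscs)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pos = np.array([d.position for d in zdiscs])
    ids = [d.id for d in zdiscs]
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=max_dist, output_type="ndarray")
    cos_min = np.cos(np.deg2rad(half_angle))
    out = []
    for i, j in pairs:
        sep = pos[j] - pos[i]
        dist = float(np.linalg.norm(sep))
        if dist == 0 or dist > max_dist:
            continue
        cos = float(np.dot(sep, axis) / dist)
        if abs(cos) < cos_min:
            continue
        a, b = (i, j) if cos > 0 else (j, i)
        angle = float(np.rad2deg(np.arccos(min(1.0, abs(cos)))))
        out.append(CandidateSarcomere(id_a=ids[a], id_b=ids[b],
                                      length=dist, axis_angle=angle))
    out.sort(key=lambda c: c.key)
    return out


def _segment_samples(p0: np.ndarray, p1: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def sample_channel(stack: VoxelStack, channel: str, points_um: np.ndarray) -> tuple[np.ndarray, bool]:
    """Trilinear interpolation of one channel at physical points.

    Out-of-bounds points are clipped to the stack boundary; the second
    return value reports whether any clipping occurred.
    """
    dx, dy, dz = stack.pitch
    data = stack.channel(channel)
    nz, ny, nx = data.shape
    coords = np.stack([
        points_um[:, 2] / dz,
        points_um[:, 1] / dy,
        points_um[:, 0] / dx,
    ])
    limits = np.array([nz - 1, ny - 1, nx - 1], dtype=float)[:, None]
    clipped = np.clip(coords, 0.0, limits)
    out_of_bounds = bool(np.any(coords != clipped))
    vals = map_coordinates(data, clipped, order=1, mode="nearest")
    return vals, out_of_bounds


def score_candidates(
    candidates: list[CandidateSarcomere],
    stack: VoxelStack,
    zdiscs: list[ZDisc],
    n_samples: int = 50,
    normalize: bool = True,
) -> list[CandidateSarcomere]:
    """Score = mean actin + mean Obscurin intensity along the segment.

    With ``normalize`` (default) each channel is divided by its stack-wide
    99th-percentile intensity first, making the two channels commensurate.
    Scores are written in place and the list returned for chaining.
    """
    by_id = {d.id: d for d in zdiscs}
    norms = {}
    for ch in ("actin", "obscurin"):
        p99 = float(np.percentile(stack.channel(ch), 99)) if normalize else 1.0
        norms[ch] = p99 if p99 > 0 else 1.0
    for cand in candidates:
        p0 = by_id[cand.id_a].position
        p1 = by_id[cand.id_b].position
        pts = _segment_samples(p0, p1, n_samples)
        total = 0.0
        flagged = False
        for ch in ("actin", "obscurin"):
            vals, oob = sample_channel(stack, ch, pts)
            flagged = flagged or oob
            total += float(vals.mean()) / norms[ch]
        cand.score = total
        cand.flagged = cand.flagged or flagged
    return candidates


def select_sarcomeres(
    candidates: list[CandidateSarcomere],
) -> list[CandidateSarcomere]:
    """Greedy maximal-score selection with branch resolution.

    Candidates are visited in descending score order (ties broken by length
    then lexicographic endpoint ids, so the output is independent of input
    ordering).  A candidate is accepted iff neither endpoint already has an
    accepted sarcomere on the same side of the fiber axis — each Z-disc can
    join at most one sarcomere toward the axis-positive side and one toward
    the axis-negative side, which both enforces degree ≤ 2 and resolves
    branches in favor of the higher-scoring candidate.
    """
    if any(c.score is None for c in candidates):
        raise ValueError("candidates must be scored before selection")
    order = sorted(candidates, key=lambda c: (-c.score, c.length, c.key))
    taken_side: set[tuple[int, int]] = set()  # (zdisc id, side) occupancy
    seen_pairs: set[tuple[int, int]] = set()
    accepted = []
    for cand in order:
        if cand.key in seen_pairs:
            continue
        slots = ((cand.id_a, +1), (cand.id_b, -1))
        if any(s in taken_side for s in slots):
            continue
        taken_side.update(slots)
        seen_pairs.add(cand.key)
        accepted.append(cand)
    accepted.sort(key=lambda c: c.key)
    return accepted


def assemble_myofibrils(
    accepted: list[CandidateSarcomere],
    zdiscs: list[ZDisc],
    axis: np.ndarray | None = None,
) -> list[Myofibril]:
    """Connected components of the sarcomere graph, ordered along the axis."""
    if axis is None:
        axis = fiber_axis(zdiscs)
    by_id = {d.id: d for d in zdiscs}
    adjacency: dict[int, list[int]] = {}
    for s in accepted:
        adjacency.setdefault(s.id_a, []).append(s.id_b)
        adjacency.setdefault(s.id_b, []).append(s.id_a)
    for node, nbrs in adjacency.items():
        if len(nbrs) > 2:
            raise ValueError(f"ZDisc {node} has degree {len(nbrs)} > 2")
    edge_by_pair = {s.key: s for s in accepted}
    visited: set[int] = set()
    fibrils = []
    for start in sorted(adjacency):
        if start in visited:
            continue
        comp = []
        queue = [start]
        visited.add(start)
        while queue:
            node = queue.pop()
            comp.append(node)
            for nbr in adjacency[node]:
                if nbr not in visited:
                    visited.add(nbr)
                    queue.append(nbr)
        n_edges = len({tuple(sorted((a, b))) for a in comp for b in adjacency[a] if b in comp})
        if n_edges >= len(comp):
            raise ValueError("cycle detected in sarcomere graph")
        comp.sort(key=lambda i: float(np.dot(by_id[i].position, axis)))
        members = []
        for a, b in zip(comp[:-1], comp[1:]):
            key = (a, b) if (a, b) in edge_by_pair else (b, a)
            members.append(edge_by_pair[key])
        fibrils.append(Myofibril(zdisc_ids=comp, sarcomeres=members))
    fibrils.sort(key=lambda f: float(np.dot(by_id[f.zdisc_ids[0]].position, axis)))
    return fibrils


def read_curation(path_or_buffer) -> pd.DataFrame:
    """Read a two-column (sarcomere_id, decision) curation CSV."""
    df = pd.read_csv(path_or_buffer, comment="#")
    required = {"sarcomere_id", "decision"}
    if not required <= set(df.columns):
        raise ValueError(f"curation file needs columns {sorted(required)}")
    return df


def apply_curation(
    accepted: list[CandidateSarcomere],
    decisions: pd.DataFrame | str | Path | None = None,
    min_length: float = MIN_QUANT_LENGTH,
) -> tuple[list[CandidateSarcomere], dict]:
    """Apply accept/reject decisions and the minimum-length filter.

    ``decisions`` may be a DataFrame, a CSV path, or None (no manual
    decisions).  Sarcomere ids are ``"a-b"`` strings built from the endpoint
    Z-disc ids.  Unknown ids raise with the offending line number.  All
    sarcomeres with length ≤ ``min_length`` μm are removed from quantitative
    output regardless of decisions.  Returns the curated list and a report
    with removal bookkeeping.
    """
    known = {f"{s.id_a}-{s.id_b}": s for s in accepted}
    rejected: set[str] = set()
    if decisions is not None:
        if not isinstance(decisions, pd.DataFrame):
            decisions = read_curation(decisions)
        for line, row in enumerate(decisions.itertuples(index=False), start=2):
            sid = str(row.sarcomere_id)
            if sid not in known:
                raise ValueError(f"curation line {line}: unknown sarcomere id {sid!r}")
            if str(row.decision).strip().lower() == "reject":
                rejected.add(sid)
    curated = [s for sid, s in known.items()
               if sid not in rejected and s.length > min_length]
    n_in = len(accepted)
    report = {
        "n_candidates": n_in,
        "n_rejected_manual": len(rejected),
        "n_rejected_short": sum(1 for s in accepted
                                if s.length <= min_length and f"{s.id_a}-{s.id_b}" not in rejected),
        "n_curated": len(curated),
        "removed_fraction": (n_in - len(curated)) / n_in if n_in else 0.0,
    }
    curated.sort(key=lambda c: c.key)
    return curated, report


def sarcomere_table(accepted: list[CandidateSarcomere], zdiscs: list[ZDisc]) -> pd.DataFrame:
    """Tabulate accepted sarcomeres with endpoint coordinates in μm."""
    by_id = {d.id: d for d in zdiscs}
    rows = []
    for s in accepted:
        a, b = by_id[s.id_a], by_id[s.id_b]
        rows.append({
            "sarcomere_id": f"{s.id_a}-{s.id_b}",
            "xa": a.x, "ya": a.y, "za": a.z,
            "xb": b.x, "yb": b.y, "zb": b.z,
            "length_um": s.length,
            "axis_angle_deg": s.axis_angle,
            "score": s.score,
            "flagged": s.flagged,
        })
    return pd.DataFrame(rows)
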