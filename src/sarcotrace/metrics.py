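"""Detection-quality metrics against ground truth."""
from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


def match_points(
    detected: np.ndarray,
    truth: np.ndarray,
    radius: float = 0.5,
) -> dict:
    """One-to-one matching of detected vs true 3D points within a radius.

    Uses optimal (Hungarian) assignment on the distance matrix; pairs
    farther than ``radius`` μm never match.  Returns recall, precision,
    matched index pairs, and the mean lateral (x, y) and axial (z)
    localization errors of the matches.
    """
    detected = np.atleast_2d(np.asarray(detected, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if detected.size == 0 or truth.size == 0:
        return {"recall": 0.0, "precision": 0.0, "matches": [],
                "lateral_error_um": np.nan, "axial_error_um": np.nan}
    dist = cdist(detected, truth)
    cost = np.where(dist <= radius, dist, 1e6)
    rows, cols = linear_sum_assignment(cost)
    matches = [(int(r), int(c)) for r, c in zip(rows, cols) if dist[r, c] <= radius]
    if matches:
        det_m = detected[[m[0] for m in matches]]
        tru_m = truth[[m[1] for m in matches]]
        lateral = float(np.mean(np.linalg.norm(det_m[:, :2] - tru_m[:, :2], axis=1)))
        axial = float(np.mean(np.abs(det_m[:, 2] - tru_m[:, 2])))
    else:
        lateral = axial = np.nan
    return {
        "recall": len(matches) / len(truth),
        "precision": len(matches) / len(detected),
        "matches": matches,
        "lateral_error_um": lateral,
        "axial_error_um": axial,
    }
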