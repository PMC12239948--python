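"""Run configuration: every pipeline parameter with its default, YAML round-trip."""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .stack import FLIGHT_PITCH


@dataclass
class RunConfig:
    """All tunable parameters of the flight-muscle pipeline.

    Defaults are the values used throughout the package: 0.4 μm Z-disc merge
    radius, 3.5 μm sarcomere search distance, 30° angular half-range, the
    1.8/2.2/2.4/2.6/3.0/3.4 μm length-bin edges, and the 0.93 quantile
    thresholds of the pronounced-peak rule.  Every stochastic operation
    receives the explicit ``seed``.
    """

    # input / output
    input_path: str | None = None
    output_dir: str = "sarcotrace_out"
    pitch: tuple[float, float, float] = FLIGHT_PITCH
    channel_names: tuple[str, ...] = ("actin", "sls", "mhc", "obscurin")

    # chromatic-shift correction
    correct_chromatic_shift: bool = True
    chrom_spot_sigma_px: float = 2.0
    chrom_max_shift_px: int = 10
    chrom_reference_slice: int | None = None

    # Z-disc detection
    sls_channel: str = "sls"
    local_window_um: float = 1.0
    sensitivity: float = 0.5
    min_area_px: int = 20
    merge_radius_um: float = 0.4
    min_support_slices: int = 2

    # tracing
    max_dist_um: float = 3.5
    half_angle_deg: float = 30.0
    score_samples: int = 50

    # curation
    curation_file: str | None = None
    min_quant_length_um: float = 1.8

    # profiles
    profile_samples: int = 100
    bin_edges: tuple[float, ...] = (1.8, 2.2, 2.4, 2.6, 3.0, 3.4)
    peak_prominence_frac: float = 0.1
    interior_window: tuple[float, float] = (0.1, 0.9)

    # pair statistics
    pronounced_max_quantile: float = 0.93
    pronounced_total_quantile: float = 0.93
    n_permutations: int = 10_000
    stratified_null: bool = False

    # randomness
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        # YAML has no tuples; restore the declared tuple fields
        cfg.pitch = tuple(cfg.pitch)
        cfg.channel_names = tuple(cfg.channel_names)
        cfg.bin_edges = tuple(cfg.bin_edges)
        cfg.interior_window = tuple(cfg.interior_window)
        return cfg

    def hash(self) -> str:
        """Short stable digest of the analysis parameters.

        I/O locations (input_path, output_dir) are excluded: the same
        analysis run into a different directory is the same analysis.
        """
        params = asdict(self)
        params.pop("input_path", None)
        params.pop("output_dir", None)
        canon = yaml.safe_dump(params, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
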