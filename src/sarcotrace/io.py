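"""File I/O and the end-to-end pipeline driver.

Stacks are stored as multipage TIFF in channel-z-y-x order with a JSON
sidecar (``<name>.json``) holding the voxel pitch and channel names; ground
truth, fit results and test results are JSON; all tables are CSV whose
first line is a ``# config_hash=...`` comment.
"""
from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import chromshift, profiles, trace, zdisc
from .config import RunConfig
from .stack import VoxelStack
from .synthdata import GroundTruth, DivisionState


def write_stack(path: str | Path, stack: VoxelStack) -> None:
    """Write a stack as CZYX TIFF plus a pitch/channel JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.intensities, dtype=np.float32))
    sidecar = {"pitch_um": list(stack.pitch),
               "channel_names": list(stack.channel_names)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(
    path: str | Path,
    pitch: tuple[float, float, float] | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> VoxelStack:
    """Read a CZYX TIFF stack; pitch/channels from the sidecar or arguments.

    Explicit arguments override the sidecar.  Missing pitch or channel
    metadata with no override is rejected: physical coordinates are
    meaningless without the voxel pitch.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:
        data = data[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    pitch = pitch or (tuple(meta["pitch_um"]) if "pitch_um" in meta else None)
    channel_names = channel_names or (
        tuple(meta["channel_names"]) if "channel_names" in meta else None)
    if pitch is None:
        raise ValueError(f"{path}: no voxel pitch in sidecar and none supplied")
    if channel_names is None:
        raise ValueError(f"{path}: no channel names in sidecar and none supplied")
    if len(channel_names) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} channel planes but "
            f"{len(channel_names)} channel names")
    return VoxelStack(intensities=data, pitch=pitch, channel_names=channel_names)


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(gt), default=_json_default, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    raw = json.loads(Path(path).read_text())
    raw["zdisc_positions"] = [[tuple(p) for p in chain] for chain in raw["zdisc_positions"]]
    raw["division_states"] = [[DivisionState(**s) for s in chain]
                              for chain in raw["division_states"]]
    raw["planted_shift"] = tuple(raw["planted_shift"])
    if raw.get("frap_params") is not None:
        raw["frap_params"] = tuple(raw["frap_params"])
    if raw.get("scan_labels") is not None:
        raw["scan_labels"] = [np.asarray(s, dtype=bool) for s in raw["scan_labels"]]
    return GroundTruth(**raw)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_table(path: str | Path, df: pd.DataFrame, config_hash: str) -> None:
    """CSV with a leading config-hash comment line."""
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(config: RunConfig, stack: VoxelStack | None = None) -> dict:
    """Run chromshift → zdisc → trace → curation → profiles and write outputs.

    ``stack`` may be passed directly (e.g. fresh from the generator);
    otherwise it is read from ``config.input_path``.  Any stage failure
    aborts with the stage name; outputs written so far are retained next to
    a ``FAILED`` marker file.  Returns a result bundle with the Z-discs,
    sarcomeres, myofibrils, binned profiles and the log dictionary.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    log: dict = {"config_hash": chash, "seed": config.seed,
                 "parameters": dataclasses.asdict(config),
                 "started": time.strftime("%Y-%m-%dT%H:%M:%S"), "stages": {}}
    bundle: dict = {"log": log}
    stage = "load"
    try:
        if stack is None:
            if config.input_path is None:
                raise ValueError("no stack given and no input_path configured")
            stack = read_stack(config.input_path, pitch=None)

        stage = "chromshift"
        if config.correct_chromatic_shift:
            stack, shift = chromshift.correct_stack(
                stack, spot_sigma=config.chrom_spot_sigma_px,
                max_shift=config.chrom_max_shift_px,
                reference_slice=config.chrom_reference_slice)
            log["stages"]["chromshift"] = {"dy": shift.dy, "dx": shift.dx,
                                           "magnitude_um": shift.magnitude_um,
                                           "exceeds_expected": shift.exceeds_expected}
            bundle["shift"] = shift

        stage = "zdisc"
        discs = zdisc.detect_zdiscs(
            stack, channel=config.sls_channel, local_window=config.local_window_um,
            sensitivity=config.sensitivity, min_area_px=config.min_area_px,
            merge_radius=config.merge_radius_um, min_support=config.min_support_slices)
        log["stages"]["zdisc"] = {"n_zdiscs": len(discs)}
        bundle["zdiscs"] = discs
        zdf = pd.DataFrame([{"id": d.id, "x_um": d.x, "y_um": d.y, "z_um": d.z,
                             "n_supporting_slices": d.n_supporting_slices,
                             "mean_intensity": d.mean_intensity, "flagged": d.flagged}
                            for d in discs])
        write_table(out / "zdiscs.csv", zdf, chash)

        stage = "trace"
        axis = trace.fiber_axis(discs)
        cands = trace.candidate_pairs(discs, max_dist=config.max_dist_um,
                                      axis=axis, half_angle=config.half_angle_deg)
        trace.score_candidates(cands, stack, discs, n_samples=config.score_samples)
        accepted = trace.select_sarcomeres(cands)
        fibrils = trace.assemble_myofibrils(accepted, discs, axis)
        log["stages"]["trace"] = {"n_candidates": len(cands),
                                  "n_accepted": len(accepted),
                                  "n_myofibrils": len(fibrils)}
        bundle["myofibrils"] = fibrils

        stage = "curation"
        curated, report = trace.apply_curation(
            accepted, decisions=config.curation_file,
            min_length=config.min_quant_length_um)
        log["stages"]["curation"] = report
        bundle["sarcomeres"] = curated
        write_table(out / "sarcomeres.csv", trace.sarcomere_table(curated, discs), chash)

        stage = "profiles"
        profs = []
        for s in curated:
            p = profiles.extract_profile(s, stack, discs, n_samples=config.profile_samples)
            profs.append(profiles.orient_profile(profiles.normalize_profile(p)))
        bins, excluded = profiles.bin_by_length(profs, edges=config.bin_edges)
        log["stages"]["profiles"] = {
            "n_profiles": len(profs), "n_excluded": excluded,
            "bin_counts": {f"[{b.low},{b.high})": len(b.members) for b in bins}}
        bundle["profiles"] = profs
        bundle["bins"] = bins
        rows = []
        for b in bins:
            if not b.members:
                continue
            mean = profiles.mean_profile(b)
            for ch, (mu, sd) in mean.items():
                for si, (m_, s_) in enumerate(zip(mu, sd)):
                    rows.append({"bin_low": b.low, "bin_high": b.high, "channel": ch,
                                 "s": si / (len(mu) - 1), "mean": m_, "sd": s_})
        write_table(out / "mean_profiles.csv", pd.DataFrame(rows), chash)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    log["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "run_log.json").write_text(json.dumps(log, indent=1, default=_json_default))
    return bundle
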