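"""File-based pipeline wiring simulate -> average -> train -> denoise -> evaluate.

Each stage reads and writes under one output root, is cached by a hash of its
config section (plus the presence of its outputs), and can be forced to
re-run.  The in-memory equivalents live in :mod:`pseudoavg.study`; this
module is the shell-workflow counterpart used by the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .evaluation import cohort_report
from .inference import pseudoaverage
from .model import UNetSpec, load_model, save_model
from .registration import average_frames
from .synthdata import make_dataset
from .training import TrainConfig, make_peer_to_peer_pairs, make_single_to_average_pairs, train
from .types import EnfaceImage, GroundTruthPhantom, Transform2D

log = logging.getLogger("pseudoavg")

STAGES = ("simulate", "average", "train", "denoise", "evaluate")

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "n_eyes": 9,
        "splits": {"train": 4, "val": 2, "test": 3},
        "size_px": [256, 256],
        "n_frames": 4,
        "max_shift_px": 8.0,
        "max_rot_deg": 2.0,
        "noise": {},
    },
    "average": {},
    "train": {
        "spec": {"levels": 5, "base_channels": 8},
        "config": {"epochs": 20, "learning_rate": 0.05, "batch_size": 32},
        "stride": 64,
        "peer_to_peer": True,
    },
    "denoise": {"match_contrast": True, "tile": 64, "stride": 32},
    "evaluate": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        import yaml

        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = path_or_dict or {}
    if not isinstance(user, dict):
        raise ValueError("pipeline config must be a mapping")
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return _merge(DEFAULT_CONFIG, user)


def _config_hash(section: dict, seed: int) -> str:
    payload = json.dumps({"seed": seed, **section}, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _stamp_path(out_root: Path, stage: str) -> Path:
    return out_root / f".{stage}.done"


def _is_cached(out_root: Path, stage: str, digest: str) -> bool:
    stamp = _stamp_path(out_root, stage)
    return stamp.exists() and stamp.read_text().strip() == digest


def _write_stamp(out_root: Path, stage: str, digest: str) -> None:
    _stamp_path(out_root, stage).write_text(digest + "\n")


def _load_phantom(out_root: Path, entry: dict) -> GroundTruthPhantom:
    perfusion = pio.read_png16(out_root / entry["truth"]["perfusion"])
    vessel = pio.read_mask_png(out_root / entry["truth"]["vessel_mask"])
    return GroundTruthPhantom(
        perfusion_map=perfusion,
        vessel_mask=vessel,
        faz_center_xy=tuple(entry["faz_center"]),
        faz_radius=entry["faz_radius"],
    )


def _load_frame(out_root: Path, fe: dict, eye_id: str) -> EnfaceImage:
    t = fe.get("true_transform") or {}
    return EnfaceImage(
        pixels=pio.read_png16(out_root / fe["path"]),
        eye_id=eye_id,
        frame_index=fe["frame_index"],
        role=fe["role"] if fe["role"] in ("single", "averaged", "pseudoaveraged", "truth") else "single",
        motion_rows=tuple(fe.get("motion_rows") or ()),
        shadow_bbox=tuple(fe["shadow_bbox"]) if fe.get("shadow_bbox") else None,
        true_transform=Transform2D(**t) if t else None,
    )


# ---- stages -----------------------------------------------------------------

def stage_simulate(cfg: dict, out_root: Path) -> dict:
    sim = cfg["simulate"]
    manifest = make_dataset(
        n_eyes=sim["n_eyes"],
        splits=dict(sim["splits"]),
        config={
            "size_px": tuple(sim["size_px"]),
            "n_frames": sim["n_frames"],
            "max_shift_px": sim["max_shift_px"],
            "max_rot_deg": sim["max_rot_deg"],
            "noise": sim.get("noise", {}),
        },
        out_dir=out_root,
        seed=cfg["seed"],
    )
    return manifest


def stage_average(cfg: dict, out_root: Path) -> None:
    manifest = pio.load_manifest(out_root / "manifest.json")
    (out_root / "averaged").mkdir(exist_ok=True)
    logs = {}
    for eye_id, entry in manifest["eyes"].items():
        frames = [_load_frame(out_root, fe, eye_id) for fe in entry["frames"]]
        if len(frames) < 2:
            continue
        from .types import FrameStack

        avg, info = average_frames(FrameStack(frames=frames), return_info=True)
        path = out_root / "averaged" / f"{eye_id}_avg.png"
        pio.write_png16(path, avg.pixels)
        logs[eye_id] = {
            "path": str(path.relative_to(out_root)),
            "reference_index": info["reference_index"],
            "quality_scores": info["quality_scores"],
            "transforms": {str(k): t.as_dict() for k, t in info["transforms"].items()},
            "failed": info["failed"],
            "motion_rows": list(avg.motion_rows),
        }
    pio.save_manifest(out_root / "averaged" / "transforms.json", logs)


def stage_train(cfg: dict, out_root: Path) -> None:
    manifest = pio.load_manifest(out_root / "manifest.json")
    avg_log = pio.load_manifest(out_root / "averaged" / "transforms.json")
    tr = cfg["train"]
    stride = tr.get("stride") or 64
    pairs = []
    for eye_id, entry in manifest["eyes"].items():
        if entry["split"] != "train" or eye_id not in avg_log:
            continue
        rec = avg_log[eye_id]
        frames = [_load_frame(out_root, fe, eye_id) for fe in entry["frames"]]
        reference = frames[rec["reference_index"]]
        averaged = pio.read_png16(out_root / rec["path"])

        mask = np.ones(averaged.shape, dtype=bool)
        h = averaged.shape[0]
        for row in rec["motion_rows"]:
            mask[max(0, row - 1) : min(h, row + 2)] = False
        for frame in frames:
            if frame.shadow_bbox is not None:
                r0, c0, bh, bw = frame.shadow_bbox
                mask[r0 : r0 + bh, c0 : c0 + bw] = False
        pairs += make_single_to_average_pairs(
            reference, averaged, mask, stride=stride, source_eye=eye_id
        )
        if tr.get("peer_to_peer", True):
            scores = rec["quality_scores"]
            lo, hi = int(np.argmin(scores)), int(np.argmax(scores))
            if lo != hi and scores[lo] < scores[hi]:
                try:
                    pairs += make_peer_to_peer_pairs(
                        frames[lo], frames[hi], stride=stride, source_eye=eye_id
                    )
                except ValueError:
                    pass  # no usable quality gap in this stack
    spec = UNetSpec(**tr.get("spec", {}))
    config = TrainConfig(seed=cfg["seed"], **tr.get("config", {}))
    model, history = train(pairs, spec, config)
    save_model(model, out_root / "weights.npz")
    pd.DataFrame({"epoch": range(1, len(history) + 1), "loss": history}).to_csv(
        out_root / "loss_history.csv", index=False
    )


def stage_denoise(cfg: dict, out_root: Path) -> None:
    manifest = pio.load_manifest(out_root / "manifest.json")
    model = load_model(out_root / "weights.npz")
    dn = cfg["denoise"]
    (out_root / "pseudoaveraged").mkdir(exist_ok=True)
    for eye_id, entry in manifest["eyes"].items():
        if entry["split"] == "train":
            continue
        frame = _load_frame(out_root, entry["frames"][0], eye_id)
        out = pseudoaverage(
            frame, model, tile=dn["tile"], stride=dn["stride"],
            match_contrast=dn["match_contrast"],
        )
        pio.write_png16(out_root / "pseudoaveraged" / f"{eye_id}_pseudo.png", out.pixels)


def stage_evaluate(cfg: dict, out_root: Path) -> dict:
    manifest = pio.load_manifest(out_root / "manifest.json")
    records = []
    for eye_id, entry in manifest["eyes"].items():
        pseudo_path = out_root / "pseudoaveraged" / f"{eye_id}_pseudo.png"
        if not pseudo_path.exists():
            continue
        original = _load_frame(out_root, entry["frames"][0], eye_id)
        processed = EnfaceImage(
            pixels=pio.read_png16(pseudo_path),
            eye_id=eye_id,
            role="pseudoaveraged",
            motion_rows=original.motion_rows,
            shadow_bbox=original.shadow_bbox,
        )
        records.append(
            {
                "eye_id": eye_id,
                "phantom": _load_phantom(out_root, entry),
                "original": original,
                "processed": processed,
            }
        )
    report = cohort_report(records)
    (out_root / "report").mkdir(exist_ok=True)
    report.per_scan.to_csv(out_root / "report" / "per_scan.csv", index=False)
    pio.save_manifest(out_root / "report" / "summary.json", report.summary)
    return report.summary


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "average": stage_average,
    "train": stage_train,
    "denoise": stage_denoise,
    "evaluate": stage_evaluate,
}


def run_pipeline(config, out_dir, force=(), stages=STAGES) -> dict:
    """Execute the pipeline stages in order with config-hash caching.

    ``force`` is an iterable of stage names (or ``"all"``) to re-run even if
    cached.  Returns a dict of stage -> status ("ran" or "cached").
    """
    cfg = load_config(config)
    out_root = Path(out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    force = set(STAGES) if "all" in force else set(force)
    status = {}
    upstream = ""
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        # chain digests so changing an upstream section re-runs downstream stages
        digest = _config_hash({"stage": cfg.get(stage, {}), "upstream": upstream}, cfg["seed"])
        upstream = digest
        if stage not in force and _is_cached(out_root, stage, digest):
            log.info("stage %s: cached", stage)
            status[stage] = "cached"
            continue
        t0 = time.time()
        _STAGE_FUNCS[stage](cfg, out_root)
        _write_stamp(out_root, stage, digest)
        log.info("stage %s: ran in %.1fs", stage, time.time() - t0)
        status[stage] = "ran"
    return status
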