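"""End-to-end orchestration: ingest → rasters → matching → models →
dark-fleet estimate, with a deterministic run manifest.

All randomness flows from the single config seed through named
substreams, so a rerun with the same config produces byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
import numpy as np
import pandas as pd

from . import ais as ais_mod
from . import matching as match_mod
from .estimator import (
    EstimatorConfig,
    LengthHistogram,
    bootstrap_uncertainty,
    estimate,
    scale_to_fishing,
)
from .models import build_L, fit_detection_curve, fit_length_quantiles, save_models
from .rasters import build_raster_set
from .scenes import load_detections, load_scenes


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    ais_csv: str
    registry_csv: str
    scenes_geojson: str
    detections_csv: str
    out_dir: str
    threshold: float = match_mod.DEFAULT_THRESHOLD
    threshold_band: tuple = match_mod.ANALYST_THRESHOLD_BAND
    raster_n_pixels: int = 150
    raster_min_samples: int = 200
    bootstrap_n: int = 200
    split_fraction: float = 0.5
    estimator_restarts: int = 4
    seed: int = 0
    format_version: int = 1


@dataclass
class RunResult:
    manifest: dict
    out_dir: str


def _settings_hash(cfg: RunConfig) -> str:
    doc = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("ingest")
def _ingest(cfg: RunConfig):
    for path, what in (
        (cfg.ais_csv, "AIS positions"),
        (cfg.registry_csv, "vessel registry"),
        (cfg.scenes_geojson, "scenes"),
        (cfg.detections_csv, "detections"),
    ):
        if not os.path.exists(path):
            raise StageError("ingest", f"missing {what} file: {path}")
    registry = ais_mod.load_registry(cfg.registry_csv)
    parsed = ais_mod.parse_positions(cfg.ais_csv, registry=registry)
    scenes = load_scenes(cfg.scenes_geojson)
    detections = load_detections(cfg.detections_csv)
    return registry, parsed, scenes, detections


def run_full(cfg: RunConfig) -> RunResult:
    """Run every stage and write the artifact tree + manifest.

    Outputs under ``cfg.out_dir``: matches.csv, unmatched.csv,
    in_scene.csv, models.json, estimate.json, histogram.csv,
    manifest.json. Any stage failure aborts with the stage name; files
    already written are preserved.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    registry, parsed, scenes, detections = _ingest(cfg)

    tracks = parsed.tracks
    gear = [t for t in tracks if ais_mod.is_gear(t.vessel)]
    vessels = [t for t in tracks if not ais_mod.is_gear(t.vessel)]

    rasters = _stage("rasters")(build_raster_set)(
        vessels, min_samples=cfg.raster_min_samples, n_pixels=cfg.raster_n_pixels
    )

    reports = [
        _stage("matching")(match_mod.match_scene)(
            vessels, sc, detections, rasters, threshold=cfg.threshold
        )
        for sc in scenes
    ]

    # ---- assemble per-instance outcomes --------------------------------
    match_rows = []
    in_scene_rows = []
    matched_det_ids = set()
    for rep in reports:
        flagged = set(rep.result.ambiguous)
        for v, d, s in rep.result.pairs:
            match_rows.append(
                {"scene_id": rep.scene_id, "vessel_id": v, "detect_id": d,
                 "score": s, "flagged": (v, d) in flagged}
            )
            matched_det_ids.add(d)
        for v, p in sorted(rep.in_scene.items()):
            in_scene_rows.append(
                {"scene_id": rep.scene_id, "vessel_id": v, "in_scene_p": p,
                 "band": match_mod.classify_in_scene(p)}
            )
    matches_df = pd.DataFrame(
        match_rows, columns=["scene_id", "vessel_id", "detect_id", "score", "flagged"]
    )
    in_scene_df = pd.DataFrame(
        in_scene_rows, columns=["scene_id", "vessel_id", "in_scene_p", "band"]
    )
    unmatched = [d for d in detections if d.detect_id not in matched_det_ids]
    unmatched_df = pd.DataFrame(
        [{"scene_id": d.scene_id, "detect_id": d.detect_id, "lat": d.lat,
          "lon": d.lon, "sar_length_m": d.sar_length_m} for d in unmatched],
        columns=["scene_id", "detect_id", "lat", "lon", "sar_length_m"],
    )
    matches_df.to_csv(os.path.join(cfg.out_dir, "matches.csv"), index=False)
    unmatched_df.to_csv(os.path.join(cfg.out_dir, "unmatched.csv"), index=False)
    in_scene_df.to_csv(os.path.join(cfg.out_dir, "in_scene.csv"), index=False)

    # ---- fit detectability + length-error models -----------------------
    det_lengths = {d.detect_id: d.sar_length_m for d in detections}
    vessel_rows = []
    pair_rows = []
    confident = in_scene_df[in_scene_df["band"] == "inside"]
    matched_by_vessel_scene = {
        (r.vessel_id, r.scene_id): r.detect_id for r in matches_df.itertuples()
    }
    for vid, grp in confident.groupby("vessel_id"):
        rec = registry.get(vid)
        if rec is None or rec.length_m is None:
            continue
        n_scenes = len(grp)
        n_det = 0
        for sid in grp["scene_id"]:
            did = matched_by_vessel_scene.get((vid, sid))
            if did is not None:
                n_det += 1
                pair_rows.append(
                    {"vessel_id": vid, "true_length_m": rec.length_m,
                     "sar_length_m": det_lengths[did]}
                )
        vessel_rows.append(
            {"vessel_id": vid, "length_m": rec.length_m,
             "n_scenes": n_scenes, "n_detected": n_det}
        )
    vessels_df = pd.DataFrame(vessel_rows, columns=["vessel_id", "length_m", "n_scenes", "n_detected"])
    pairs_df = pd.DataFrame(pair_rows, columns=["vessel_id", "true_length_m", "sar_length_m"])

    def _fit_models():
        curve = fit_detection_curve(
            vessels_df.assign(detection_fraction=vessels_df["n_detected"] / vessels_df["n_scenes"])
        )
        q13, q23 = fit_length_quantiles(pairs_df)
        return curve, build_L(q13, q23)

    curve, lmat = _stage("models")(_fit_models)()
    save_models(os.path.join(cfg.out_dir, "models.json"), curve, lmat)

    # ---- estimate the dark fleet ---------------------------------------
    def _estimate_all():
        l_o = LengthHistogram.from_lengths(unmatched_df["sar_length_m"], role="observed")
        est_cfg = EstimatorConfig(restarts=cfg.estimator_restarts)
        est = estimate(l_o, curve, lmat, config=est_cfg, seed=cfg.seed)
        # threshold-band spread: re-threshold the stored score matrices
        totals = {}
        # a higher threshold rejects more matches, leaving more unmatched
        # detections and therefore a larger dark estimate
        for name, thr in (
            ("at_band_low_threshold", cfg.threshold_band[0]),
            ("at_band_high_threshold", cfg.threshold_band[1]),
        ):
            unmatched_ids = set()
            for rep in reports:
                res = match_mod.greedy_assign(
                    rep.scores, thr, vessel_ids=rep.vessel_ids, detection_ids=rep.detection_ids
                )
                unmatched_ids.update(res.unmatched_detections)
            lengths = [det_lengths[d] for d in unmatched_ids]
            alt = estimate(
                LengthHistogram.from_lengths(lengths), curve, lmat,
                config=EstimatorConfig(restarts=2), seed=cfg.seed + 1,
            )
            totals[name] = alt.total
        boot = None
        if len(vessels_df) >= 40 and cfg.bootstrap_n > 0:
            boot = bootstrap_uncertainty(
                vessels_df, pairs_df, n_experiments=cfg.bootstrap_n,
                split_fraction=cfg.split_fraction, seed=cfg.seed,
            )
            est.ci90 = boot.dress(est.total)
        census = pd.DataFrame(
            [{"vclass": r.vclass, "length_m": r.length_m}
             for r in registry.values() if r.length_m is not None]
        )
        est.fishing_total = scale_to_fishing(est.total, census)
        return est, totals, boot

    est, band_totals, boot = _stage("estimate")(_estimate_all)()

    hist_df = pd.DataFrame(
        {"length_bin_m": np.arange(0, 400, 5),
         "count": est.l_A_hat.counts.reshape(80, 5).sum(axis=1)}
    )
    hist_df.to_csv(os.path.join(cfg.out_dir, "histogram.csv"), index=False)

    n_flagged = int(matches_df["flagged"].sum()) if len(matches_df) else 0
    manifest = {
        "format_version": cfg.format_version,
        "settings_hash": _settings_hash(cfg),
        "seed": cfg.seed,
        "counts": {
            "tracks_parsed": len(tracks),
            "rows_rejected": parsed.n_rejected,
            "gear_removed": len(gear),
            "scenes": len(scenes),
            "detections": len(detections),
            "candidates": int(sum(r.n_candidates for r in reports)),
            "in_scene_confident": int((in_scene_df["band"] == "inside").sum()),
            "in_scene_uncertain": int((in_scene_df["band"] == "uncertain").sum()),
            "matched": len(matches_df),
            "matched_low": len(matches_df) - n_flagged,
            "matched_high": len(matches_df),
            "unmatched": len(unmatched_df),
        },
        "estimate": {
            "dark_total": est.total,
            "ci90": list(est.ci90) if est.ci90 else None,
            "fishing_total": est.fishing_total,
            "objective_value": est.objective_value,
            "threshold_band_totals": band_totals,
            "bootstrap_mape": boot.mape if boot else None,
        },
    }
    with open(os.path.join(cfg.out_dir, "estimate.json"), "w") as fh:
        json.dump(manifest["estimate"], fh, sort_keys=True, indent=1)
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return RunResult(manifest=manifest, out_dir=cfg.out_dir)
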