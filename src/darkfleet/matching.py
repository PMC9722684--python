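"""Score AIS vessels against SAR detections and assign matches.

The score for a vessel/detection pair is the vessel's fused location
probability density (vessels per km²) evaluated at the detection point.
A pair is acceptable when that density beats the combined density of dark
vessels and false detections: p_v·p_d > d_d·p_d + p_f, which for a score
threshold means p_v > (d_d·p_d + p_f)/p_d. Absent fitted densities the
default operating threshold is 2.5×10⁻⁵ vessels/km², inside the analyst
band of 5×10⁻⁶–1×10⁻⁴.

Assignment is greedy: the globally highest-scoring pair is matched and its
row and column removed, until the best remaining score falls below the
threshold. Matches whose score is within a configurable factor (default
100) of a competing score in their row or column are flagged ambiguous,
giving low/high match-count ranges instead of a manual review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import ais as ais_mod
from .ais import VesselTrack, bracket_positions, candidate_tracks, is_gear
from .fusion import AnchoredRaster, GeoRaster, IncompatibleEvidenceError, fuse, multiply_renormalize, resample_to_common_grid
from .rasters import RasterSet
from .scenes import Detection, Scene  # noqa: F401  (re-exported module surface)

logger = logging.getLogger(__name__)

#: Default operating score threshold, vessels per km².
DEFAULT_THRESHOLD = 2.5e-5
#: Analyst-reviewed plausible band for the threshold, vessels per km².
ANALYST_THRESHOLD_BAND = (5e-6, 1e-4)
#: In-scene probability bands: above/below these a vessel is treated as
#: definitely inside/outside the footprint.
IN_SCENE_HIGH = 0.95
IN_SCENE_LOW = 0.05

AMBIGUITY_FACTOR = 100.0


@dataclass
class MatchDecisionParams:
    p_v: float = 0.0          # score density at the detection, vessels/km²
    p_d: float = 1.0          # detection probability given length
    d_d: float = 0.0          # dark-vessel density, vessels/km²
    p_f: float = 0.0          # false-detection density, detections/km²
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self):
        if min(self.p_v, self.p_d, self.d_d, self.p_f, self.threshold) < 0:
            raise ValueError("densities must be non-negative")
        if self.p_d > 1:
            raise ValueError("p_d is a probability")


@dataclass
class MatchResult:
    """One-to-one assignment outcome for a score matrix."""

    pairs: list                      # (vessel_id, detection_id, score)
    unmatched_detections: list       # detection ids
    undetected_vessels: list         # vessel ids with no accepted match
    ambiguous: list = field(default_factory=list)  # flagged (vessel_id, detection_id)

    @property
    def n_matched_low(self) -> int:
        """Match count treating every flagged pair as rejected."""
        flagged = set(self.ambiguous)
        return sum((v, d) not in flagged for v, d, _ in self.pairs)

    @property
    def n_matched_high(self) -> int:
        """Match count treating every flagged pair as accepted."""
        return len(self.pairs)


def score(fused: GeoRaster, det: Detection) -> float:
    """Fused-density lookup (bilinear) at the detection point; 0 outside."""
    return float(fused.sample_latlon(det.lat, det.lon)[0])


def decision_threshold(
    d_d: Optional[float] = None,
    p_d: Optional[float] = None,
    p_f: Optional[float] = None,
    default: float = DEFAULT_THRESHOLD,
) -> float:
    """Score level at which the match criterion flips.

    With fitted densities returns (d_d·p_d + p_f)/p_d; without them,
    the configured default.
    """
    if d_d is None and p_d is None and p_f is None:
        return default
    if p_d is None or p_d == 0:
        raise ValueError("p_d must be positive to form a score threshold")
    d_d = d_d or 0.0
    p_f = p_f or 0.0
    if min(d_d, p_f) < 0 or not 0 < p_d <= 1:
        raise ValueError("invalid densities")
    return (d_d * p_d + p_f) / p_d


def greedy_assign(
    scores: np.ndarray,
    threshold: float = DEFAULT_THRESHOLD,
    vessel_ids: Optional[list] = None,
    detection_ids: Optional[list] = None,
) -> MatchResult:
    """Greedy one-to-one assignment on a vessels × detections score matrix.

    Repeatedly accept the globally best remaining pair with score ≥
    threshold, removing its row and column. Exact ties are broken by
    smaller vessel id, then smaller detection id, for determinism.
    """
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2:
        raise ValueError("scores must be a 2-D matrix")
    if not np.all(np.isfinite(s)) or (s < 0).any():
        raise ValueError("scores must be finite and non-negative")
    nv, nd = s.shape
    vids = list(vessel_ids) if vessel_ids is not None else list(range(nv))
    dids = list(detection_ids) if detection_ids is not None else list(range(nd))

    work = s.copy()
    row_alive = np.ones(nv, dtype=bool)
    col_alive = np.ones(nd, dtype=bool)
    pairs = []
    while row_alive.any() and col_alive.any():
        masked = np.where(np.outer(row_alive, col_alive), work, -np.inf)
        best = masked.max()
        if best < threshold or best == -np.inf:
            break
        cand = np.argwhere(masked == best)
        i, j = min(cand, key=lambda ij: (vids[ij[0]], dids[ij[1]]))
        pairs.append((vids[i], dids[j], float(s[i, j])))
        row_alive[i] = False
        col_alive[j] = False
    return MatchResult(
        pairs=pairs,
        unmatched_detections=[dids[j] for j in range(nd) if col_alive[j]],
        undetected_vessels=[vids[i] for i in range(nv) if row_alive[i]],
    )


def flag_ambiguous(
    scores: np.ndarray,
    result: MatchResult,
    factor: float = AMBIGUITY_FACTOR,
    vessel_ids: Optional[list] = None,
    detection_ids: Optional[list] = None,
) -> MatchResult:
    """Mark matches with a competing score within ``factor`` of their own.

    A competitor is any other entry in the matched pair's row or column.
    Flagged matches are retained; they define the low/high match-count
    range on the result.
    """
    s = np.asarray(scores, dtype=float)
    nv, nd = s.shape
    vids = list(vessel_ids) if vessel_ids is not None else list(range(nv))
    dids = list(detection_ids) if detection_ids is not None else list(range(nd))
    vpos = {v: i for i, v in enumerate(vids)}
    dpos = {d: j for j, d in enumerate(dids)}
    flagged = []
    for v, d, sc in result.pairs:
        i, j = vpos[v], dpos[d]
        competitors = np.concatenate([np.delete(s[i, :], j), np.delete(s[:, j], i)])
        if competitors.size and sc > 0 and competitors.max() * factor >= sc:
            if competitors.max() > 0:
                flagged.append((v, d))
    result.ambiguous = flagged
    return result


def in_scene_probability(fused: GeoRaster, scene: Scene) -> float:
    """Probability the vessel was inside the footprint at image time:
    fused density summed over cells inside the footprint."""
    return fused.mass_in_polygon(scene.footprint)


def classify_in_scene(p: float) -> str:
    if p > IN_SCENE_HIGH:
        return "inside"
    if p < IN_SCENE_LOW:
        return "outside"
    return "uncertain"


# --------------------------------------------------------------------------
# Per-scene orchestration


@dataclass
class VesselSceneEvidence:
    vessel_id: str
    fused: Optional[GeoRaster]           # scoring raster (10-minute rule)
    fused_multiplied: Optional[GeoRaster]  # always-multiplied, for in-scene prob
    in_scene_p: float
    excluded: Optional[str] = None       # reason, when unusable


@dataclass
class SceneMatchReport:
    scene_id: str
    result: MatchResult
    in_scene: dict                       # vessel_id -> in-scene probability
    excluded: dict                       # vessel_id -> reason
    n_candidates: int
    scores: Optional[np.ndarray] = None  # vessels × detections, for re-thresholding
    vessel_ids: Optional[list] = None
    detection_ids: Optional[list] = None


def _sided_anchor(raster_set: RasterSet, track: VesselTrack, ping, t_scene) -> AnchoredRaster:
    dt = (t_scene - ping.t).total_seconds() / 60.0
    # a ping exactly at scene time uses the shortest-offset raster with a
    # zero-length extrapolation
    bin_dt = dt if dt != 0 else 0.5
    raster = raster_set.lookup(track.vessel.vclass, ping.sog, bin_dt)
    return AnchoredRaster.from_ping(raster, ping, dt)


def vessel_scene_evidence(
    track: VesselTrack, scene: Scene, raster_set: RasterSet
) -> VesselSceneEvidence:
    """Build the fused rasters and in-scene probability for one vessel."""
    vid = track.vessel.vessel_id
    before, after = bracket_positions(track, scene.t)
    a_before = _sided_anchor(raster_set, track, before, scene.t) if before else None
    a_after = _sided_anchor(raster_set, track, after, scene.t) if after else None
    try:
        fused = fuse(
            a_before, a_after, scene.t,
            before.t if before else None, after.t if after else None,
        )
        if a_before is not None and a_after is not None and fused.method != "multiplied":
            ga, gb = resample_to_common_grid(a_before, a_after, extent="intersection")
            fused_mult = multiply_renormalize(ga, gb)
        else:
            fused_mult = fused
    except IncompatibleEvidenceError:
        logger.info("vessel %s: incompatible before/after evidence at %s", vid, scene.scene_id)
        return VesselSceneEvidence(vid, None, None, 0.0, excluded="incompatible_evidence")
    p_in = in_scene_probability(fused_mult, scene)
    return VesselSceneEvidence(vid, fused, fused_mult, p_in)


def match_scene(
    tracks: Iterable[VesselTrack],
    scene: Scene,
    detections: list,
    raster_set: RasterSet,
    threshold: float = DEFAULT_THRESHOLD,
    ambiguity_factor: float = AMBIGUITY_FACTOR,
) -> SceneMatchReport:
    """Run the full per-scene matching: candidate filter, fused rasters,
    in-scene screening, scoring, greedy assignment, ambiguity flags.

    Vessels that are definitely outside the footprint (in-scene
    probability < 5%) are removed before matching; vessels whose
    bracketing evidence is self-contradictory are excluded and logged.
    """
    dets = [d for d in detections if d.scene_id == scene.scene_id]
    cands = candidate_tracks(tracks, scene)
    evidence = []
    excluded = {}
    in_scene = {}
    for tr in cands:
        ev = vessel_scene_evidence(tr, scene, raster_set)
        in_scene[ev.vessel_id] = ev.in_scene_p
        if ev.excluded:
            excluded[ev.vessel_id] = ev.excluded
        elif ev.in_scene_p < IN_SCENE_LOW:
            excluded[ev.vessel_id] = "outside_footprint"
        else:
            evidence.append(ev)

    vids = [ev.vessel_id for ev in evidence]
    dids = [d.detect_id for d in dets]
    scores = np.zeros((len(evidence), len(dets)))
    for i, ev in enumerate(evidence):
        for j, det in enumerate(dets):
            scores[i, j] = score(ev.fused, det)
    result = greedy_assign(scores, threshold, vessel_ids=vids, detection_ids=dids)
    result = flag_ambiguous(scores, result, ambiguity_factor, vessel_ids=vids, detection_ids=dids)
    return SceneMatchReport(
        scene_id=scene.scene_id,
        result=result,
        in_scene=in_scene,
        excluded=excluded,
        n_candidates=len(cands),
        scores=scores,
        vessel_ids=vids,
        detection_ids=dids,
    )


def gear_match_audit(
    tracks: Iterable[VesselTrack],
    scene: Scene,
    detections: list,
    raster_set: RasterSet,
    threshold: float = DEFAULT_THRESHOLD,
    slow_knots: float = 2.0,
) -> pd.DataFrame:
    """Diagnostic: would excluded gear beacons have matched any detection?

    Gear is dropped before matching, so this audit only reports, per gear
    beacon near the scene, its speed at the closest ping and its best
    score against the scene's detections. Slow gear (< 2 kn, i.e. in the
    water) matching anything would indicate the gear filter is discarding
    real vessels.
    """
    dets = [d for d in detections if d.scene_id == scene.scene_id]
    rows = []
    max_km = 200.0 * 1.852
    dt_max = pd.Timedelta(hours=12)
    gear = []
    for t in tracks:
        if not t.pings or not is_gear(t.vessel):
            continue
        near = [p for p in t.pings if abs(p.t - scene.t) <= dt_max]
        if near and np.any(
            ais_mod.distance_to_footprint_km(
                [p.lat for p in near], [p.lon for p in near], scene.footprint
            )
            <= max_km
        ):
            gear.append(t)
    for tr in gear:
        ev = vessel_scene_evidence(tr, scene, raster_set)
        if ev.fused is None:
            continue
        best = max((score(ev.fused, d) for d in dets), default=0.0)
        ping, _ = bracket_positions(tr, scene.t)
        if ping is None:
            _, ping = bracket_positions(tr, scene.t)
        rows.append(
            {
                "vessel_id": tr.vessel.vessel_id,
                "sog": ping.sog,
                "slow": ping.sog < slow_knots,
                "best_score": best,
                "would_match": best >= threshold,
            }
        )
    return pd.DataFrame(rows, columns=["vessel_id", "sog", "slow", "best_score", "would_match"])
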