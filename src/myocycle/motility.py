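"""In vitro motility analysis: filament detection, tracking, velocities.

Per frame, actin filaments in the configured 2-6 px width band are enhanced
with a multiscale Hessian ridge (tubeness) filter, thresholded into a binary
mask, skeletonized, and pruned to the longest geodesic path so each fiber
becomes a line; the arc-length midpoint of that line is the filament's
position.  Midpoints are linked frame-to-frame by solving a linear assignment
problem with a gating radius and birth/death costs, and per-track velocities
are the mean frame-to-frame midpoint speed.

Coordinates are pixel centers, origin top-left, x right / y down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.optimize import linear_sum_assignment
from skimage import filters, measure, morphology

FWHM_TO_SIGMA = 1.0 / 2.355
_BIG = 1e12


@dataclass
class FilamentRecord:
    """One detected filament in one frame."""

    path: np.ndarray           #: (n, 2) skeleton path as (x, y) px
    length_px: float           #: arc length of the pruned skeleton
    midpoint: tuple            #: (x, y) px at half arc length (interpolated)
    width_px: float            #: mean width estimate (area / skeleton length)


@dataclass
class FrameDetection:
    """All filament detections of a single frame."""

    frame_index: int
    filaments: list = field(default_factory=list)


@dataclass
class Track:
    """A linked filament trajectory: at most one midpoint per frame."""

    track_id: int
    frames: list = field(default_factory=list)
    points: list = field(default_factory=list)   #: (x, y) px

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class VelocitySummary:
    """Per-video velocity statistics."""

    velocities: np.ndarray     #: per-track, um/s
    mean: float
    sd: float
    n_tracks: int
    pixel_size: float          #: um/px
    frame_interval: float      #: s


# ---------------------------------------------------------------------------
# detection

def _longest_path(skel: np.ndarray) -> np.ndarray | None:
    """Longest geodesic path through an 8-connected skeleton (rows, cols)."""
    pts = np.argwhere(skel)
    if len(pts) == 0:
        return None
    if len(pts) == 1:
        return pts
    index = {tuple(p): i for i, p in enumerate(pts)}
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    for (r, c), i in index.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    g.add_edge(i, j, weight=float(np.hypot(dr, dc)))
    # double-sweep: farthest node from an arbitrary node, then farthest again
    comp = max(nx.connected_components(g), key=len)
    start = next(iter(comp))
    dist = nx.single_source_dijkstra_path_length(g, start)
    e1 = max(dist, key=dist.get)
    dist, paths = nx.single_source_dijkstra(g, e1)
    e2 = max(dist, key=dist.get)
    return pts[paths[e2]]


def detect_filaments(frame: np.ndarray, width_band_px=(2.0, 6.0),
                     threshold: str | float = "otsu",
                     min_length_px: float = 8.0, border_px: float = 2.0,
                     simple_path_frac: float = 0.8,
                     frame_index: int = 0) -> FrameDetection:
    """Detect filaments in one frame via ridge filter, mask, skeleton, prune.

    The ridge response is the maximum over Hessian (tubeness) scales matched
    to the width band (sigma = width/2.355 for widths spanning the band);
    the mask threshold is Otsu's on the response unless a fixed value or
    quantile policy is supplied.  Each connected component is skeletonized
    and pruned to its longest geodesic path; components whose mean width
    falls outside the band, whose path is shorter than ``min_length_px``, or
    whose skeleton touches the image border (within ``border_px``: the
    filament is clipped and its midpoint would lag its motion) are dropped.
    Components whose longest path covers less than ``simple_path_frac`` of
    the skeleton are crossing/overlapping fibers whose midpoint is not
    meaningful and are likewise dropped.  An empty frame yields an empty
    detection.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a single-channel 2-D image")
    lo, hi = width_band_px
    if not (1.0 <= lo < hi <= 20.0):
        raise ValueError("width band must lie within [1, 20] px")
    sigmas = [w * FWHM_TO_SIGMA for w in np.arange(lo, hi + 0.5)]
    ridge = filters.sato(img, sigmas=sigmas, black_ridges=False)

    if threshold == "otsu":
        thr = filters.threshold_otsu(ridge)
    elif isinstance(threshold, str) and threshold.startswith("q"):
        thr = np.quantile(ridge, float(threshold[1:]))
    else:
        thr = float(threshold)
    mask = ridge > thr

    det = FrameDetection(frame_index=frame_index)
    labels = measure.label(mask, connectivity=2)
    for region in measure.regionprops(labels):
        comp = labels[region.slice] == region.label
        skel = morphology.skeletonize(comp)
        path = _longest_path(skel)
        if path is None or len(path) < 2:
            continue
        steps = np.hypot(*np.diff(path, axis=0).T)
        length = float(steps.sum())
        if length < min_length_px:
            continue
        if len(path) < simple_path_frac * skel.sum():
            continue    # crossing fibers: no single line through the mask
        # mean width = twice the mean distance-to-background along the
        # skeleton (orientation-independent, unlike area / length)
        edt = distance_transform_edt(np.pad(comp, 1))[1:-1, 1:-1]
        width = 2.0 * float(np.mean(edt[skel])) - 1.0
        if not lo <= width <= hi:
            continue
        r0b, c0b = region.slice[0].start, region.slice[1].start
        rr, cc = path[:, 0] + r0b, path[:, 1] + c0b
        if (rr.min() < border_px or cc.min() < border_px
                or rr.max() >= img.shape[0] - border_px
                or cc.max() >= img.shape[1] - border_px):
            continue
        # arc-length midpoint, interpolated between path pixels
        arc = np.concatenate([[0.0], np.cumsum(steps)])
        half = length / 2.0
        j = int(np.searchsorted(arc, half))
        j = min(max(j, 1), len(path) - 1)
        frac = (half - arc[j - 1]) / max(arc[j] - arc[j - 1], 1e-12)
        mid_rc = path[j - 1] + frac * (path[j] - path[j - 1])
        r0, c0 = region.slice[0].start, region.slice[1].start
        path_xy = np.stack([path[:, 1] + c0, path[:, 0] + r0], axis=1)
        midpoint = (float(mid_rc[1] + c0), float(mid_rc[0] + r0))
        det.filaments.append(FilamentRecord(path=path_xy.astype(float),
                                            length_px=length,
                                            midpoint=midpoint,
                                            width_px=float(width)))
    return det


def detect_stack(stack: np.ndarray, **kwargs) -> list[FrameDetection]:
    """Run :func:`detect_filaments` over every frame of a stack."""
    return [detect_filaments(stack[i], frame_index=i, **kwargs)
            for i in range(stack.shape[0])]


# ---------------------------------------------------------------------------
# linking

def link_tracks(detections: list[FrameDetection], gate_px: float = 15.0,
                gap_frames: int = 0) -> list[Track]:
    """Link per-frame midpoints into tracks by linear assignment.

    Frame-to-frame assignment minimizes summed squared midpoint displacement
    subject to the gating radius; unmatched detections are births and
    unmatched tracks die after ``gap_frames`` missed frames (the gate scales
    with the time gap).  The no-link (birth/death) cost is ``gate_px**2``.
    """
    if len(detections) < 2:
        raise ValueError("need >= 2 frames to link")
    tracks: list[Track] = []
    active: list[Track] = []
    ages: list[int] = []
    next_id = 0

    for det in sorted(detections, key=lambda d: d.frame_index):
        pts = np.array([f.midpoint for f in det.filaments], float
                       ).reshape(-1, 2)
        nt, nd = len(active), len(pts)
        matched_det = set()
        if nt and nd:
            cost = np.full((nt + nd, nd + nt), _BIG)
            for i, (tr, age) in enumerate(zip(active, ages)):
                last = np.asarray(tr.points[-1])
                gap = det.frame_index - tr.frames[-1]
                gate = gate_px * gap
                d2 = np.sum((pts - last) ** 2, axis=1)
                row = np.where(d2 <= gate ** 2, d2, _BIG)
                cost[i, :nd] = row
                cost[i, nd + i] = gate_px ** 2      # track death
            for j in range(nd):
                cost[nt + j, j] = gate_px ** 2      # detection birth
            cost[nt:, nd:] = 0.0
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if i < nt and j < nd and cost[i, j] < _BIG:
                    active[i].frames.append(det.frame_index)
                    active[i].points.append(tuple(pts[j]))
                    ages[i] = 0
                    matched_det.add(j)
        # births
        for j in range(nd):
            if j not in matched_det:
                tr = Track(track_id=next_id, frames=[det.frame_index],
                           points=[tuple(pts[j])])
                next_id += 1
                active.append(tr)
                ages.append(0)
                tracks.append(tr)
        # age unmatched tracks; kill the stale ones
        keep_a, keep_g = [], []
        for tr, age in zip(active, ages):
            if tr.frames[-1] == det.frame_index:
                keep_a.append(tr)
                keep_g.append(0)
            elif age + 1 <= gap_frames:
                keep_a.append(tr)
                keep_g.append(age + 1)
        active, ages = keep_a, keep_g
    return tracks


# ---------------------------------------------------------------------------
# velocities

def compute_velocities(tracks: list[Track], pixel_size: float,
                       frame_interval: float, min_track_len: int = 5,
                       min_speed: float | None = None) -> VelocitySummary:
    """Per-track mean frame-to-frame speed and the per-video summary.

    Velocity per track is the mean of per-step midpoint displacement divided
    by the step's time gap, scaled by ``pixel_size / frame_interval`` to
    um/s.  Tracks shorter than ``min_track_len`` frames are excluded; an
    optional minimum-speed filter is off by default.
    """
    if pixel_size <= 0 or frame_interval <= 0:
        raise ValueError("pixel_size and frame_interval must be positive")
    vels = []
    for tr in tracks:
        if len(tr) < min_track_len:
            continue
        pts = np.asarray(tr.points, dtype=float)
        gaps = np.diff(np.asarray(tr.frames, dtype=float))
        steps = np.hypot(*np.diff(pts, axis=0).T) / gaps
        v = float(np.mean(steps)) * pixel_size / frame_interval
        if min_speed is not None and v < min_speed:
            continue
        vels.append(v)
    if not vels:
        raise ValueError("no qualifying tracks")
    vels = np.asarray(vels)
    return VelocitySummary(velocities=vels, mean=float(vels.mean()),
                           sd=float(vels.std(ddof=1)) if len(vels) > 1
                           else 0.0,
                           n_tracks=len(vels), pixel_size=pixel_size,
                           frame_interval=frame_interval)


def analyze_movie(stack: np.ndarray, pixel_size: float, frame_interval: float,
                  gate_px: float = 15.0, gap_frames: int = 0,
                  min_track_len: int = 5, **detect_kwargs) -> VelocitySummary:
    """Full pipeline: detect every frame, link, and summarize velocities."""
    detections = detect_stack(stack, **detect_kwargs)
    tracks = link_tracks(detections, gate_px=gate_px, gap_frames=gap_frames)
    return compute_velocities(tracks, pixel_size, frame_interval,
                              min_track_len=min_track_len)
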