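"""Linking detections into trajectories.

Foci are linked in 3D by motion-informed global assignment: each live track
carries a constant-velocity state (position + velocity, a minimal Kalman
state), predicts its next position, and the frame-to-frame correspondence is
solved as an optimal one-to-one assignment on prediction-to-detection
distances with a hard gate. Unmatched detections seed new tracks; a track
coasts through up to ``max_gap`` missed frames on its prediction before
terminating. This predictive cost is what resolves crossing trajectories
that defeat plain nearest-neighbour linking.

Territories (2D, slow, well separated) are linked by greedy mutual
nearest-neighbour association.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import Trajectory
from .detection import Detection

__all__ = ["track_foci", "track_territories", "filter_tracks"]


@dataclass
class _LiveTrack:
    track_id: int
    frames: list = field(default_factory=list)
    positions: list = field(default_factory=list)
    velocity: np.ndarray | None = None
    missed: int = 0

    @property
    def last_pos(self) -> np.ndarray:
        return self.positions[-1]

    @property
    def last_frame(self) -> int:
        return self.frames[-1]

    def predict(self, frame: int) -> np.ndarray:
        if self.velocity is None:
            return self.last_pos
        return self.last_pos + self.velocity * (frame - self.last_frame)

    def update(self, frame: int, pos: np.ndarray) -> None:
        if self.frames:
            gap = frame - self.last_frame
            v_new = (pos - self.last_pos) / gap
            # blend with the previous velocity for a little motion memory
            self.velocity = v_new if self.velocity is None else 0.5 * self.velocity + 0.5 * v_new
        self.frames.append(frame)
        self.positions.append(pos)
        self.missed = 0


def _finalize(live: list[_LiveTrack], dt_s: float, dims: int, tag: str) -> list[Trajectory]:
    out = []
    for lt in live:
        if len(lt.frames) < 2:
            continue
        out.append(
            Trajectory(
                track_id=lt.track_id,
                frames=np.asarray(lt.frames),
                positions_um=np.asarray(lt.positions)[:, :dims],
                dt_s=dt_s,
                resolution_tag=tag,
            )
        )
    return out


def track_foci(
    detections: dict[int, list[Detection]],
    gate_radius_um: float = 0.5,
    max_gap: int = 1,
    dt_s: float = 10.0,
    dims: int = 3,
    resolution_tag: str = "",
) -> list[Trajectory]:
    """Link per-frame detections into 3D trajectories.

    ``detections`` maps frame index to that frame's detections; frames may
    be missing (treated as empty). Assignment is globally optimal per frame
    pair (linear assignment on predictive distance) with ``gate_radius_um``
    as a hard gate.
    """
    if gate_radius_um <= 0:
        raise ValueError("gate_radius must be positive")
    if not detections:
        return []
    frames = sorted(detections)
    live: list[_LiveTrack] = []
    done: list[_LiveTrack] = []
    next_id = 0
    big = 1e9
    for f in frames:
        dets = detections.get(f, [])
        pos = np.array([d.position_um[:dims] for d in dets], dtype=float).reshape(len(dets), dims)
        assigned_det = np.zeros(len(dets), dtype=bool)
        if live and len(dets):
            preds = np.stack([lt.predict(f) for lt in live])
            cost = np.linalg.norm(preds[:, None, :] - pos[None, :, :], axis=2)
            cost = np.where(cost <= gate_radius_um, cost, big)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] >= big:
                    continue
                live[r].update(f, pos[c])
                assigned_det[c] = True
        # age unmatched tracks, retire those past the gap limit
        still = []
        for lt in live:
            if lt.last_frame == f:
                still.append(lt)
            elif f - lt.last_frame <= max_gap:
                still.append(lt)
            else:
                done.append(lt)
        live = still
        for c in np.nonzero(~assigned_det)[0]:
            lt = _LiveTrack(track_id=next_id)
            lt.update(f, pos[c])
            live.append(lt)
            next_id += 1
    done.extend(live)
    done.sort(key=lambda lt: lt.track_id)
    return _finalize(done, dt_s, dims, resolution_tag)


def track_territories(
    centroids,
    gate_radius_um: float = 2.0,
    dt_s: float = 10.0,
) -> list[Trajectory]:
    """Greedy mutual nearest-neighbour linking of 2D territory centroids.

    ``centroids`` is a DataFrame with columns frame, x_um, y_um (the output
    of :func:`chromomotion.detection.segment_territories`) or a mapping
    frame -> (n, 2) array. A territory whose mutual nearest neighbour in the
    next frame is beyond the gate (or absent) ends its track.
    """
    if hasattr(centroids, "groupby"):
        per_frame = {
            int(f): g[["x_um", "y_um"]].to_numpy(dtype=float)
            for f, g in centroids.groupby("frame")
        }
    else:
        per_frame = {int(f): np.atleast_2d(np.asarray(v, dtype=float)) for f, v in centroids.items()}
    if not per_frame:
        return []
    frames = sorted(per_frame)
    live: list[_LiveTrack] = []
    done: list[_LiveTrack] = []
    next_id = 0
    for f in frames:
        pos = per_frame[f]
        assigned = np.zeros(len(pos), dtype=bool)
        if live and len(pos):
            last = np.stack([lt.last_pos for lt in live])
            dist = np.linalg.norm(last[:, None, :] - pos[None, :, :], axis=2)
            nn_fwd = dist.argmin(axis=1)
            nn_bwd = dist.argmin(axis=0)
            for r, c in enumerate(nn_fwd):
                if nn_bwd[c] == r and dist[r, c] <= gate_radius_um:
                    live[r].update(f, pos[c])
                    assigned[c] = True
        done.extend(lt for lt in live if lt.last_frame != f)
        live = [lt for lt in live if lt.last_frame == f]
        for c in np.nonzero(~assigned)[0]:
            lt = _LiveTrack(track_id=next_id)
            lt.update(f, pos[c])
            live.append(lt)
            next_id += 1
    done.extend(live)
    done.sort(key=lambda lt: lt.track_id)
    return _finalize(done, dt_s, dims=2, tag="territory")


def filter_tracks(tracks: list[Trajectory], min_steps: int = 4) -> list[Trajectory]:
    """Keep tracks spanning at least ``min_steps`` inter-frame steps.

    With the 10 s frame interval the default of 4 steps keeps only
    trajectories of at least 40 s duration (>= 5 points).
    """
    return [tr for tr in tracks if tr.n_steps >= min_steps]
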