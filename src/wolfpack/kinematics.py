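"""Stimulus-side simulation of the interactive avoidance display.

The display is screen-centered (x rightward, y upward, units = degrees of
visual angle) and divided into four quadrants by the coordinate axes.  Each
quadrant contains a 5.9-degree square flush with the display center in which
agents move; the participant-controlled chasee is confined to a circle of
11.75 degrees radius.  Agents travel at constant speed, change direction at
exponentially distributed intervals (3 changes per second on average, new
direction uniform within +/-45 degrees of the current one) and bounce off the
quadrant walls by mirroring the trajectory while leaving the orientation
untouched.

Sprite geometry and the pivot-shift convention: every agent has a *pivot*
(the point whose trajectory is simulated and about which the sprite rotates)
and a body *reference point* (the dart's concave vertex / the circle center).
The signed pivot shift ``d`` places the reference point at

    ref_pos = pivot_pos + d * orientation

so negative ``d`` moves the pivot toward the nose and positive ``d`` moves it
tailward of the reference point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

logger = logging.getLogger("wolfpack")

HEAD_ON = "head_on"
PERPENDICULAR = "perpendicular"

QUADRANTS = (0, 1, 2, 3)  # 0: x>=0,y>=0; 1: x<0,y>=0; 2: x<0,y<0; 3: x>=0,y<0


class InvalidInputError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class DisplayGeometry:
    """Display and sprite geometry in degrees of visual angle."""

    quadrant_side: float = 5.9
    boundary_radius: float = 11.75
    frame_rate: float = 75.0
    chasee_diameter: float = 1.2
    bug_diameter: float = 1.9
    dart_vertex_distance: float = 0.95
    eye_offset: float = 0.71
    eye_separation: float = 0.49
    eye_diameter: float = 0.19

    def __post_init__(self):
        for name, val in asdict(self).items():
            if val <= 0:
                raise InvalidInputError(f"{name} must be > 0, got {val}")


@dataclass(frozen=True)
class MotionParams:
    """Agent motion parameters: constant speed random-turn process."""

    speed: float = 7.8  # degrees / s
    turn_rate: float = 3.0  # expected direction changes / s
    turn_range: float = 45.0  # new heading uniform within +/- this, degrees
    duration: float = 17.0  # trial length, s

    def __post_init__(self):
        if self.speed <= 0:
            raise InvalidInputError("speed must be > 0")
        if self.turn_rate < 0:
            raise InvalidInputError("turn_rate must be >= 0")
        if not 0 <= self.turn_range <= 180:
            raise InvalidInputError("turn_range must be in [0, 180]")


@dataclass
class AgentState:
    """Snapshot of one agent at one frame."""

    pivot_pos: np.ndarray
    ref_pos: np.ndarray
    orientation: np.ndarray  # unit vector, nose/eyes direction
    motion_dir: np.ndarray  # unit vector
    kind: str = "bug"  # bug | dart | circle
    condition: str = HEAD_ON


def quadrant_of(pos: np.ndarray) -> np.ndarray:
    """Quadrant id(s) of position(s), half-open convention (x>=0 -> right,
    y>=0 -> top)."""
    pos = np.asarray(pos, dtype=float)
    x, y = pos[..., 0], pos[..., 1]
    right, top = x >= 0, y >= 0
    return np.where(
        right & top, 0, np.where(~right & top, 1, np.where(~right & ~top, 2, 3))
    )


def quadrant_bounds(q: int, geometry: DisplayGeometry) -> tuple[float, float, float, float]:
    """(xmin, xmax, ymin, ymax) of quadrant q's agent square (flush with the
    display center)."""
    s = geometry.quadrant_side
    return {
        0: (0.0, s, 0.0, s),
        1: (-s, 0.0, 0.0, s),
        2: (-s, 0.0, -s, 0.0),
        3: (0.0, s, -s, 0.0),
    }[q]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise InvalidInputError("cannot normalize a zero vector (coincident positions)")
    return v / n


def _rot90(v: np.ndarray, side: int) -> np.ndarray:
    """Rotate 2-vectors by +90 (side=+1, counterclockwise) or -90 degrees."""
    x, y = v[..., 0], v[..., 1]
    return np.stack([-side * y, side * x], axis=-1)


def assign_orientation(
    agent_pos: np.ndarray,
    chasee_pos: np.ndarray,
    condition: str,
    perp_side: int = 1,
) -> np.ndarray:
    """Orientation of an agent: toward the chasee (head-on) or rotated 90
    degrees from that direction (perpendicular, side fixed per agent)."""
    toward = _unit(np.asarray(chasee_pos, float) - np.asarray(agent_pos, float))
    if condition == HEAD_ON:
        return toward
    if condition == PERPENDICULAR:
        return _rot90(toward, perp_side)
    raise InvalidInputError(f"unknown condition {condition!r}")


def apply_pivot_shift(pivot_pos: np.ndarray, orientation: np.ndarray, d: float) -> np.ndarray:
    """Body reference-point position for pivot shift d: pivot + d*orientation."""
    return np.asarray(pivot_pos, float) + d * np.asarray(orientation, float)


def _reflect_into_bounds(
    pos: np.ndarray, dirs: np.ndarray, bounds: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror positions (and motion directions) across violated walls until
    inside bounds.  bounds: (..., 4) as (xmin, xmax, ymin, ymax)."""
    pos = pos.copy()
    dirs = dirs.copy()
    for _ in range(16):
        lo_x = pos[..., 0] < bounds[..., 0]
        hi_x = pos[..., 0] > bounds[..., 1]
        lo_y = pos[..., 1] < bounds[..., 2]
        hi_y = pos[..., 1] > bounds[..., 3]
        if not (lo_x.any() or hi_x.any() or lo_y.any() or hi_y.any()):
            break
        pos[..., 0] = np.where(lo_x, 2 * bounds[..., 0] - pos[..., 0], pos[..., 0])
        pos[..., 0] = np.where(hi_x, 2 * bounds[..., 1] - pos[..., 0], pos[..., 0])
        pos[..., 1] = np.where(lo_y, 2 * bounds[..., 2] - pos[..., 1], pos[..., 1])
        pos[..., 1] = np.where(hi_y, 2 * bounds[..., 3] - pos[..., 1], pos[..., 1])
        flip_x = lo_x | hi_x
        flip_y = lo_y | hi_y
        dirs[..., 0] = np.where(flip_x, -dirs[..., 0], dirs[..., 0])
        dirs[..., 1] = np.where(flip_y, -dirs[..., 1], dirs[..., 1])
    return pos, dirs


def generate_agent_trajectories(
    bounds: np.ndarray,
    motion: MotionParams,
    geometry: DisplayGeometry,
    seed: int | np.random.Generator,
    start: np.ndarray | None = None,
    n_frames: int | None = None,
    return_turn_count: bool = False,
):
    """Simulate pivot trajectories for several agents at once.

    bounds: (A, 4) wall boxes per agent.  Direction changes follow a Poisson
    process (exponential inter-event intervals) with rate ``turn_rate``; at
    each event the heading turns by a uniform draw within +/- turn_range.
    Returns (pos, dirs) with shape (n_frames, A, 2); optionally also the total
    number of direction-change events.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    A = bounds.shape[0]
    fps = geometry.frame_rate
    if n_frames is None:
        n_frames = int(round(motion.duration * fps))
    step = motion.speed / fps
    if step >= geometry.quadrant_side:
        raise InvalidInputError("per-frame step exceeds quadrant side")

    if start is None:
        start = np.column_stack(
            [
                rng.uniform(bounds[:, 0], bounds[:, 1]),
                rng.uniform(bounds[:, 2], bounds[:, 3]),
            ]
        )
    else:
        start = np.atleast_2d(np.asarray(start, dtype=float))
        inside = (
            (start[:, 0] >= bounds[:, 0])
            & (start[:, 0] <= bounds[:, 1])
            & (start[:, 1] >= bounds[:, 2])
            & (start[:, 1] <= bounds[:, 3])
        )
        if not inside.all():
            raise InvalidInputError("start position outside quadrant bounds")

    theta = rng.uniform(0, 2 * np.pi, size=A)
    pos = np.empty((n_frames, A, 2))
    dirs = np.empty((n_frames, A, 2))
    pos[0] = start
    dirs[0] = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    half = np.deg2rad(motion.turn_range)
    p_event = motion.turn_rate / fps
    n_turns = 0
    for t in range(1, n_frames):
        # Poisson thinning of the exponential-interval turn process per frame
        counts = rng.poisson(p_event, size=A) if motion.turn_rate > 0 else np.zeros(A, int)
        if counts.any():
            n_turns += int(counts.sum())
            for a in np.nonzero(counts)[0]:
                dtheta = rng.uniform(-half, half, size=counts[a]).sum()
                theta[a] += dtheta
            dirs_t = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
        else:
            dirs_t = dirs[t - 1]
        new_pos = pos[t - 1] + step * dirs_t
        new_pos, dirs_t = _reflect_into_bounds(new_pos, dirs_t, bounds)
        theta = np.arctan2(dirs_t[:, 1], dirs_t[:, 0])
        pos[t] = new_pos
        dirs[t] = dirs_t
    if return_turn_count:
        return pos, dirs, n_turns
    return pos, dirs


def generate_agent_trajectory(
    quadrant_bounds_: Sequence[float],
    motion: MotionParams,
    geometry: DisplayGeometry,
    seed: int | np.random.Generator,
    start: np.ndarray | None = None,
    n_frames: int | None = None,
):
    """Single-agent convenience wrapper; returns (pos, dirs) of shape (n, 2)."""
    start_arr = None if start is None else np.asarray(start, float)[None, :]
    pos, dirs = generate_agent_trajectories(
        np.asarray(quadrant_bounds_, float)[None, :],
        motion,
        geometry,
        seed,
        start=start_arr,
        n_frames=n_frames,
    )
    return pos[:, 0], dirs[:, 0]


def dart_polygon(ref_pos: np.ndarray, orientation: np.ndarray, geometry: DisplayGeometry) -> Polygon:
    """Dart sprite polygon: three convex vertices on an equilateral triangle
    (circumradius = dart_vertex_distance) around the concave vertex, which
    sits at the body reference point.  The nose points along ``orientation``."""
    r = geometry.dart_vertex_distance
    ux, uy = float(orientation[0]), float(orientation[1])
    c, s = ux, uy  # rotation taking +x to the orientation

    def body_to_screen(bx, by):
        return (ref_pos[0] + c * bx - s * by, ref_pos[1] + s * bx + c * by)

    ang = 2 * np.pi / 3
    verts = [
        body_to_screen(r, 0.0),  # nose
        body_to_screen(r * np.cos(ang), r * np.sin(ang)),  # rear wing
        body_to_screen(0.0, 0.0),  # concave vertex
        body_to_screen(r * np.cos(-ang), r * np.sin(-ang)),  # rear wing
    ]
    return Polygon(verts)


def dart_centroid_offset(geometry: DisplayGeometry = DisplayGeometry()) -> float:
    """Distance from the concave vertex to the uniform-lamina centroid of the
    dart polygon, along the nose axis."""
    poly = dart_polygon(np.zeros(2), np.array([1.0, 0.0]), geometry)
    return float(poly.centroid.x)


def detect_collision(agent: AgentState, chasee_pos: np.ndarray, geometry: DisplayGeometry) -> bool:
    """Chasee-agent contact test: circle overlap for bugs/circles, exact
    polygon-circle intersection for darts."""
    chasee_pos = np.asarray(chasee_pos, float)
    r_chasee = geometry.chasee_diameter / 2
    if agent.kind in ("bug", "circle"):
        return bool(
            np.linalg.norm(agent.ref_pos - chasee_pos)
            < (geometry.bug_diameter + geometry.chasee_diameter) / 2
        )
    if agent.kind == "dart":
        poly = dart_polygon(agent.ref_pos, agent.orientation, geometry)
        return bool(poly.distance(Point(chasee_pos)) < r_chasee)
    raise InvalidInputError(f"unknown stimulus kind {agent.kind!r}")


@dataclass
class TrialRecord:
    """Frame-indexed stimulus record for one trial.

    ``pivot`` and ``motion_dir`` are (n_frames, A, 2); the chasee series is
    (n_frames, 2) and is filled by a controller (synthetic or human data).
    Orientations depend on the chasee position and are materialized by
    :meth:`finalize`.
    """

    task: str  # LMA | bisection | recall_probe | static
    stimulus_kind: str
    d: float  # pivot shift, degrees
    geometry: DisplayGeometry
    motion: MotionParams
    pivot: np.ndarray
    motion_dir: np.ndarray
    conditions: list[str]  # per agent
    perp_sides: list[int]  # per agent, +1 CCW / -1 CW of the chasee direction
    agent_quadrant: list[int]
    wolfpack_quadrants: tuple[int, ...]
    chasee: np.ndarray  # (n_frames, 2); frame 0 = initial position
    layout_seed: int = 0
    motion_seed: int = 0
    missing_agent: int | None = None
    orientation: np.ndarray | None = None  # (n_frames, A, 2) after finalize
    static_orientation: np.ndarray | None = None  # (A, 2) for static trials

    @property
    def n_frames(self) -> int:
        return self.pivot.shape[0]

    @property
    def n_agents(self) -> int:
        return self.pivot.shape[1]

    @property
    def quadrant_layout(self) -> dict[int, str]:
        return {
            q: (HEAD_ON if q in self.wolfpack_quadrants else PERPENDICULAR)
            for q in QUADRANTS
        }

    def orientations_at(self, frame: int, chasee_pos: np.ndarray | None = None) -> np.ndarray:
        """Per-agent unit orientation vectors at a frame, given the chasee."""
        if self.task == "static":
            return self.static_orientation
        if chasee_pos is None:
            chasee_pos = self.chasee[frame]
        out = np.empty((self.n_agents, 2))
        for a in range(self.n_agents):
            out[a] = assign_orientation(
                self.pivot[frame, a], chasee_pos, self.conditions[a], self.perp_sides[a]
            )
        return out

    def finalize(self, chasee_series: np.ndarray) -> "TrialRecord":
        """Attach a chasee trajectory and materialize orientations/refs."""
        chasee_series = np.asarray(chasee_series, float)
        if chasee_series.shape != (self.n_frames, 2):
            raise InvalidInputError("chasee series must be (n_frames, 2)")
        self.chasee = chasee_series
        if self.task == "static":
            ori = np.broadcast_to(
                self.static_orientation[None], (self.n_frames, self.n_agents, 2)
            ).copy()
        else:
            delta = chasee_series[:, None, :] - self.pivot  # (n, A, 2)
            ori = _unit(delta)
            perp = np.array(self.perp_sides)
            is_perp = np.array([c == PERPENDICULAR for c in self.conditions])
            rotated = _rot90(ori, 1) * perp[None, :, None]
            ori = np.where(is_perp[None, :, None], rotated, ori)
        self.orientation = ori
        return self

    @property
    def ref_pos(self) -> np.ndarray:
        """(n_frames, A, 2) body reference-point positions (needs finalize)."""
        if self.orientation is None:
            raise InvalidInputError("trial not finalized: no chasee series")
        return self.pivot + self.d * self.orientation

    def agent_state(self, frame: int, agent: int) -> AgentState:
        ori = self.orientation[frame, agent]
        return AgentState(
            pivot_pos=self.pivot[frame, agent],
            ref_pos=self.pivot[frame, agent] + self.d * ori,
            orientation=ori,
            motion_dir=self.motion_dir[frame, agent],
            kind=self.stimulus_kind,
            condition=self.conditions[agent],
        )

    # -- serialization -----------------------------------------------------
    def to_jsonl(self, path) -> None:
        """JSON-lines export: one header object, then one frame per line."""
        header = {
            "task": self.task,
            "stimulus_kind": self.stimulus_kind,
            "d": self.d,
            "geometry": asdict(self.geometry),
            "motion": asdict(self.motion),
            "conditions": self.conditions,
            "perp_sides": self.perp_sides,
            "agent_quadrant": self.agent_quadrant,
            "wolfpack_quadrants": list(self.wolfpack_quadrants),
            "layout_seed": self.layout_seed,
            "motion_seed": self.motion_seed,
            "missing_agent": self.missing_agent,
            "static_orientation": None
            if self.static_orientation is None
            else self.static_orientation.tolist(),
        }
        fps = self.geometry.frame_rate
        with open(path, "w") as fh:
            fh.write(json.dumps(header, default=float) + "\n")
            for t in range(self.n_frames):
                row = {
                    "t": t / fps,
                    "chasee": self.chasee[t].tolist(),
                    "pivot": self.pivot[t].tolist(),
                    "dir": self.motion_dir[t].tolist(),
                }
                if self.orientation is not None:
                    ori = self.orientation[t]
                    row["ori_deg"] = np.rad2deg(np.arctan2(ori[:, 1], ori[:, 0])).tolist()
                    row["ref"] = (self.pivot[t] + self.d * ori).tolist()
                fh.write(json.dumps(row) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "TrialRecord":
        with open(path) as fh:
            header = json.loads(fh.readline())
            frames = [json.loads(line) for line in fh if line.strip()]
        pivot = np.array([f["pivot"] for f in frames])
        dirs = np.array([f["dir"] for f in frames])
        chasee = np.array([f["chasee"] for f in frames])
        trial = cls(
            task=header["task"],
            stimulus_kind=header["stimulus_kind"],
            d=header["d"],
            geometry=DisplayGeometry(**header["geometry"]),
            motion=MotionParams(**header["motion"]),
            pivot=pivot,
            motion_dir=dirs,
            conditions=header["conditions"],
            perp_sides=header["perp_sides"],
            agent_quadrant=header["agent_quadrant"],
            wolfpack_quadrants=tuple(header["wolfpack_quadrants"]),
            chasee=chasee,
            layout_seed=header["layout_seed"],
            motion_seed=header["motion_seed"],
            missing_agent=header["missing_agent"],
            static_orientation=None
            if header["static_orientation"] is None
            else np.array(header["static_orientation"]),
        )
        return trial

    def to_csv(self, path) -> None:
        """Flat CSV export (one row per frame x agent)."""
        import pandas as pd

        rows = []
        fps = self.geometry.frame_rate
        for t in range(self.n_frames):
            for a in range(self.n_agents):
                rows.append(
                    {
                        "t": t / fps,
                        "agent": a,
                        "pivot_x": self.pivot[t, a, 0],
                        "pivot_y": self.pivot[t, a, 1],
                        "dir_deg": np.rad2deg(
                            np.arctan2(self.motion_dir[t, a, 1], self.motion_dir[t, a, 0])
                        ),
                        "chasee_x": self.chasee[t, 0],
                        "chasee_y": self.chasee[t, 1],
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)


def build_trial(
    task: str,
    stimulus_kind: str = "bug",
    d: float = 0.0,
    layout_seed: int = 0,
    motion_seed: int = 0,
    geometry: DisplayGeometry = DisplayGeometry(),
    motion: MotionParams = MotionParams(),
    duration: float | None = None,
) -> TrialRecord:
    """Assemble a trial: quadrant layout, agent trajectories, chasee start.

    LMA / recall_probe trials place 12 agents (3 per quadrant) with two
    randomly chosen wolfpack (head-on) quadrants; the chasee starts at least
    4 degrees from the nearest agent.  Bisection trials show two agents from
    different quadrants (one head-on, one perpendicular) with the chasee at
    the nominal midpoint of the two pivots.  Static trials freeze one agent
    with a random orientation.
    """
    layout_rng = np.random.default_rng(layout_seed)
    motion_rng = np.random.default_rng(motion_seed)
    if duration is not None:
        motion = replace(motion, duration=duration)
    n_frames = int(round(motion.duration * geometry.frame_rate))

    if task in ("LMA", "recall_probe"):
        wolf = tuple(sorted(layout_rng.choice(QUADRANTS, size=2, replace=False)))
        agent_quadrant = [q for q in QUADRANTS for _ in range(3)]
        conditions = [HEAD_ON if q in wolf else PERPENDICULAR for q in agent_quadrant]
    elif task == "bisection":
        qs = layout_rng.choice(QUADRANTS, size=2, replace=False)
        agent_quadrant = [int(qs[0]), int(qs[1])]
        conditions = [HEAD_ON, PERPENDICULAR]
        wolf = (int(qs[0]),)
    elif task == "static":
        agent_quadrant = [int(layout_rng.integers(4))]
        conditions = [HEAD_ON]
        wolf = ()
    else:
        raise InvalidInputError(f"unknown task {task!r}")

    perp_sides = [int(layout_rng.choice([-1, 1])) for _ in agent_quadrant]
    bounds = np.array([quadrant_bounds(q, geometry) for q in agent_quadrant])

    static_orientation = None
    if task == "static":
        theta = layout_rng.uniform(0, 2 * np.pi)
        pivot0 = layout_rng.uniform(-2.0, 2.0, size=2)
        pivot = np.broadcast_to(pivot0[None, None, :], (n_frames, 1, 2)).copy()
        dirs = np.zeros((n_frames, 1, 2))
        static_orientation = np.array([[np.cos(theta), np.sin(theta)]])
        chasee0 = np.zeros(2)
    else:
        pivot, dirs = generate_agent_trajectories(
            bounds, motion, geometry, motion_rng, n_frames=n_frames
        )
        if task == "bisection":
            chasee0 = 0.5 * (pivot[0, 0] + pivot[0, 1])
        else:
            chasee0 = None
            for _ in range(1000):
                cand = layout_rng.uniform(-geometry.boundary_radius, geometry.boundary_radius, 2)
                if np.linalg.norm(cand) > geometry.boundary_radius - geometry.chasee_diameter:
                    continue
                if np.min(np.linalg.norm(pivot[0] - cand, axis=1)) >= 4.0:
                    chasee0 = cand
                    break
            if chasee0 is None:
                raise PlacementError("could not place the chasee 4 deg from agents")

    chasee = np.broadcast_to(chasee0[None, :], (n_frames, 2)).copy()
    return TrialRecord(
        task=task,
        stimulus_kind=stimulus_kind,
        d=d,
        geometry=geometry,
        motion=motion,
        pivot=pivot,
        motion_dir=dirs,
        conditions=conditions,
        perp_sides=perp_sides,
        agent_quadrant=list(map(int, agent_quadrant)),
        wolfpack_quadrants=tuple(map(int, wolf)),
        chasee=chasee,
        layout_seed=layout_seed,
        motion_seed=motion_seed,
        static_orientation=static_orientation,
    )


def choose_missing_agent(
    trial: TrialRecord,
    rng: np.random.Generator,
    prefer_condition: str | None = None,
) -> int:
    """Pick the to-be-recalled agent among the three nearest to the chasee's
    final position, preferring agents whose sprite does not overlap others.
    ``prefer_condition`` lets the caller balance head-on vs perpendicular
    picks across trials."""
    final = trial.chasee[-1]
    pivots = trial.pivot[-1]
    order = np.argsort(np.linalg.norm(pivots - final, axis=1))
    nearest = list(order[:3])
    diam = trial.geometry.bug_diameter
    non_overlap = [
        a
        for a in nearest
        if np.min(
            np.linalg.norm(pivots[[b for b in range(trial.n_agents) if b != a]] - pivots[a], axis=1)
        )
        > diam
    ]
    pool = non_overlap or nearest
    if prefer_condition is not None:
        matching = [a for a in pool if trial.conditions[a] == prefer_condition]
        pool = matching or pool
    pick = int(pool[int(rng.integers(len(pool)))])
    trial.missing_agent = pick
    return pick
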