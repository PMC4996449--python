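"""Animated streamlet engine for the migration flow visualization.

A fixed-size population (450 by default) of short streamline segments is
advected through the time-varying velocity field. Each frame every
streamlet's head moves along the local interpolated velocity, its previous
heads trail behind with geometrically fading opacity, and streamlets that
reach their (randomized) lifespan are replaced by fresh random seeds so the
population size is conserved. After a fixed number of frames the engine
advances to the next 20-minute interval and the field updates underneath
the particles. Density is deliberately not used here — the animation shows
speed and direction only.

All randomness flows from a single seedable generator, so a given seed
replays bit-identical frame geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import datetime
from typing import Optional

import numpy as np

from .field import FieldUndefinedError, VectorField

DEFAULT_POPULATION = 450
DEFAULT_MAX_AGE_RANGE = (30, 90)  # frames; each streamlet draws its own lifespan


@dataclass
class Streamlet:
    """One animated particle: head position, fading trail, age."""

    head: np.ndarray  # (2,) projected km
    trail: list = dc_field(default_factory=list)  # prior heads, most recent last
    segment_opacities: list = dc_field(default_factory=list)  # one per trail point
    age: int = 0
    max_age: int = 60
    frozen: bool = False  # field was undefined at the head this frame

    def polyline(self) -> np.ndarray:
        return np.array(self.trail + [self.head]) if self.trail else self.head.reshape(1, 2)


@dataclass
class FlowState:
    """Full animation state; advanced in place by :func:`step`."""

    streamlets: list
    rng: np.random.Generator
    domain: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    band: int = 0
    time: Optional[datetime] = None  # start of the current interval
    frame_index: int = 0
    frames_per_interval: int = 120
    fade: float = 0.95
    speed_scale: float = 30.0
    dt_frame: float = 10.0  # simulated seconds per frame (before speed_scale)
    max_age_range: tuple[int, int] = DEFAULT_MAX_AGE_RANGE
    trail_max: int = 90  # oldest (fully faded) trail points are dropped

    @property
    def n(self) -> int:
        return len(self.streamlets)


def _spawn(rng: np.random.Generator, domain, max_age_range) -> Streamlet:
    xmin, xmax, ymin, ymax = domain
    head = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
    return Streamlet(head=head, age=0, max_age=int(rng.integers(*max_age_range)))


def seed(
    domain: tuple[float, float, float, float],
    n: int = DEFAULT_POPULATION,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    band: int = 0,
    start_time: Optional[datetime] = None,
    frames_per_interval: int = 120,
    fade: float = 0.95,
    speed_scale: float = 30.0,
    dt_frame: float = 10.0,
    max_age_range: tuple[int, int] = DEFAULT_MAX_AGE_RANGE,
) -> FlowState:
    """Seed ``n`` streamlets uniformly in the domain box.

    Initial ages are drawn uniformly in [0, max_age) so deaths (and hence
    reseeding) are staggered rather than synchronized.
    """
    xmin, xmax, ymin, ymax = domain
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"seeding domain must have positive area, got {domain}")
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    streamlets = []
    for _ in range(n):
        s = _spawn(rng, domain, max_age_range)
        s.age = int(rng.integers(0, s.max_age))
        streamlets.append(s)
    return FlowState(
        streamlets=streamlets,
        rng=rng,
        domain=domain,
        band=band,
        time=start_time,
        frames_per_interval=frames_per_interval,
        fade=fade,
        speed_scale=speed_scale,
        dt_frame=dt_frame,
        max_age_range=max_age_range,
    )


def step(state: FlowState, field: VectorField) -> FlowState:
    """Advance the animation one frame (in place; returns the state).

    Per streamlet: move the head by field(head) * dt_frame * speed_scale,
    push the old head onto the trail, fade all trail segments, retire and
    replace streamlets whose age reached their lifespan. Every
    ``frames_per_interval`` frames the state's interval advances one
    aggregation window.
    """
    if state.time is None:
        state.time = field.t0
    snapshot = field.at(state.time, state.band)
    km_per_frame = state.dt_frame * state.speed_scale / 1000.0  # m/s -> km
    for i, s in enumerate(state.streamlets):
        s.age += 1
        if s.age >= s.max_age:
            state.streamlets[i] = _spawn(state.rng, state.domain, state.max_age_range)
            continue
        try:
            vel = snapshot.velocity(s.head)
        except FieldUndefinedError:
            s.frozen = True
            s.segment_opacities = [o * state.fade for o in s.segment_opacities]
            continue
        s.frozen = False
        s.trail.append(s.head.copy())
        s.segment_opacities = [o * state.fade for o in s.segment_opacities]
        s.segment_opacities.append(1.0)
        s.head = s.head + vel * km_per_frame
        if len(s.trail) > state.trail_max:
            del s.trail[0], s.segment_opacities[0]
    state.frame_index += 1
    if state.frame_index % state.frames_per_interval == 0:
        new_time = state.time + field.interval
        # hold the last interval rather than stepping off the data
        if new_time < field.t_end:
            state.time = new_time
    return state


def frame_geometry(state: FlowState) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-streamlet (polyline, per-segment opacity) pairs in projected km.

    A streamlet with an empty trail yields a single-point polyline and an
    empty opacity array; a trail of m points yields m segments.
    """
    out = []
    for s in state.streamlets:
        poly = s.polyline()
        out.append((poly, np.asarray(s.segment_opacities, dtype=float)))
    return out


def run(
    state: FlowState, field: VectorField, n_frames: int
) -> list[list[tuple[np.ndarray, np.ndarray]]]:
    """Step ``n_frames`` times, collecting frame geometry after each step."""
    frames = []
    for _ in range(n_frames):
        step(state, field)
        frames.append(frame_geometry(state))
    return frames
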