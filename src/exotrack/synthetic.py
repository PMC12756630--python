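"""Synthetic TIRF scene generation with exact ground truth.

Artificial images of punctate vesicles are built from explicit circle
specifications, corrupted with a normalized two-component noise mixture
(Gaussian and/or Poisson), and optionally animated into time-lapse stacks
carrying simulated exocytosis signatures (linear fluorescence rise followed
by abrupt, complete signal loss).  Because the truth (circle count, per-frame
presence, event frames) is stored alongside, these scenes serve as ground
truth for validating the detection pipeline end to end.

Coordinate convention: 0-based ``(row, col) = (y, x)`` everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CircleSpec",
    "NoiseMix",
    "SceneSpec",
    "EventSpec",
    "EventSchedule",
    "rasterize_circles",
    "compose_noisy",
    "generate_time_lapse",
    "random_scene",
]

GeometryClass = Literal["distinct", "tangent", "intersecting"]
NoiseKind = Literal["gaussian", "poisson"]


class SceneValidationError(ValueError):
    """A scene or schedule specification is malformed."""


@dataclass(frozen=True)
class CircleSpec:
    """A single vesicle-like disc: center ``(y, x)`` and radius in pixels."""

    center_y: float
    center_x: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise SceneValidationError(f"radius must be >= 1, got {self.radius}")


@dataclass(frozen=True)
class NoiseMix:
    """Two-component noise mixture: ``w1*N1 + w2*N2 + (1-(w1+w2))*raw``.

    Each noise field is min-max normalized to [0, 1] before weighting.
    Gaussian noise is zero-mean with standard deviation ``gaussian_sigma``
    (fraction of dynamic range).  Poisson noise is drawn per pixel with rate
    ``poisson_scale * raw``, i.e. shot noise proportional to the underlying
    signal.
    """

    w1: float = 0.2
    w2: float = 0.2
    noise1_kind: NoiseKind = "gaussian"
    noise2_kind: NoiseKind = "poisson"
    gaussian_sigma: float = 0.1
    poisson_scale: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.w1 <= 1 and 0 <= self.w2 <= 1):
            raise SceneValidationError("noise weights must lie in [0, 1]")
        if self.w1 + self.w2 > 1 + 1e-12:
            raise SceneValidationError(
                f"w1 + w2 must be <= 1, got {self.w1 + self.w2}"
            )


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth description of a synthetic image.

    ``geometry_class`` must be consistent with the pairwise center distances:
    distinct means every pair is separated by more than the sum of radii,
    tangent means some pair touches exactly and none overlap, intersecting
    means some pair overlaps.
    """

    shape: tuple[int, int]
    circles: tuple[CircleSpec, ...]
    noise: NoiseMix = NoiseMix()
    geometry_class: GeometryClass | None = None
    foreground_level: float = 1.0
    background_level: float = 0.0

    def __post_init__(self) -> None:
        h, w = self.shape
        if h <= 0 or w <= 0:
            raise SceneValidationError(f"shape must be positive, got {self.shape}")
        if not (0 < self.foreground_level <= 1):
            raise SceneValidationError("foreground_level must lie in (0, 1]")
        if not (0 <= self.background_level < self.foreground_level):
            raise SceneValidationError(
                "background_level must lie in [0, foreground_level)"
            )
        object.__setattr__(self, "circles", tuple(self.circles))
        for c in self.circles:
            if (
                c.center_y + c.radius < 0
                or c.center_y - c.radius > h - 1
                or c.center_x + c.radius < 0
                or c.center_x - c.radius > w - 1
            ):
                raise SceneValidationError(
                    f"circle at ({c.center_y}, {c.center_x}) r={c.radius} lies "
                    "fully outside the frame"
                )
        if self.geometry_class is not None:
            actual = classify_geometry(self.circles)
            if actual != self.geometry_class:
                raise SceneValidationError(
                    f"declared geometry_class {self.geometry_class!r} but circle "
                    f"distances imply {actual!r}"
                )

    @property
    def true_count(self) -> int:
        """Number of circles — the ground-truth particle count, stored, never
        re-derived from the rendered image."""
        return len(self.circles)


def classify_geometry(circles: Sequence[CircleSpec]) -> GeometryClass:
    """Classify a circle set from pairwise center distances."""
    tangent = False
    for i in range(len(circles)):
        for j in range(i + 1, len(circles)):
            a, b = circles[i], circles[j]
            d = math.hypot(a.center_y - b.center_y, a.center_x - b.center_x)
            s = a.radius + b.radius
            if d < s - 1e-9:
                return "intersecting"
            if abs(d - s) <= 1e-9:
                tangent = True
    return "tangent" if tangent else "distinct"


def rasterize_circles(spec: SceneSpec) -> np.ndarray:
    """Render the scene's circles into a clean (noise-free) float frame.

    A pixel ``(y, x)`` takes ``foreground_level`` iff
    ``(y - y1)**2 + (x - x1)**2 <= r**2`` for some circle, else
    ``background_level``.  Circles partially outside the frame are clipped.
    """
    h, w = spec.shape
    frame = np.full((h, w), spec.background_level, dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    for c in spec.circles:
        inside = (yy - c.center_y) ** 2 + (xx - c.center_x) ** 2 <= c.radius**2
        frame[inside] = spec.foreground_level
    return frame


def _normalized_noise(
    kind: NoiseKind, raw: np.ndarray, mix: NoiseMix, rng: np.random.Generator
) -> np.ndarray:
    if kind == "gaussian":
        field_ = rng.normal(0.0, mix.gaussian_sigma, size=raw.shape)
    elif kind == "poisson":
        field_ = rng.poisson(np.clip(raw, 0, None) * mix.poisson_scale).astype(
            np.float64
        )
    else:  # pragma: no cover - guarded by Literal typing
        raise SceneValidationError(f"unknown noise kind {kind!r}")
    lo, hi = field_.min(), field_.max()
    if hi - lo < 1e-300:
        return np.zeros_like(field_)
    return (field_ - lo) / (hi - lo)


def compose_noisy(
    raw: np.ndarray, mix: NoiseMix, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Mix normalized noise fields into a clean frame.

    ``final = w1*noise1 + w2*noise2 + (1 - (w1 + w2))*raw`` with each noise
    field min-max normalized to [0, 1] before weighting; the output therefore
    stays in [0, 1] whenever ``raw`` does.  Deterministic for a fixed
    ``mix.seed`` (or an explicitly supplied generator).
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.min() < -1e-12 or raw.max() > 1 + 1e-12:
        raise SceneValidationError("raw frame must be normalized to [0, 1]")
    if rng is None:
        rng = np.random.default_rng(mix.seed)
    n1 = _normalized_noise(mix.noise1_kind, raw, mix, rng)
    n2 = _normalized_noise(mix.noise2_kind, raw, mix, rng)
    return mix.w1 * n1 + mix.w2 * n2 + (1.0 - (mix.w1 + mix.w2)) * raw


def render_scene(spec: SceneSpec) -> np.ndarray:
    """Rasterize and add the scene's noise mixture (single noisy frame)."""
    return compose_noisy(rasterize_circles(spec), spec.noise)


# ---------------------------------------------------------------------------
# time-lapse generation with exocytosis signatures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventSpec:
    """Scheduled exocytosis signature for one particle.

    The particle's contrast above background rises linearly from baseline
    (multiplier 1) at ``rise_start_frame`` to ``peak_amplitude`` at
    ``peak_frame``, holds, then drops abruptly to pure background at
    ``loss_frame`` and stays lost.
    """

    particle: int
    appear_frame: int = 0
    rise_start_frame: int = 0
    peak_frame: int = 1
    loss_frame: int = 2
    peak_amplitude: float = 1.7

    def __post_init__(self) -> None:
        if not (
            self.appear_frame <= self.rise_start_frame
            < self.peak_frame
            < self.loss_frame
        ):
            raise SceneValidationError(
                "need appear <= rise_start < peak < loss, got "
                f"{self.appear_frame}, {self.rise_start_frame}, "
                f"{self.peak_frame}, {self.loss_frame}"
            )
        if self.peak_amplitude <= 1:
            raise SceneValidationError("peak_amplitude must exceed 1")


@dataclass(frozen=True)
class EventSchedule:
    events: tuple[EventSpec, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        seen = set()
        for e in self.events:
            if e.particle in seen:
                raise SceneValidationError(
                    f"particle {e.particle} scheduled twice"
                )
            seen.add(e.particle)

    def for_particle(self, idx: int) -> EventSpec | None:
        for e in self.events:
            if e.particle == idx:
                return e
        return None


def _multiplier(e: EventSpec | None, t: int) -> float | None:
    """Contrast multiplier of a particle at frame t; None when absent."""
    if e is None:
        return 1.0
    if t < e.appear_frame or t >= e.loss_frame:
        return None
    if t <= e.rise_start_frame:
        return 1.0
    if t <= e.peak_frame:
        frac = (t - e.rise_start_frame) / (e.peak_frame - e.rise_start_frame)
        return 1.0 + (e.peak_amplitude - 1.0) * frac
    return e.peak_amplitude


def generate_time_lapse(
    spec: SceneSpec,
    schedule: EventSchedule,
    n_frames: int,
) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Render a T×H×W stack with scheduled exocytosis signatures.

    Returns ``(stack, truth, events)``:

    * ``stack`` — float64 array in [0, 1], one independent noise draw per
      frame (seeded by ``spec.noise.seed``).
    * ``truth`` — per-frame particle table with columns
      ``frame, particle_id, y, x, r, present``.
    * ``events`` — ground-truth event records, one row per scheduled event
      (``particle_id, appear, rise_start, peak, loss, peak_amplitude``).
    """
    if n_frames < 1:
        raise SceneValidationError("n_frames must be >= 1")
    for e in schedule.events:
        if e.particle >= len(spec.circles):
            raise SceneValidationError(
                f"event references particle {e.particle} but the scene has "
                f"{len(spec.circles)} circles"
            )
        if e.loss_frame > n_frames:
            raise SceneValidationError(
                f"loss_frame {e.loss_frame} beyond n_frames {n_frames}"
            )
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    masks = [
        (yy - c.center_y) ** 2 + (xx - c.center_x) ** 2 <= c.radius**2
        for c in spec.circles
    ]
    contrast = spec.foreground_level - spec.background_level
    rng = np.random.default_rng(spec.noise.seed)

    stack = np.empty((n_frames, h, w), dtype=np.float64)
    truth_rows = []
    for t in range(n_frames):
        raw = np.full((h, w), spec.background_level, dtype=np.float64)
        for i, c in enumerate(spec.circles):
            m = _multiplier(schedule.for_particle(i), t)
            present = m is not None
            if present:
                raw[masks[i]] = np.clip(
                    spec.background_level + contrast * m, 0.0, 1.0
                )
            truth_rows.append(
                {
                    "frame": t,
                    "particle_id": i,
                    "y": c.center_y,
                    "x": c.center_x,
                    "r": c.radius,
                    "present": present,
                }
            )
        stack[t] = compose_noisy(raw, spec.noise, rng=rng)

    events = pd.DataFrame(
        [
            {
                "particle_id": e.particle,
                "appear": e.appear_frame,
                "rise_start": e.rise_start_frame,
                "peak": e.peak_frame,
                "loss": e.loss_frame,
                "peak_amplitude": e.peak_amplitude,
            }
            for e in schedule.events
        ],
        columns=[
            "particle_id", "appear", "rise_start", "peak", "loss",
            "peak_amplitude",
        ],
    )
    return stack, pd.DataFrame(truth_rows), events


def random_scene(
    shape: tuple[int, int],
    n_circles: int,
    radius_range: tuple[float, float],
    rng: np.random.Generator,
    noise: NoiseMix = NoiseMix(),
    foreground_level: float = 1.0,
    background_level: float = 0.0,
    min_gap: float = 2.0,
    max_tries: int = 10_000,
) -> SceneSpec:
    """Draw a distinct-geometry scene by rejection sampling.

    Circle centers are placed uniformly with every pairwise distance
    exceeding ``r_i + r_j + min_gap`` and the full disc inside the frame, so
    the rendered puncta are well separated (the "distinguished" condition).
    """
    h, w = shape
    placed: list[CircleSpec] = []
    tries = 0
    while len(placed) < n_circles:
        tries += 1
        if tries > max_tries:
            raise SceneValidationError(
                f"could not place {n_circles} distinct circles in {shape}"
            )
        r = rng.uniform(*radius_range)
        cy = rng.uniform(r + 1, h - 2 - r)
        cx = rng.uniform(r + 1, w - 2 - r)
        ok = all(
            math.hypot(cy - c.center_y, cx - c.center_x)
            > r + c.radius + min_gap
            for c in placed
        )
        if ok:
            placed.append(CircleSpec(cy, cx, r))
    return SceneSpec(
        shape=shape,
        circles=tuple(placed),
        noise=noise,
        geometry_class="distinct",
        foreground_level=foreground_level,
        background_level=background_level,
    )
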