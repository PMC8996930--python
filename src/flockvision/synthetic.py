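"""Ground-truthed synthetic pen scenes for end-to-end pipeline testing.

Each scene emulates a top-view compartment holding ten broilers: dark
elliptical blobs on a light litter background sprinkled with small dark
specks (feathers/shavings noise). Bird movement is a bounded random walk
with attractor blending — each second a bird either sits or takes a step
whose direction is a mix of a uniformly random heading and the heading
toward an attractor (drinker, feeder, enrichment objects) — not a
behavioural model: it only needs to span controllable crowding (mean
centroid distance, merged blobs) and per-second displacement statistics.

Four regime presets encode the qualitative study conditions: heat stress
slows birds down and pulls them toward attractors (crowding), enrichment
adds attractor objects and raises activity within each temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigurationError, ParameterError
from .indices import CameraGeometry, calibration_factor
from .io_frames import FrameRecord, FrameSequence

RegimeName = Literal[
    "comfort_enriched", "comfort_plain", "stress_enriched", "stress_plain"
]

#: 3-m ceiling camera, 60° lens, 976-px sensor → k ≈ 0.355 cm/px.
DEFAULT_GEOMETRY = CameraGeometry(
    mount_height_cm=300.0, lens_angle_deg=60.0, sensor_length_px=976
)


@dataclass(frozen=True)
class SyntheticSceneConfig:
    """All parameters of one synthetic pen scene.

    Pixel geometry defaults to the native 496 × 976 camera frame; lengths
    given in cm (step sizes) are converted to pixels through ``geometry``.
    ``attractors`` are (row, col, weight) pull points; higher weight wins
    when a bird chooses its nearest attractor (distance is divided by
    weight).
    """

    arena_px: tuple[int, int] = (496, 976)
    n_birds: int = 10
    bird_axes_px: tuple[float, float] = (14.0, 20.0)  # (semi-minor, semi-major)
    bird_intensity: int = 60
    litter_intensity: int = 200
    attractors: tuple[tuple[float, float, float], ...] = ()
    crowding_strength: float = 0.2
    step_cm_per_s: float = 12.0
    step_dispersion_cm: float = 4.0
    sit_probability: float = 0.25
    noise_speck_density: float = 2e-4  # expected specks per pixel per frame
    speck_intensity: int = 120
    seed: int = 0
    geometry: CameraGeometry = DEFAULT_GEOMETRY
    regime: str = "custom"

    def __post_init__(self) -> None:
        if self.n_birds < 1:
            raise ParameterError("n_birds must be >= 1")
        if not (0.0 <= self.crowding_strength <= 1.0):
            raise ParameterError("crowding_strength must be in [0, 1]")
        if not (0.0 <= self.sit_probability <= 1.0):
            raise ParameterError("sit_probability must be in [0, 1]")
        if self.bird_intensity == self.litter_intensity:
            raise ParameterError("bird and litter intensities must differ")
        h, w = self.arena_px
        a, b = self.bird_axes_px
        # rough feasibility: birds at twice their bounding boxes must fit
        if self.n_birds * (2 * a) * (2 * b) * 2 > h * w:
            raise ConfigurationError(
                f"arena {self.arena_px} too small for {self.n_birds} birds "
                f"with axes {self.bird_axes_px}"
            )

    @property
    def k_cm_per_px(self) -> float:
        return calibration_factor(self.geometry)

    @property
    def step_px_per_s(self) -> float:
        return self.step_cm_per_s / self.k_cm_per_px

    @property
    def step_dispersion_px(self) -> float:
        return self.step_dispersion_cm / self.k_cm_per_px


@dataclass
class GroundTruthTrack:
    """True per-second bird centres underlying a rendered sequence.

    ``positions`` has shape (duration_s + 1, n_birds, 2) in (row, col)
    pixels: entry 0 is the initial placement, entry t the positions after t
    seconds.
    """

    positions: np.ndarray
    regime: str
    config: SyntheticSceneConfig

    @property
    def duration_s(self) -> int:
        return self.positions.shape[0] - 1

    def to_dataframe(self) -> pd.DataFrame:
        t_idx, b_idx = np.meshgrid(
            np.arange(self.positions.shape[0]),
            np.arange(self.positions.shape[1]),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "t": t_idx.ravel(),
                "bird_id": b_idx.ravel(),
                "row": self.positions[..., 0].ravel(),
                "col": self.positions[..., 1].ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(Path(path), index=False)


def _default_attractors(
    arena: tuple[int, int], enriched: bool, drinker_weight: float = 1.5
) -> tuple[tuple[float, float, float], ...]:
    """Drinker and feeder for every pen; three enrichment objects if enriched.

    ``drinker_weight`` models the microclimate pull of the water line: under
    heat stress birds congregate near the drinker, so stress presets raise
    this weight far above the other attractors.
    """
    h, w = arena
    base = [
        (0.30 * h, 0.20 * w, drinker_weight),
        (0.70 * h, 0.20 * w, 1.0),  # feeder
    ]
    if enriched:
        # enrichment objects occupy one central band of the pen, so birds
        # drawn to them form one loose aggregation rather than far-flung
        # corner groups
        base += [
            (0.40 * h, 0.45 * w, 1.0),  # hanging rings
            (0.60 * h, 0.55 * w, 1.0),  # sand box
            (0.50 * h, 0.35 * w, 1.0),  # perch
        ]
    return tuple(base)


# Step magnitudes and sit probabilities ordered to reproduce the qualitative
# regime structure: movement comfort > stress within each enrichment level,
# enriched > plain within each temperature, stress_plain slowest/sittiest;
# attractor pull (crowding) stronger under heat stress.
_PRESETS: dict[str, dict] = {
    "comfort_enriched": dict(
        step_cm_per_s=14.0, step_dispersion_cm=4.0, sit_probability=0.15,
        crowding_strength=0.20, enriched=True, drinker_weight=1.5,
    ),
    "comfort_plain": dict(
        step_cm_per_s=12.0, step_dispersion_cm=4.0, sit_probability=0.25,
        crowding_strength=0.15, enriched=False, drinker_weight=1.5,
    ),
    "stress_enriched": dict(
        step_cm_per_s=8.0, step_dispersion_cm=3.0, sit_probability=0.45,
        crowding_strength=0.80, enriched=True, drinker_weight=8.0,
    ),
    "stress_plain": dict(
        step_cm_per_s=6.5, step_dispersion_cm=3.0, sit_probability=0.55,
        crowding_strength=0.80, enriched=False, drinker_weight=8.0,
    ),
}


def regime_preset(
    name: RegimeName, seed: int = 0, scale: float = 1.0
) -> SyntheticSceneConfig:
    """Scene configuration for one temperature × enrichment regime.

    All four presets share the arena, bird count and bird geometry so the
    regimes differ only in movement and crowding parameters. ``scale``
    renders the same pen through a lower-resolution camera: the arena, bird
    axes, attractor coordinates and sensor length shrink together, so k
    grows by 1/scale and cm-level motion statistics are unchanged.
    """
    if name not in _PRESETS:
        raise ParameterError(
            f"unknown regime {name!r}; choose one of {sorted(_PRESETS)}"
        )
    if not (0 < scale <= 1):
        raise ParameterError("scale must be in (0, 1]")
    p = _PRESETS[name]
    arena = (round(496 * scale), round(976 * scale))
    geometry = CameraGeometry(
        mount_height_cm=300.0,
        lens_angle_deg=60.0,
        sensor_length_px=max(1, round(976 * scale)),
    )
    return SyntheticSceneConfig(
        arena_px=arena,
        n_birds=10,
        bird_axes_px=(14.0 * scale, 20.0 * scale),
        attractors=_default_attractors(arena, p["enriched"], p["drinker_weight"]),
        crowding_strength=p["crowding_strength"],
        step_cm_per_s=p["step_cm_per_s"],
        step_dispersion_cm=p["step_dispersion_cm"],
        sit_probability=p["sit_probability"],
        seed=seed,
        geometry=geometry,
        regime=name,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _initial_positions(config: SyntheticSceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping start positions inside the margins."""
    h, w = config.arena_px
    a, b = config.bird_axes_px
    margin = max(a, b) + 1
    min_dist = 2 * max(a, b)
    positions: list[np.ndarray] = []
    for _ in range(10000):
        if len(positions) == config.n_birds:
            break
        cand = np.array(
            [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
        )
        if all(np.linalg.norm(cand - p) >= min_dist for p in positions):
            positions.append(cand)
    if len(positions) < config.n_birds:
        raise ConfigurationError(
            "could not place all birds without overlap; arena too small"
        )
    return np.array(positions)


def _nearest_attractor(
    pos: np.ndarray, attractors: np.ndarray
) -> np.ndarray | None:
    """Attractor minimising weight-discounted distance, or None if none exist."""
    if attractors.size == 0:
        return None
    pts, weights = attractors[:, :2], attractors[:, 2]
    d = np.linalg.norm(pts - pos, axis=1) / weights
    return pts[int(np.argmin(d))]


def simulate_flock(config: SyntheticSceneConfig, duration_s: int) -> GroundTruthTrack:
    """Simulate per-second bird centres for ``duration_s`` seconds.

    Each second every bird independently sits (probability
    ``sit_probability``) or steps: magnitude drawn from a normal with mean
    ``step_cm_per_s`` and sd ``step_dispersion_cm`` (converted to pixels,
    truncated at zero), direction the normalised blend
    ``crowding_strength · (unit vector to its nearest attractor) +
    (1 − crowding_strength) · (uniform random unit vector)``. Positions are
    clipped to the arena margins; a soft pairwise separation keeps birds
    from stacking exactly while still allowing the touching/merging that
    signals crowding. Fully reproducible from ``config.seed``.
    """
    if duration_s < 1:
        raise ParameterError("duration_s must be >= 1")
    rng = np.random.default_rng(config.seed)
    h, w = config.arena_px
    a, b = config.bird_axes_px
    margin = max(a, b) + 1
    soft_dist = 1.0 * max(a, b)  # centres closer than this get nudged apart

    pos = _initial_positions(config, rng)
    attractors = np.asarray(config.attractors, dtype=np.float64).reshape(-1, 3)
    out = np.empty((duration_s + 1, config.n_birds, 2))
    out[0] = pos
    for t in range(1, duration_s + 1):
        new = pos.copy()
        for i in range(config.n_birds):
            if rng.random() < config.sit_probability:
                continue
            mag = max(
                0.0,
                rng.normal(config.step_px_per_s, config.step_dispersion_px),
            )
            theta = rng.uniform(0, 2 * math.pi)
            u_rand = np.array([math.sin(theta), math.cos(theta)])
            target = _nearest_attractor(pos[i], attractors)
            if target is None or config.crowding_strength == 0:
                direction = u_rand
            else:
                u_att = _unit(target - pos[i])
                direction = _unit(
                    config.crowding_strength * u_att
                    + (1 - config.crowding_strength) * u_rand
                )
                if not np.any(direction):
                    direction = u_rand
            new[i] = pos[i] + mag * direction
        # soft non-overlap relaxation: single symmetric pass
        for i in range(config.n_birds):
            for j in range(i + 1, config.n_birds):
                delta = new[j] - new[i]
                d = np.linalg.norm(delta)
                if d < soft_dist:
                    push = _unit(delta if d > 0 else rng.normal(size=2))
                    shift = min(2.0, (soft_dist - d) / 2)
                    new[i] -= push * shift
                    new[j] += push * shift
        new[:, 0] = np.clip(new[:, 0], margin, h - margin)
        new[:, 1] = np.clip(new[:, 1], margin, w - margin)
        pos = new
        out[t] = pos
    return GroundTruthTrack(positions=out, regime=config.regime, config=config)


def render_frames(
    track: GroundTruthTrack, config: SyntheticSceneConfig | None = None
) -> FrameSequence:
    """Rasterise a track into a 1-fps grayscale frame sequence.

    Litter background at ``litter_intensity``, one filled ellipse per bird
    at ``bird_intensity`` (fixed per-bird orientation drawn once from the
    seed), and dark single-pixel specks at ``noise_speck_density`` per
    pixel. Deterministic from ``config.seed``.
    """
    config = config or track.config
    if track.positions.shape[1] != config.n_birds:
        raise ConfigurationError("track bird count does not match config")
    h, w = config.arena_px
    a, b = config.bird_axes_px
    orient_rng = np.random.default_rng([config.seed, 7341])
    orientations = orient_rng.uniform(0, math.pi, size=config.n_birds)
    n_frames = track.positions.shape[0]
    frames = []
    for t in range(n_frames):
        pixels = np.full((h, w), config.litter_intensity, dtype=np.uint8)
        speck_rng = np.random.default_rng([config.seed, 9050, t])
        n_specks = speck_rng.poisson(config.noise_speck_density * h * w)
        if n_specks > 0:
            rr = speck_rng.integers(0, h, size=n_specks)
            cc = speck_rng.integers(0, w, size=n_specks)
            pixels[rr, cc] = config.speck_intensity
        for i in range(config.n_birds):
            r, c = track.positions[t, i]
            rr, cc = draw_ellipse(
                r, c, a, b, shape=(h, w), rotation=orientations[i]
            )
            pixels[rr, cc] = config.bird_intensity
        frames.append(FrameRecord(index=t, timestamp_s=float(t), pixels=pixels))
    return FrameSequence(frames=frames, sample_rate_fps=1.0)


def save_config(config: SyntheticSceneConfig, path: str | Path) -> None:
    """Write a scene configuration as a YAML file."""
    import yaml
    from dataclasses import asdict

    d = asdict(config)
    d["attractors"] = [list(a) for a in config.attractors]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_config(path: str | Path) -> SyntheticSceneConfig:
    """Read a scene configuration written by :func:`save_config`."""
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["arena_px"] = tuple(d["arena_px"])
    d["bird_axes_px"] = tuple(d["bird_axes_px"])
    d["attractors"] = tuple(tuple(a) for a in d.get("attractors", ()))
    d["geometry"] = CameraGeometry(**d["geometry"])
    return SyntheticSceneConfig(**d)


def write_scene(
    track: GroundTruthTrack,
    directory: str | Path,
    config: SyntheticSceneConfig | None = None,
) -> None:
    """Write rendered PNG frames plus the ground-truth CSV to a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seq = render_frames(track, config)
    seq.dump_png(directory)
    track.to_csv(directory / "ground_truth.csv")
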