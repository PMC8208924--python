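"""Task-environment geometry: the hidden two-layer foraging arena.

The arena is a square aerial map hiding circular resource patches; entering
a patch opens a separate, same-sized "patch view" canvas on which the
patch's resources are scattered.  Patch centers and resource positions are
drawn by uniform rejection sampling subject to minimum-distance
constraints.  A run-level countdown counter decreases linearly so that it
reaches zero exactly when the run ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "EnvironmentConfig",
    "Patch",
    "PatchLayout",
    "InfeasibleLayoutError",
    "generate_patch_layout",
    "generate_resource_field",
    "validate_layout",
    "counter_value",
    "layout_to_json",
    "layout_from_json",
]


class InfeasibleLayoutError(RuntimeError):
    """Raised when rejection sampling exhausts its attempt budget."""


@dataclass(frozen=True)
class EnvironmentConfig:
    """Geometry, kinematics and timing of one foraging run.

    All lengths are in pixels, durations in seconds, speeds in px/s.
    Defaults describe a 600 x 600 px arena with nine hidden patches of
    radius 57 px, each holding 40 resources, explored for 300 s.
    """

    arena_size: float = 600.0
    n_patches: int = 9
    patch_radius: float = 57.0
    resources_per_patch: int = 40
    min_patch_gap: float = 9.0
    min_border_distance: float = 15.0
    min_center_distance: float = 57.0
    aerial_reveal_radius: float = 15.0
    resource_reveal_radius: float = 30.0
    min_resource_spacing: float = 30.0
    aerial_max_speed: float = 60.0
    patch_max_speed: float = 90.0
    run_duration: float = 300.0
    counter_rate: float = 60.0
    max_placement_attempts: int = 10_000

    def __post_init__(self) -> None:
        positive = (
            "arena_size",
            "patch_radius",
            "min_patch_gap",
            "min_border_distance",
            "min_center_distance",
            "aerial_reveal_radius",
            "resource_reveal_radius",
            "min_resource_spacing",
            "aerial_max_speed",
            "patch_max_speed",
            "run_duration",
            "counter_rate",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.n_patches < 1:
            raise ValueError(f"n_patches must be >= 1, got {self.n_patches}")
        if self.resources_per_patch < 1:
            raise ValueError(f"resources_per_patch must be >= 1, got {self.resources_per_patch}")
        if self.max_placement_attempts < 1:
            raise ValueError("max_placement_attempts must be >= 1")

    @property
    def counter_start(self) -> float:
        """Initial counter value: aerial max speed times run duration."""
        return self.aerial_max_speed * self.run_duration


@dataclass
class Patch:
    """One hidden patch: aerial-frame center plus patch-view resources."""

    id: int
    center: tuple[float, float]
    radius: float
    resources: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class PatchLayout:
    """A full arena layout: patches, the config that produced it, the seed."""

    patches: list[Patch]
    config: EnvironmentConfig
    seed: int


def generate_resource_field(config: EnvironmentConfig, seed: int) -> list[tuple[float, float]]:
    """Scatter ``resources_per_patch`` points on the patch-view canvas.

    Points are drawn uniformly on the full ``arena_size`` x ``arena_size``
    canvas by rejection sampling, keeping every pair of resource centers
    at least ``min_resource_spacing`` apart.

    Raises
    ------
    InfeasibleLayoutError
        If ``max_placement_attempts`` rejections are exhausted (the
        requested spacing cannot be met on this canvas).
    """
    rng = np.random.default_rng(seed)
    size = config.arena_size
    spacing2 = config.min_resource_spacing**2
    points: list[tuple[float, float]] = []
    attempts = 0
    while len(points) < config.resources_per_patch:
        if attempts >= config.max_placement_attempts:
            raise InfeasibleLayoutError(
                "infeasible spacing: could not place "
                f"{config.resources_per_patch} resources at spacing "
                f"{config.min_resource_spacing} within "
                f"{config.max_placement_attempts} attempts"
            )
        x, y = rng.uniform(0.0, size, size=2)
        attempts += 1
        if all((x - px) ** 2 + (y - py) ** 2 >= spacing2 for px, py in points):
            points.append((float(x), float(y)))
    return points


def generate_patch_layout(config: EnvironmentConfig, seed: int) -> PatchLayout:
    """Draw a full arena layout by uniform rejection sampling.

    Patch centers are drawn uniformly over the arena subject to three
    constraints, all measured with Euclidean center distances:

    * boundary gap: center-to-center distance between any two patches is
      at least ``2 * patch_radius + min_patch_gap``;
    * border clearance: the patch boundary stays at least
      ``min_border_distance`` from every arena border, i.e. centers lie
      at least ``patch_radius + min_border_distance`` from each edge;
    * arena-center clearance: each patch center is at least
      ``min_center_distance`` from the arena midpoint.

    Per-patch resource fields are drawn with :func:`generate_resource_field`
    using seeds spawned deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    size = config.arena_size
    margin = config.patch_radius + config.min_border_distance
    if 2 * margin >= size:
        raise InfeasibleLayoutError(
            "infeasible layout: border clearance leaves no room for patch centers"
        )
    min_cc = 2 * config.patch_radius + config.min_patch_gap
    cx = cy = size / 2.0
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < config.n_patches:
        if attempts >= config.max_placement_attempts:
            raise InfeasibleLayoutError(
                f"infeasible layout: placed {len(centers)}/{config.n_patches} "
                f"patches within {config.max_placement_attempts} attempts"
            )
        x = rng.uniform(margin, size - margin)
        y = rng.uniform(margin, size - margin)
        attempts += 1
        if (x - cx) ** 2 + (y - cy) ** 2 < config.min_center_distance**2:
            continue
        if any((x - ox) ** 2 + (y - oy) ** 2 < min_cc**2 for ox, oy in centers):
            continue
        centers.append((float(x), float(y)))

    resource_seeds = np.random.SeedSequence(seed).spawn(config.n_patches)
    patches = [
        Patch(
            id=i,
            center=centers[i],
            radius=config.patch_radius,
            resources=generate_resource_field(
                config, int(resource_seeds[i].generate_state(1)[0] % (2**31))
            ),
        )
        for i in range(config.n_patches)
    ]
    return PatchLayout(patches=patches, config=config, seed=seed)


def validate_layout(layout: PatchLayout) -> list[str]:
    """Check every placement constraint; return human-readable violations.

    An empty list means the layout satisfies the full
    :func:`generate_patch_layout` contract.
    """
    cfg = layout.config
    size = cfg.arena_size
    cx = cy = size / 2.0
    violations: list[str] = []

    if len(layout.patches) != cfg.n_patches:
        violations.append(
            f"patch count: expected {cfg.n_patches}, found {len(layout.patches)}"
        )

    min_cc = 2 * cfg.patch_radius + cfg.min_patch_gap
    for i, p in enumerate(layout.patches):
        x, y = p.center
        margin = p.radius + cfg.min_border_distance
        if not (margin <= x <= size - margin and margin <= y <= size - margin):
            violations.append(
                f"border clearance: patch {p.id} center {p.center} closer than "
                f"{cfg.min_border_distance} px (boundary-to-border) to an edge"
            )
        if np.hypot(x - cx, y - cy) < cfg.min_center_distance:
            violations.append(
                f"arena-center clearance: patch {p.id} center {p.center} within "
                f"{cfg.min_center_distance} px of the arena midpoint"
            )
        for q in layout.patches[i + 1 :]:
            d = np.hypot(x - q.center[0], y - q.center[1])
            if d < min_cc:
                violations.append(
                    f"patch overlap: patches {p.id} and {q.id} centers {d:.2f} px "
                    f"apart, need >= {min_cc:.2f}"
                )
        if len(p.resources) != cfg.resources_per_patch:
            violations.append(
                f"resource count: patch {p.id} has {len(p.resources)}, "
                f"expected {cfg.resources_per_patch}"
            )
        for (rx, ry) in p.resources:
            if not (0.0 <= rx <= size and 0.0 <= ry <= size):
                violations.append(
                    f"resource bounds: patch {p.id} resource ({rx:.1f}, {ry:.1f}) "
                    "outside the patch-view canvas"
                )
        pts = np.asarray(p.resources, dtype=float)
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                d = float(np.hypot(*(pts[a] - pts[b])))
                if d < cfg.min_resource_spacing:
                    violations.append(
                        f"resource spacing: patch {p.id} resources {a} and {b} are "
                        f"{d:.2f} px apart, need >= {cfg.min_resource_spacing}"
                    )
    return violations


def counter_value(t: float, config: EnvironmentConfig | None = None) -> float:
    """On-screen countdown at time ``t``: start value minus rate * t, floored at 0.

    With defaults the counter starts at 18,000 (60 px/s * 300 s) and
    decreases by 60 units per second, reaching 0 exactly at the run's end.
    """
    if config is None:
        config = EnvironmentConfig()
    if not (0.0 <= t <= config.run_duration):
        raise ValueError(f"t={t!r} outside [0, {config.run_duration}]")
    return max(0.0, config.counter_start - config.counter_rate * t)


def layout_to_json(layout: PatchLayout) -> str:
    """Serialize a layout (config echo, seed, centers, resources) to JSON."""
    doc = {
        "config": asdict(layout.config),
        "seed": layout.seed,
        "patches": [
            {
                "id": p.id,
                "center": list(p.center),
                "radius": p.radius,
                "resources": [list(r) for r in p.resources],
            }
            for p in layout.patches
        ],
    }
    return json.dumps(doc, indent=1)


def layout_from_json(text: str) -> PatchLayout:
    """Inverse of :func:`layout_to_json`; bit-exact on numeric fields."""
    doc = json.loads(text)
    config = EnvironmentConfig(**doc["config"])
    patches = [
        Patch(
            id=int(p["id"]),
            center=(float(p["center"][0]), float(p["center"][1])),
            radius=float(p["radius"]),
            resources=[(float(x), float(y)) for x, y in p["resources"]],
        )
        for p in doc["patches"]
    ]
    return PatchLayout(patches=patches, config=config, seed=int(doc["seed"]))
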