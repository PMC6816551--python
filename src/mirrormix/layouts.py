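"""Task geometry: landmarks, targets and their symmetry structure.

Both virtual arenas used elongated, locally symmetric landmarks, so every
target has a *local mirror*: the location obtained by reflecting it across
its nearest landmark's symmetry axis.  Responses at the mirror are the
diagnostic error for single-cue (one-landmark) spatial coding, and the
response models in :mod:`mirrormix.response_models` are mixtures over these
target/mirror locations.

Exact target coordinates were never published; the canonical layouts shipped
with the package are reconstructions from the stated constraints (arena
radius, landmark lengths and separations, the 1.2 m end-mirror distance) and
live in versioned YAML files so that measured coordinates can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Landmark",
    "TargetDef",
    "Layout",
    "canonical_layout",
    "load_layout",
    "nearest_landmark",
    "nearest_target",
    "pairwise_target_distances",
]

CANONICAL_NAMES = ("arctic", "jetty")


@dataclass(frozen=True)
class Landmark:
    """An elongated elliptical landmark in the overhead plane (metres)."""

    id: int
    label: str
    center: tuple[float, float]
    orientation: float  # radians, direction of the major axis
    semi_major: float
    semi_minor: float

    def __post_init__(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError(
                f"landmark {self.id}: need semi_major >= semi_minor > 0, "
                f"got {self.semi_major}, {self.semi_minor}"
            )


@dataclass(frozen=True)
class TargetDef:
    """A response target, tied to its nearest landmark and its local mirror."""

    id: int
    position: tuple[float, float]
    landmark_id: int
    relation: str  # "end" or "side" of the landmark
    mirror_id: int

    def __post_init__(self) -> None:
        if self.relation not in ("end", "side"):
            raise ValueError(f"target {self.id}: unknown relation {self.relation!r}")


@dataclass(frozen=True)
class Layout:
    """One arena: landmarks, targets, symmetry pairing and chance levels.

    ``chance_p1`` is the probability of picking the correct landmark by
    guessing (1 / number of landmarks).  ``has_side_targets`` records whether
    the side/end distinction exists (it does not in the jetty arena, whose
    targets are all on landmark ends).
    """

    name: str
    arena_radius: float
    landmarks: tuple[Landmark, ...]
    targets: tuple[TargetDef, ...]
    chance_p1: float
    has_side_targets: bool
    provenance: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- derived arrays ---------------------------------------------------

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def target_ids(self) -> tuple[int, ...]:
        return tuple(t.id for t in self.targets)

    def target_positions(self) -> np.ndarray:
        """(T, 2) array of target centres, row order = ``target_ids``."""
        return np.array([t.position for t in self.targets], dtype=float)

    def landmark_centers(self) -> np.ndarray:
        return np.array([lm.center for lm in self.landmarks], dtype=float)

    def target(self, target_id: int) -> TargetDef:
        for t in self.targets:
            if t.id == target_id:
                return t
        raise KeyError(f"layout {self.name!r} has no target {target_id}")

    def target_index(self, target_id: int) -> int:
        for i, t in enumerate(self.targets):
            if t.id == target_id:
                return i
        raise KeyError(f"layout {self.name!r} has no target {target_id}")

    def mirror_of(self, target_id: int) -> int:
        return self.target(target_id).mirror_id

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        ids = [t.id for t in self.targets]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate target ids")
        lm_ids = {lm.id for lm in self.landmarks}
        if len(lm_ids) != len(self.landmarks):
            raise ValueError("duplicate landmark ids")
        for t in self.targets:
            if t.landmark_id not in lm_ids:
                raise ValueError(f"target {t.id} references unknown landmark")
            m = self.target(t.mirror_id)
            if m.mirror_id != t.id:
                raise ValueError(f"mirror pairing not an involution at target {t.id}")
            if t.id == t.mirror_id:
                raise ValueError(f"target {t.id} is its own mirror")
            if (m.landmark_id, m.relation) != (t.landmark_id, t.relation):
                raise ValueError(
                    f"target {t.id} and mirror {m.id} differ in landmark/relation"
                )
            if nearest_landmark(self, t.position) != t.landmark_id:
                raise ValueError(f"target {t.id} is not nearest its own landmark")
            r = math.hypot(*t.position)
            if r > self.arena_radius:
                raise ValueError(f"target {t.id} lies outside the arena")
        centers = self.landmark_centers()
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) < 1.5 - 1e-9:
                    raise ValueError("landmark centres closer than 1.5 m")
        if not self.has_side_targets and any(t.relation == "side" for t in self.targets):
            raise ValueError("side targets present but has_side_targets is false")


def _layout_from_dict(spec: dict, provenance: str = "") -> Layout:
    landmarks = tuple(
        Landmark(
            id=int(lm["id"]),
            label=str(lm["label"]),
            center=tuple(float(v) for v in lm["center"]),
            orientation=float(lm["orientation"]),
            semi_major=float(lm["semi_major"]),
            semi_minor=float(lm["semi_minor"]),
        )
        for lm in spec["landmarks"]
    )
    targets = tuple(
        TargetDef(
            id=int(t["id"]),
            position=tuple(float(v) for v in t["position"]),
            landmark_id=int(t["landmark_id"]),
            relation=str(t["relation"]),
            mirror_id=int(t["mirror_id"]),
        )
        for t in spec["targets"]
    )
    return Layout(
        name=str(spec["name"]),
        arena_radius=float(spec["arena_radius"]),
        landmarks=landmarks,
        targets=targets,
        chance_p1=float(spec["chance_p1"]),
        has_side_targets=bool(spec["has_side_targets"]),
        provenance=provenance,
    )


def load_layout(path: str | Path) -> Layout:
    """Load and validate a layout from a YAML file."""
    path = Path(path)
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return _layout_from_dict(spec, provenance=str(path))


def canonical_layout(name: str) -> Layout:
    """Return the canonical reconstruction of one of the two arenas.

    Parameters
    ----------
    name : {"arctic", "jetty"}
        ``arctic``: 2.5 m arena, two 1 m landmarks at a right angle, 8 targets
        (two ends and two sides per landmark), end-mirror pairs 1.2 m apart,
        landmark-guessing chance 1/2.  ``jetty``: three 0.8 m landmarks at
        oblique angles, 6 end targets, chance 1/3.
    """
    if name not in CANONICAL_NAMES:
        raise ValueError(f"unknown layout {name!r}; expected one of {CANONICAL_NAMES}")
    ref = resources.files("mirrormix.data").joinpath(f"{name}.yaml")
    spec = yaml.safe_load(ref.read_text())
    return _layout_from_dict(spec, provenance=f"canonical:{name}")


def nearest_landmark(layout: Layout, point) -> int:
    """Id of the landmark whose centre is closest to ``point``.

    Centre-to-centre distance, ties broken to the lowest id (landmarks are
    listed in id order in the canonical files).
    """
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point coordinates must be finite")
    d = np.linalg.norm(layout.landmark_centers() - p, axis=1)
    order = np.lexsort((np.array([lm.id for lm in layout.landmarks]), d))
    return int(layout.landmarks[order[0]].id)


def nearest_target(layout: Layout, point) -> int:
    """Id of the target whose centre is closest to ``point`` (ties: lowest id)."""
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point coordinates must be finite")
    d = np.linalg.norm(layout.target_positions() - p, axis=1)
    order = np.lexsort((np.array(layout.target_ids), d))
    return int(layout.targets[order[0]].id)


def pairwise_target_distances(layout: Layout) -> np.ndarray:
    """Symmetric (T, T) matrix of Euclidean distances between target centres."""
    pos = layout.target_positions()
    return np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
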