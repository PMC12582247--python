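"""Canonical data model for planar locomotion bouts and species configuration.

The package analyses walking kinematics of any legged species from two planar
coordinates per marker: ``x`` is fore-aft (positive along the direction of
travel after heading alignment) and ``y`` is lateral (positive to the left of
travel).  A :class:`SpeciesProfile` describes the embodiment -- how many legs,
how they are grouped into the two alternating support sets of walking gaits,
which markers constitute the body state -- and a :class:`TrajectoryBout` holds
one continuous recording.

Units are species-native (mm for small-arena data, m for motion capture); all
downstream quantities (regression slopes, R^2, correlations, spectral radii)
are either unit-covariant or unit-free, so no conversion is performed.

Canonical file formats
----------------------
HDF5: one group per bout with datasets ``t`` and ``pos/<marker>`` (n x 2,
columns x, y) and attributes ``bout_id``, ``animal_id``, ``species``.
CSV (long): columns ``bout_id, animal_id, t, marker, x, y``.
Species profiles are stored as YAML mappings of the profile fields.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("stablegait")

#: Maximum fraction of non-finite samples per marker that will be repaired by
#: linear interpolation; above this the bout is rejected.
MAX_GAP_FRACTION = 0.05

#: Default straightness threshold in degrees (heading range per retained bout).
DEFAULT_STRAIGHTNESS_DEG = 30.0


class SchemaError(ValueError):
    """A file does not conform to the canonical bout schema."""


class ValidationError(ValueError):
    """Data are structurally valid but violate a bout invariant."""


@dataclass(frozen=True)
class SpeciesProfile:
    """Embodiment description of a legged walker.

    Parameters
    ----------
    name : str
        Species or configuration label.
    leg_labels : tuple of str
        Leg marker names ordered anterior to posterior, left before right
        within a segment (e.g. ``("left", "right")`` for a biped).
    limb_groups : pair of tuples
        Two-set partition of ``leg_labels`` into the alternating support
        groups of walking (contralateral legs for bipeds, diagonal pairs for
        trot, tripods for hexapods).
    body_markers : tuple of str
        Markers whose positions and velocities constitute the body state.
    frame_rate : float
        Sampling rate in Hz.
    phase_grid_size : int
        Number of uniform gait-fraction samples per normalized cycle; by
        convention set near the average number of raw frames per cycle.
    straightness_threshold : float
        Maximum heading range (degrees) for a bout segment to count as
        straight-line locomotion.
    """

    name: str
    leg_labels: tuple[str, ...]
    limb_groups: tuple[tuple[str, ...], tuple[str, ...]]
    body_markers: tuple[str, ...]
    frame_rate: float
    phase_grid_size: int = 50
    straightness_threshold: float = DEFAULT_STRAIGHTNESS_DEG

    def __post_init__(self) -> None:
        groups = tuple(tuple(g) for g in self.limb_groups)
        object.__setattr__(self, "limb_groups", groups)
        object.__setattr__(self, "leg_labels", tuple(self.leg_labels))
        object.__setattr__(self, "body_markers", tuple(self.body_markers))
        if len(groups) != 2:
            raise ValidationError("limb_groups must contain exactly two groups")
        flat = [leg for g in groups for leg in g]
        if sorted(flat) != sorted(self.leg_labels) or len(set(flat)) != len(flat):
            raise ValidationError("limb_groups must partition leg_labels")
        if self.phase_grid_size < 4:
            raise ValidationError("phase_grid_size must be >= 4")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")

    @property
    def n_legs(self) -> int:
        return len(self.leg_labels)

    @property
    def markers(self) -> tuple[str, ...]:
        return self.body_markers + self.leg_labels

    def group_of(self, leg: str) -> int:
        for i, g in enumerate(self.limb_groups):
            if leg in g:
                return i
        raise KeyError(f"unknown leg {leg!r}")

    def front_leg(self, group: int) -> str:
        """Anterior-most leg of a support group (leg_labels order)."""
        members = self.limb_groups[group]
        for leg in self.leg_labels:
            if leg in members:
                return leg
        raise ValueError("empty limb group")

    @property
    def front_legs(self) -> tuple[str, str]:
        return (self.front_leg(0), self.front_leg(1))

    def opposite_front(self, leg: str) -> str:
        """Front limb of the support group opposite to ``leg``."""
        return self.front_leg(1 - self.group_of(leg))


@dataclass(frozen=True)
class ContactEvent:
    """One stance period of one leg.

    ``placement`` is the contact location P = (p_x, p_y), the mean foot
    position over the stance interval.
    """

    leg: str
    onset_index: int
    offset_index: int
    placement: tuple[float, float]
    onset_time: float = float("nan")
    offset_time: float = float("nan")

    def __post_init__(self) -> None:
        if not self.onset_index < self.offset_index:
            raise ValidationError("contact onset must precede offset")
        if not np.all(np.isfinite(self.placement)):
            raise ValidationError("contact placement must be finite")


@dataclass
class TrajectoryBout:
    """One continuous locomotion bout: time-stamped planar marker positions."""

    bout_id: str
    species: SpeciesProfile
    t: np.ndarray
    positions: dict[str, np.ndarray]
    animal_id: str = ""
    provided_contacts: dict[str, list[ContactEvent]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.animal_id:
            self.animal_id = self.bout_id

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def copy(self) -> "TrajectoryBout":
        return TrajectoryBout(
            bout_id=self.bout_id,
            species=self.species,
            t=self.t.copy(),
            positions={k: v.copy() for k, v in self.positions.items()},
            animal_id=self.animal_id,
            provided_contacts=self.provided_contacts,
            meta=dict(self.meta),
        )


def validate_bout(bout: TrajectoryBout) -> TrajectoryBout:
    """Validate a bout in place, repairing small tracking gaps.

    Time must be strictly increasing; every marker named in the species
    profile must be present with one (x, y) row per frame.  Runs of
    non-finite samples covering at most ``MAX_GAP_FRACTION`` of a marker's
    series are linearly interpolated (tracker dropouts); larger losses
    reject the bout.  Validation is idempotent.
    """
    t = np.asarray(bout.t, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValidationError(f"bout {bout.bout_id}: need >= 2 frames")
    if not np.all(np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise ValidationError(f"bout {bout.bout_id}: time must be strictly increasing")
    bout.t = t
    for marker in bout.species.markers:
        if marker not in bout.positions:
            raise SchemaError(f"bout {bout.bout_id}: missing marker {marker!r}")
        pos = np.asarray(bout.positions[marker], dtype=float)
        if pos.shape != (len(t), 2):
            raise ValidationError(
                f"bout {bout.bout_id}: marker {marker!r} has shape {pos.shape}, "
                f"expected {(len(t), 2)}"
            )
        bad = ~np.all(np.isfinite(pos), axis=1)
        if bad.any():
            frac = bad.mean()
            if frac > MAX_GAP_FRACTION:
                raise ValidationError(
                    f"bout {bout.bout_id}: marker {marker!r} has {frac:.1%} "
                    f"non-finite samples (limit {MAX_GAP_FRACTION:.0%})"
                )
            good = ~bad
            for c in (0, 1):
                pos[bad, c] = np.interp(t[bad], t[good], pos[good, c])
            logger.info(
                "bout %s: interpolated %d gap frames in marker %s",
                bout.bout_id, int(bad.sum()), marker,
            )
        bout.positions[marker] = pos
    # Restrict to the markers the profile names.
    bout.positions = {m: bout.positions[m] for m in bout.species.markers}
    return bout


# ---------------------------------------------------------------------------
# Species profile YAML I/O
# ---------------------------------------------------------------------------

def load_profile(path: str | Path) -> SpeciesProfile:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return SpeciesProfile(
        name=raw["name"],
        leg_labels=tuple(raw["leg_labels"]),
        limb_groups=tuple(tuple(g) for g in raw["limb_groups"]),
        body_markers=tuple(raw["body_markers"]),
        frame_rate=float(raw["frame_rate"]),
        phase_grid_size=int(raw.get("phase_grid_size", 50)),
        straightness_threshold=float(
            raw.get("straightness_threshold", DEFAULT_STRAIGHTNESS_DEG)
        ),
    )


def save_profile(profile: SpeciesProfile, path: str | Path) -> Path:
    path = Path(path)
    data = {
        "name": profile.name,
        "leg_labels": list(profile.leg_labels),
        "limb_groups": [list(g) for g in profile.limb_groups],
        "body_markers": list(profile.body_markers),
        "frame_rate": profile.frame_rate,
        "phase_grid_size": profile.phase_grid_size,
        "straightness_threshold": profile.straightness_threshold,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# Built-in synthetic embodiments
# ---------------------------------------------------------------------------

def builtin_profile(kind: str, frame_rate: float = 50.0,
                    phase_grid_size: int = 50) -> SpeciesProfile:
    """Built-in synthetic embodiments: ``biped``, ``quadruped``, ``hexapod``.

    The biped alternates left/right (2x1), the quadruped trots on diagonal
    pairs (2x2) and the hexapod walks in alternating tripods (2x3).  All use
    a single ``body`` marker.
    """
    if kind == "biped":
        legs = ("left", "right")
        groups = (("left",), ("right",))
    elif kind == "quadruped":
        legs = ("front_left", "front_right", "hind_left", "hind_right")
        groups = (("front_left", "hind_right"), ("front_right", "hind_left"))
    elif kind == "hexapod":
        legs = ("front_left", "front_right", "mid_left", "mid_right",
                "hind_left", "hind_right")
        groups = (("front_left", "mid_right", "hind_left"),
                  ("front_right", "mid_left", "hind_right"))
    else:
        raise ValueError(f"unknown builtin profile {kind!r}")
    return SpeciesProfile(
        name=kind,
        leg_labels=legs,
        limb_groups=groups,
        body_markers=("body",),
        frame_rate=frame_rate,
        phase_grid_size=phase_grid_size,
    )


# ---------------------------------------------------------------------------
# Bout file I/O
# ---------------------------------------------------------------------------

def write_bouts(bouts: Sequence[TrajectoryBout], path: str | Path) -> Path:
    """Write bouts to a canonical-schema file (HDF5 ``.h5``/``.hdf5`` or CSV).

    ``load_bouts(write_bouts(b))`` reproduces time and positions
    bit-compatibly at double precision.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.attrs["schema"] = "stablegait-bouts-v1"
            for bout in bouts:
                grp = fh.create_group(bout.bout_id)
                grp.attrs["bout_id"] = bout.bout_id
                grp.attrs["animal_id"] = bout.animal_id
                grp.attrs["species"] = bout.species.name
                grp.create_dataset("t", data=np.asarray(bout.t, dtype=np.float64))
                pos = grp.create_group("pos")
                for marker, xy in bout.positions.items():
                    pos.create_dataset(marker, data=np.asarray(xy, dtype=np.float64))
    elif path.suffix == ".csv":
        frames = []
        for bout in bouts:
            for marker, xy in bout.positions.items():
                frames.append(pd.DataFrame({
                    "bout_id": bout.bout_id,
                    "animal_id": bout.animal_id,
                    "t": bout.t,
                    "marker": marker,
                    "x": xy[:, 0],
                    "y": xy[:, 1],
                }))
        cols = ["bout_id", "animal_id", "t", "marker", "x", "y"]
        df = pd.concat(frames) if frames else pd.DataFrame(columns=cols)
        df.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unsupported bout file extension {path.suffix!r}")
    return path


def load_bouts(path: str | Path, profile: SpeciesProfile) -> list[TrajectoryBout]:
    """Load and validate bouts from a canonical-schema HDF5 or CSV file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    bouts: list[TrajectoryBout] = []
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            for key in sorted(fh.keys()):
                grp = fh[key]
                positions = {m: np.asarray(grp["pos"][m]) for m in grp["pos"]}
                bouts.append(TrajectoryBout(
                    bout_id=str(grp.attrs.get("bout_id", key)),
                    species=profile,
                    t=np.asarray(grp["t"]),
                    positions=positions,
                    animal_id=str(grp.attrs.get("animal_id", key)),
                ))
    elif path.suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"bout_id", "t", "marker", "x", "y"}
        if not required.issubset(df.columns):
            raise SchemaError(
                f"CSV missing columns {sorted(required - set(df.columns))}"
            )
        for bout_id, sub in df.groupby("bout_id", sort=True):
            positions = {}
            t_ref = None
            for marker, block in sub.groupby("marker", sort=True):
                block = block.sort_values("t")
                if t_ref is None:
                    t_ref = block["t"].to_numpy(dtype=float)
                positions[marker] = block[["x", "y"]].to_numpy(dtype=float)
            animal = (str(sub["animal_id"].iloc[0])
                      if "animal_id" in sub.columns else str(bout_id))
            bouts.append(TrajectoryBout(
                bout_id=str(bout_id), species=profile, t=t_ref,
                positions=positions, animal_id=animal,
            ))
    else:
        raise ValueError(f"unsupported bout file extension {path.suffix!r}")
    return [validate_bout(b) for b in bouts]
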