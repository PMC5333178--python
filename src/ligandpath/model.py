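"""Core data model: frames, trajectories, tunnel profiles and simplification state.

All time-step indexing is 0-based; intervals are half-open ``[start, end)``.
Coordinates are in Angstrom, time spacing in femtoseconds, charges in
elementary charge units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .scales import vdw_radius


class ValidationError(ValueError):
    """Input violates a documented invariant (exit code 1 in the CLI)."""


class FormatError(ValidationError):
    """A file could not be parsed as its declared format."""


class SelectionError(ValidationError):
    """An atom/residue selection matched nothing or was ambiguous."""


class ConsistencyError(ValidationError):
    """Structurally valid inputs that disagree with each other."""


# ---------------------------------------------------------------------------
# spatial context


@dataclass
class FrameSet:
    """Per-time-step protein atom coordinates with residue/atom metadata.

    ``coords`` has shape (n_frames, n_atoms, 3); annotation arrays have
    length n_atoms and are constant across frames (atom ordering is stable).
    """

    coords: np.ndarray
    elements: np.ndarray
    atom_names: np.ndarray
    res_names: np.ndarray
    res_ids: np.ndarray
    chain_ids: np.ndarray
    charges: np.ndarray | None = None
    radii: np.ndarray | None = None
    dt: float = 2.0  # femtoseconds between frames

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if not np.isfinite(self.coords).all():
            raise ValidationError("FrameSet coordinates must be finite")
        if self.dt <= 0:
            raise ValidationError(f"dt must be positive, got {self.dt}")
        n_atoms = self.coords.shape[1]
        for name in ("elements", "atom_names", "res_names", "chain_ids"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n_atoms,):
                raise ValidationError(f"{name} must have length {n_atoms}")
            setattr(self, name, arr)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if self.res_ids.shape != (n_atoms,):
            raise ValidationError(f"res_ids must have length {n_atoms}")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (n_atoms,):
                raise ValidationError("charges must have one value per atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def vdw_radii(self) -> np.ndarray:
        """Per-atom vdW radii: explicit (e.g. from PQR) or element lookup."""
        if self.radii is not None:
            return np.asarray(self.radii, dtype=float)
        return np.array([vdw_radius(el) for el in self.elements])

    def residue_labels(self) -> np.ndarray:
        """Per-atom residue key ``CHAIN:RESID`` (stable across frames)."""
        return np.array(
            [f"{c}:{r}" for c, r in zip(self.chain_ids, self.res_ids)]
        )

    def residue_name_map(self) -> dict[str, str]:
        """Map residue label -> three-letter residue name."""
        labels = self.residue_labels()
        return {lab: name for lab, name in zip(labels, self.res_names)}


@dataclass
class LigandTrajectory:
    """Ordered ligand reference positions P(x), one per time step.

    ``atom_coords``/``atom_elements`` optionally carry the full ligand atom
    coordinates per frame (needed for surface-distance attributes).
    ``indices`` maps vertices of a decimated trajectory back to raw steps.
    """

    positions: np.ndarray
    provenance: str = "raw"
    indices: np.ndarray | None = None
    atom_coords: np.ndarray | None = None
    atom_elements: np.ndarray | None = None
    state: "SimplificationState | None" = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError(
                f"positions must have shape (n, 3), got {self.positions.shape}"
            )
        if not np.isfinite(self.positions).all():
            raise ValidationError("trajectory positions must be finite")
        if self.indices is not None:
            self.indices = np.asarray(self.indices, dtype=int)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_steps(self) -> int:
        return len(self.positions)

    def ligand_atoms(self, x: int) -> np.ndarray:
        """Ligand atom coordinates at step ``x``; falls back to the single
        reference point when per-atom coordinates were not loaded."""
        if self.atom_coords is not None:
            return self.atom_coords[x]
        return self.positions[x][None, :]


@dataclass
class ActiveSiteSpec:
    """Residues (chain + sequence id) whose atoms define the active site;
    its per-frame position is their mass-weighted centre."""

    residues: list[tuple[str, int]]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError("active site needs at least one residue")
        self.residues = [(str(c), int(r)) for c, r in self.residues]

    def atom_mask(self, frames: FrameSet) -> np.ndarray:
        """Boolean mask of FrameSet atoms belonging to the active site."""
        mask = np.zeros(frames.n_atoms, dtype=bool)
        for chain, resid in self.residues:
            sel = (frames.chain_ids == chain) & (frames.res_ids == resid)
            if not sel.any():
                raise SelectionError(
                    f"active-site residue {chain}:{resid} not found in structure"
                )
            mask |= sel
        return mask


@dataclass
class TunnelProfile:
    """Per-time-step sphere sets describing available void space.

    ``spheres[frame]`` is an (k, 4) array of ``x, y, z, r`` rows.  Imported
    profiles may have any number of spheres per frame; the derived temporal
    tunnel has exactly one.
    """

    spheres: dict[int, np.ndarray]
    source: str = "imported"  # "imported" | "temporal"

    def __post_init__(self) -> None:
        clean: dict[int, np.ndarray] = {}
        for frame, arr in self.spheres.items():
            arr = np.asarray(arr, dtype=float).reshape(-1, 4)
            if (arr[:, 3] < 0).any():
                raise ValidationError(f"negative sphere radius at frame {frame}")
            clean[int(frame)] = arr
        self.spheres = clean
        if self.source == "temporal":
            for frame, arr in self.spheres.items():
                if len(arr) != 1:
                    raise ValidationError(
                        "temporal tunnel must have exactly one sphere per step"
                    )

    @property
    def n_frames(self) -> int:
        return len(self.spheres)

    def __contains__(self, frame: int) -> bool:
        return frame in self.spheres


# ---------------------------------------------------------------------------
# simplification state


@dataclass(frozen=True)
class SimplificationState:
    """Contiguous interval partition of ``[0, n)`` with per-interval
    non-negative simplification levels; adjacent equal-level intervals are
    merged on construction."""

    intervals: tuple[tuple[int, int, int], ...]
    n: int

    @classmethod
    def raw(cls, n: int) -> "SimplificationState":
        return cls(intervals=((0, n, 0),), n=n)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[tuple[int, int, int]], n: int
    ) -> "SimplificationState":
        merged = _merge_intervals(intervals, n)
        return cls(intervals=merged, n=n)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "intervals", _merge_intervals(self.intervals, self.n)
        )

    def with_interval(self, start: int, end: int, level: int) -> "SimplificationState":
        """New state with ``[start, end)`` set to ``level``."""
        if not (0 <= start < end <= self.n):
            raise ValidationError(
                f"interval [{start}, {end}) out of bounds for n={self.n}"
            )
        if level < 0:
            raise ValidationError("simplification level must be >= 0")
        pieces: list[tuple[int, int, int]] = []
        for s, e, lv in self.intervals:
            if e <= start or s >= end:
                pieces.append((s, e, lv))
                continue
            if s < start:
                pieces.append((s, start, lv))
            if e > end:
                pieces.append((end, e, lv))
        pieces.append((start, end, level))
        pieces.sort()
        return SimplificationState.from_intervals(pieces, self.n)

    def level_at(self, i: int) -> int:
        for s, e, lv in self.intervals:
            if s <= i < e:
                return lv
        raise IndexError(i)

    def levels_array(self) -> np.ndarray:
        out = np.zeros(self.n, dtype=int)
        for s, e, lv in self.intervals:
            out[s:e] = lv
        return out

    def max_level(self) -> int:
        return max(lv for _, _, lv in self.intervals)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "intervals": [
                {"start": s, "end": e, "level": lv} for s, e, lv in self.intervals
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimplificationState":
        return cls.from_intervals(
            [(iv["start"], iv["end"], iv["level"]) for iv in d["intervals"]],
            d["n"],
        )


def _merge_intervals(
    intervals: Iterable[tuple[int, int, int]], n: int
) -> tuple[tuple[int, int, int], ...]:
    ivs = sorted((int(s), int(e), int(lv)) for s, e, lv in intervals)
    if not ivs:
        raise ValidationError("state needs at least one interval")
    if ivs[0][0] != 0 or ivs[-1][1] != n:
        raise ValidationError(f"intervals must cover [0, {n})")
    merged: list[tuple[int, int, int]] = []
    pos = 0
    for s, e, lv in ivs:
        if s != pos:
            raise ValidationError("intervals must be contiguous and non-overlapping")
        if s >= e:
            raise ValidationError(f"empty interval [{s}, {e})")
        if lv < 0:
            raise ValidationError("negative simplification level")
        if merged and merged[-1][2] == lv:
            merged[-1] = (merged[-1][0], e, lv)
        else:
            merged.append((s, e, lv))
        pos = e
    return tuple(merged)


# ---------------------------------------------------------------------------
# derived-attribute containers


#: Classification categories in priority order (highest first).
CATEGORY_PRIORITY = ("active-site", "outside", "inside", "surface")


@dataclass
class CategoryThresholds:
    """Geometric thresholds for the four-way positional classification."""

    active_site_radius: float = 4.0  # A; d_AS below this => active-site
    outside_clearance: float = 5.0  # A; min surface distance above => outside
    burial_contacts: int = 40  # atoms within the contact shell => inside
    contact_shell: float = 8.0  # A, centre-to-centre contact radius

    def __post_init__(self) -> None:
        for name in ("active_site_radius", "outside_clearance", "contact_shell"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.burial_contacts <= 0:
            raise ValidationError("burial_contacts must be positive")


@dataclass
class StucknessParams:
    """Half-window n of the stuckness statistic (window = 2n+1 steps)."""

    n: int = 4

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("stuckness half-window n must be >= 1")


@dataclass
class AttributeTable:
    """Per-time-step derived attributes plus the positional category.

    ``data`` is a pandas DataFrame with one row per time step; ``dt`` is the
    frame spacing in femtoseconds.  Missing values are NaN/None, never 0.
    """

    data: "object"  # pandas.DataFrame; kept untyped to avoid import cycle
    dt: float = 2.0

    def __len__(self) -> int:
        return len(self.data)
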