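"""Deterministic synthetic protein+ligand trajectories with labeled phases.

The generator emulates the structure the analysis assumes, not physics: a
static pseudo-residue shell with a cleared cylindrical channel down +z, an
active site buried at the channel's inner end, and a ligand path built from
labeled phases:

* ``outside``  -- random walk well beyond the protein surface,
* ``surface``  -- walk constrained to a thin layer above the outer radius,
* ``transit``  -- persistent (direction-correlated) walk bouncing inside
  the channel,
* ``stuck``    -- Ornstein-Uhlenbeck oscillation around a fixed channel
  point (zero mean drift),
* ``active-site`` -- the same oscillation around the active-site centre.

Gaussian positional jitter is added everywhere.  Every draw comes from one
seeded ``numpy.random.Generator`` (PCG64), so outputs are bitwise
reproducible for a fixed spec.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import md_io
from .model import (
    ActiveSiteSpec,
    FrameSet,
    LigandTrajectory,
    ValidationError,
)

AMINO_ACIDS = tuple(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

PHASE_LABELS = ("outside", "surface", "transit", "stuck", "active-site")

#: Phase plans of the named presets as (label, fraction) lists.
PRESETS: dict[str, tuple[tuple[str, float], ...]] = {
    "binding": (
        ("outside", 0.25),
        ("surface", 0.15),
        ("transit", 0.20),
        ("stuck", 0.25),
        ("active-site", 0.15),
    ),
    "rolling": (
        ("outside", 0.30),
        ("surface", 0.45),
        ("outside", 0.25),
    ),
    "impasse": (
        ("outside", 0.20),
        ("surface", 0.15),
        ("transit", 0.25),
        ("stuck", 0.40),
    ),
}


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic scenario.

    The default phase plan (500/300/400/500/300 over 2,000 steps) walks the
    ligand from solvent, across the surface, down the channel into a stuck
    oscillation and finally into the active site.
    """

    seed: int = 42
    n_steps: int = 2000
    phases: tuple[tuple[str, int], ...] = (
        ("outside", 500),
        ("surface", 300),
        ("transit", 400),
        ("stuck", 500),
        ("active-site", 300),
    )
    n_residues: int = 200  # 3-atom pseudo-residues
    inner_radius: float = 5.0  # A, cavity radius
    outer_radius: float = 13.0  # A, protein surface
    channel_radius: float = 3.0  # A, cleared cylinder down +z
    jitter: float = 0.15  # A, global positional noise
    step_length: float = 0.7  # A, transit step
    stuck_amplitude: float = 0.8  # A, stationary std of the OU oscillation
    dt: float = 2.0  # fs

    def __post_init__(self) -> None:
        if sum(d for _, d in self.phases) != self.n_steps:
            raise ValidationError("phase durations must sum to n_steps")
        for label, dur in self.phases:
            if label not in PHASE_LABELS:
                raise ValidationError(f"unknown phase label {label!r}")
            if dur < 1:
                raise ValidationError("phase durations must be positive")
        if self.jitter < 0:
            raise ValidationError("jitter must be >= 0")
        if not (0 < self.inner_radius < self.outer_radius):
            raise ValidationError("need 0 < inner_radius < outer_radius")
        if self.channel_radius >= self.inner_radius:
            raise ValidationError("channel radius must be below the inner radius")
        if self.channel_radius <= 1.7:  # ligand vdW radius
            raise ValidationError("channel radius must exceed the ligand radius")
        if self.n_residues < 20:
            raise ValidationError("need at least 20 residues for a usable shell")

    @classmethod
    def preset(cls, name: str, seed: int = 42, n_steps: int = 2000, **kwargs) -> "ScenarioSpec":
        if name not in PRESETS:
            raise ValidationError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
        fracs = PRESETS[name]
        durations = [int(round(f * n_steps)) for _, f in fracs]
        durations[-1] += n_steps - sum(durations)
        phases = tuple((label, d) for (label, _), d in zip(fracs, durations))
        return cls(seed=seed, n_steps=n_steps, phases=phases, **kwargs)


@dataclass
class GroundTruth:
    """What the generator actually did, for oracle tests."""

    labels: np.ndarray  # per-step phase label
    stuck_intervals: list[tuple[int, int]]  # half-open step ranges
    active_site_center: np.ndarray
    residue_centers: dict[str, list[float]]  # residue label -> centre
    spec_seed: int

    def to_dict(self) -> dict:
        return {
            "labels": [str(l) for l in self.labels],
            "stuck_intervals": [list(iv) for iv in self.stuck_intervals],
            "active_site_center": [float(v) for v in self.active_site_center],
            "residue_centers": self.residue_centers,
            "seed": self.spec_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            labels=np.array(d["labels"], dtype=object),
            stuck_intervals=[tuple(iv) for iv in d["stuck_intervals"]],
            active_site_center=np.array(d["active_site_center"], dtype=float),
            residue_centers=d["residue_centers"],
            spec_seed=d["seed"],
        )


# ---------------------------------------------------------------------------
# protein shell


def _build_shell(spec: ScenarioSpec, rng: np.random.Generator):
    """Static 3-atom pseudo-residue shell with a cleared channel and three
    active-site residues ringed around the channel's buried end."""
    n_site = 3
    n_bulk = spec.n_residues - n_site
    clear = spec.channel_radius + 1.0
    centers = []
    while len(centers) < n_bulk:
        # uniform in the shell by rejection from the bounding cube
        c = rng.uniform(-spec.outer_radius, spec.outer_radius, size=3)
        r = np.linalg.norm(c)
        if not (spec.inner_radius <= r <= spec.outer_radius):
            continue
        if c[2] > 0 and np.hypot(c[0], c[1]) < clear:
            continue  # inside the channel
        centers.append(c)

    site_z = spec.inner_radius - 1.5
    ring_r = spec.channel_radius + 0.8
    for angle in (90.0, 210.0, 330.0):
        a = np.deg2rad(angle)
        centers.append(
            np.array([ring_r * np.cos(a), ring_r * np.sin(a), site_z])
        )
    centers = np.array(centers)

    atoms = centers[:, None, :] + rng.normal(scale=0.5, size=(spec.n_residues, 3, 3))
    coords = atoms.reshape(-1, 3)

    res_names = np.repeat(
        [AMINO_ACIDS[i % len(AMINO_ACIDS)] for i in range(spec.n_residues)], 3
    )
    res_ids = np.repeat(np.arange(1, spec.n_residues + 1), 3)
    chain_ids = np.full(coords.shape[0], "A")
    elements = np.tile(np.array(["C", "N", "O"]), spec.n_residues)
    atom_names = np.tile(np.array(["C1", "N1", "O1"]), spec.n_residues)

    # alternating +-0.3 charges on channel-lining residues, 0 elsewhere
    charges = np.zeros(coords.shape[0])
    lining = [
        i
        for i, c in enumerate(centers)
        if c[2] > 0 and np.hypot(c[0], c[1]) < spec.channel_radius + 2.5
    ]
    for j, i in enumerate(sorted(lining)):
        charges[3 * i : 3 * i + 3] = 0.3 if j % 2 == 0 else -0.3

    site_residues = [("A", int(spec.n_residues - 2 + k)) for k in range(3)]
    site_center = centers[-3:].mean(axis=0)
    return (
        coords, elements, atom_names, res_names, res_ids, chain_ids, charges,
        centers, site_residues, site_center,
    )


# ---------------------------------------------------------------------------
# ligand path phases


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _walk_banded(rng, n, start, step, rad_lo, rad_hi, target=None, tail_frac=0.25):
    """Random walk radially confined to [rad_lo, rad_hi], optionally biased
    toward ``target`` over the final ``tail_frac`` of its steps."""
    pos = np.asarray(start, dtype=float).copy()
    out = np.empty((n, 3))
    for i in range(n):
        pos = pos + _unit(rng.normal(size=3)) * step
        if target is not None:
            rem = n - i
            if rem <= max(2, int(tail_frac * n)):
                pos = pos + (np.asarray(target) - pos) / rem
        r = np.linalg.norm(pos)
        if r < rad_lo:
            pos *= rad_lo / r
        elif r > rad_hi:
            pos *= rad_hi / r
        out[i] = pos
    return out


def _transit_walk(rng, n, start, step, chan_clear, z_lo, z_hi, target):
    """Persistent walk bouncing inside the channel (radial < chan_clear,
    z in [z_lo, z_hi]), drifting to ``target`` over the final 15%."""
    pos = np.asarray(start, dtype=float).copy()
    v = np.array([0.0, 0.0, -1.0])
    out = np.empty((n, 3))
    tail = max(2, int(0.15 * n))
    for i in range(n):
        if pos[2] > z_hi:
            # swift insertion: drop straight down the channel mouth
            v = _unit(np.array([0.0, 0.0, -1.0]) + rng.normal(scale=0.1, size=3))
        else:
            v = _unit(0.85 * v + rng.normal(scale=0.55, size=3))
        cand = pos + v * step
        rxy = np.hypot(cand[0], cand[1])
        if rxy > chan_clear:
            cand[:2] *= chan_clear / rxy
            v[:2] = -v[:2]
        if cand[2] > z_hi and v[2] > 0:
            v[2] = -v[2]
        if cand[2] < z_lo:
            cand[2] = z_lo
            v[2] = abs(v[2])
        rem = n - i
        if rem <= tail:
            cand = cand + (np.asarray(target) - cand) / rem
        pos = cand
        out[i] = pos
    return out


def _ou_oscillation(rng, n, start, center, amplitude, mean_reversion=0.7, settle=0):
    """Ornstein-Uhlenbeck oscillation with stationary std ``amplitude`` per
    coordinate; the centre glides from ``start`` to ``center`` over the
    first ``settle`` steps so phases stay spatially continuous."""
    a = mean_reversion
    sigma = amplitude * np.sqrt(1.0 - a * a)
    pos = np.asarray(start, dtype=float).copy()
    center = np.asarray(center, dtype=float)
    out = np.empty((n, 3))
    for i in range(n):
        if settle and i < settle:
            c = pos + (center - pos) / max(1, settle - i)
        else:
            c = center
        pos = c + a * (pos - c) + rng.normal(scale=sigma, size=3)
        out[i] = pos
    return out


def _ligand_path(spec: ScenarioSpec, rng, site_center: np.ndarray):
    """Concatenate phase walks; returns (positions, labels, stuck_intervals)."""
    out_lo = spec.outer_radius + 10.0
    out_hi = spec.outer_radius + 18.0
    surf_lo = spec.outer_radius + 3.0
    surf_hi = spec.outer_radius + 4.0
    entrance = np.array([0.0, 0.0, surf_hi + 0.5])
    chan_clear = spec.channel_radius - 1.0
    z_hi = spec.outer_radius - 2.0
    z_lo = site_center[2] + 5.0
    stuck_point = np.array([0.0, 0.0, 0.5 * (z_lo + z_hi)])

    pos = np.array([0.0, 0.0, out_lo + 3.0])
    chunks: list[np.ndarray] = []
    labels: list[str] = []
    stuck_intervals: list[tuple[int, int]] = []
    step_cursor = 0
    for label, dur in spec.phases:
        if label == "outside":
            walk = _walk_banded(
                rng, dur, pos, spec.step_length, out_lo, out_hi,
                target=np.array([0.0, 0.0, out_lo + 1.0]),
            )
        elif label == "surface":
            start = pos if np.linalg.norm(pos) <= surf_hi + 2 else pos * (surf_hi / np.linalg.norm(pos))
            walk = _walk_banded(
                rng, dur, start, spec.step_length, surf_lo, surf_hi,
                target=entrance,
            )
        elif label == "transit":
            walk = _transit_walk(
                rng, dur, pos, spec.step_length, chan_clear, z_lo, z_hi,
                target=stuck_point,
            )
        elif label == "stuck":
            walk = _ou_oscillation(
                rng, dur, pos, stuck_point, spec.stuck_amplitude, settle=10
            )
            stuck_intervals.append((step_cursor, step_cursor + dur))
        elif label == "active-site":
            walk = _ou_oscillation(
                rng, dur, pos, site_center, spec.stuck_amplitude, settle=25
            )
        else:  # pragma: no cover - validated in ScenarioSpec
            raise ValidationError(label)
        chunks.append(walk)
        labels.extend([label] * dur)
        pos = walk[-1]
        step_cursor += dur
    positions = np.concatenate(chunks, axis=0)
    positions = positions + rng.normal(scale=spec.jitter, size=positions.shape)
    return positions, np.array(labels, dtype=object), stuck_intervals


# ---------------------------------------------------------------------------
# public entry point


def generate(
    spec: ScenarioSpec | None = None, outdir: str | Path | None = None
) -> tuple[FrameSet, LigandTrajectory, ActiveSiteSpec, GroundTruth]:
    """Generate a labeled scenario; optionally write the on-disk bundle
    (multi-model PDB, PQR, active-site YAML, ground-truth JSON)."""
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng(spec.seed)
    (
        coords, elements, atom_names, res_names, res_ids, chain_ids, charges,
        centers, site_residues, _ring_center,
    ) = _build_shell(spec, rng)

    n = spec.n_steps
    frames = FrameSet(
        coords=np.broadcast_to(coords, (n, *coords.shape)).copy(),
        elements=elements,
        atom_names=atom_names,
        res_names=res_names,
        res_ids=res_ids,
        chain_ids=chain_ids,
        charges=charges,
        dt=spec.dt,
    )
    site = ActiveSiteSpec(residues=site_residues)

    # the attribute pipeline uses the mass-weighted centre; the generator
    # steers the ligand toward the same point
    from .attributes import active_site_position

    site_center = active_site_position(frames, site, 0)
    positions, labels, stuck_intervals = _ligand_path(spec, rng, site_center)

    traj = LigandTrajectory(
        positions=positions,
        provenance="raw",
        atom_coords=positions[:, None, :],
        atom_elements=np.array(["C"]),
    )
    labels_arr = np.array(labels, dtype=object)
    res_labels = [f"A:{i}" for i in range(1, spec.n_residues + 1)]
    truth = GroundTruth(
        labels=labels_arr,
        stuck_intervals=stuck_intervals,
        active_site_center=site_center,
        residue_centers={
            lab: [float(v) for v in c] for lab, c in zip(res_labels, centers)
        },
        spec_seed=spec.seed,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        md_io.write_frameset_pdb(
            frames, outdir / "trajectory.pdb", ligand=traj, ligand_res_name="LIG"
        )
        md_io.write_pqr(frames, outdir / "system.pqr", frame=0, ligand=traj)
        md_io.write_active_site(site, outdir / "active_site.yaml")
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth.to_dict(), indent=1)
        )
    return frames, traj, site, truth


# ---------------------------------------------------------------------------
# small analytic fixtures for the simplification tests


def jitter_cloud(
    n_steps: int = 200, sigma: float = 0.5, seed: int = 42,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> LigandTrajectory:
    """Pure positional noise around a fixed point: maximally 'stuck'."""
    rng = np.random.default_rng(seed)
    pts = np.asarray(center, dtype=float) + rng.normal(scale=sigma, size=(n_steps, 3))
    return LigandTrajectory(positions=pts)


def helix_with_noisy_knot(
    n_steps: int = 300, seed: int = 7, radius: float = 8.0,
    rise_per_step: float = 0.3, arc_step: float = 0.7, knot_sigma: float = 0.5,
) -> tuple[LigandTrajectory, tuple[int, int]]:
    """A gentle helix whose middle third carries strong positional noise.

    Returns the trajectory and the half-open index range of the noisy
    third; the clean thirds are locally near-straight (low turning
    complexity), the knot is not.
    """
    rng = np.random.default_rng(seed)
    theta = np.arange(n_steps) * (arc_step / radius)
    pts = np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise_per_step * np.arange(n_steps)],
        axis=1,
    )
    a, b = n_steps // 3, 2 * n_steps // 3
    pts[a:b] += rng.normal(scale=knot_sigma, size=(b - a, 3))
    return LigandTrajectory(positions=pts), (a, b)
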