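"""Per-time-step attributes of a ligand trajectory through a protein.

Attributes: stuckness (ratio of maximal pairwise displacement to path
length over a 2n+1 step window; emitted both as the raw "straightness"
ratio and as its display complement 1-s), distance and binary direction to
the active site, free-space radius (from an imported tunnel or the derived
temporal tunnel), lining residues, hydrophobicity and charge profiles,
speed, residue turnover, and the four-way positional category
(outside / surface / inside / active-site).

Residue-ligand distances are vdW-surface distances (centre distance minus
both radii, clamped at 0); a centre-to-centre mode is available via
``surface=False`` where it matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .model import (
    ActiveSiteSpec,
    AttributeTable,
    CATEGORY_PRIORITY,
    CategoryThresholds,
    FrameSet,
    LigandTrajectory,
    SelectionError,
    StucknessParams,
    TunnelProfile,
    ValidationError,
)
from .scales import atomic_mass, hydrophobicity_scale, vdw_radius

logger = logging.getLogger(__name__)

_FROZEN_EPS = 1.0e-9


# ---------------------------------------------------------------------------
# stuckness


def straightness(
    traj: LigandTrajectory | np.ndarray,
    x: int,
    params: StucknessParams | None = None,
) -> float:
    """Raw stuckness statistic s(x) in (0, 1].

    Maximal pairwise distance among positions x-n .. x+n divided by the
    summed consecutive step lengths over the same window; the window is
    clipped at the trajectory ends.  A frozen window (path length below
    1e-9 A) returns NaN -- the display stuckness treats it as maximally
    stuck (see :func:`stuckness_series`).
    """
    params = params or StucknessParams()
    pts = traj.positions if isinstance(traj, LigandTrajectory) else np.asarray(traj, float)
    n_steps = len(pts)
    if n_steps < 2:
        raise ValidationError("stuckness needs at least 2 positions")
    lo = max(0, x - params.n)
    hi = min(n_steps - 1, x + params.n)
    window = pts[lo : hi + 1]
    path = float(np.linalg.norm(np.diff(window, axis=0), axis=1).sum())
    if path < _FROZEN_EPS:
        return float("nan")
    max_pair = float(pdist(window).max()) if len(window) > 1 else 0.0
    return max_pair / path


def stuckness_series(
    traj: LigandTrajectory | np.ndarray, params: StucknessParams | None = None
) -> pd.DataFrame:
    """Per-step ``straightness`` (raw s), ``stuckness`` (1-s, frozen
    windows = 1.0) and ``frozen`` flag."""
    params = params or StucknessParams()
    pts = traj.positions if isinstance(traj, LigandTrajectory) else np.asarray(traj, float)
    s = np.array([straightness(pts, x, params) for x in range(len(pts))])
    frozen = np.isnan(s)
    display = np.where(frozen, 1.0, 1.0 - s)
    return pd.DataFrame(
        {"straightness": s, "stuckness": display, "frozen": frozen}
    )


# ---------------------------------------------------------------------------
# active site: position, distance, direction


def active_site_position(frames: FrameSet, spec: ActiveSiteSpec, x: int) -> np.ndarray:
    """Mass-weighted centre of the active-site residues' atoms at frame x."""
    mask = spec.atom_mask(frames)
    masses = np.array([atomic_mass(el) for el in frames.elements[mask]])
    coords = frames.coords[x, mask, :]
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def active_site_series(frames: FrameSet, spec: ActiveSiteSpec) -> np.ndarray:
    """A(x) for every frame, shape (n_frames, 3)."""
    mask = spec.atom_mask(frames)
    masses = np.array([atomic_mass(el) for el in frames.elements[mask]])
    coords = frames.coords[:, mask, :]
    return (coords * masses[None, :, None]).sum(axis=1) / masses.sum()


def distance_series(
    traj: LigandTrajectory, frames: FrameSet, spec: ActiveSiteSpec
) -> np.ndarray:
    """Euclidean distance d_AS(x) from the ligand reference point to the
    active-site centre, per step."""
    site = active_site_series(frames, spec)
    if len(site) != len(traj):
        raise ValidationError("trajectory and frame counts differ")
    return np.linalg.norm(traj.positions - site, axis=1)


def direction_series(distances: np.ndarray) -> np.ndarray:
    """Binary movement direction relative to the active site.

    Step x is "toward" iff d(x+1) - d(x) < 0 and "away" iff > 0; exact
    ties inherit the previous label (the first step defaults to "away");
    the last step repeats its predecessor.
    """
    d = np.asarray(distances, dtype=float)
    if len(d) < 2:
        raise ValidationError("direction needs at least 2 steps")
    labels = np.empty(len(d), dtype=object)
    prev = "away"
    for x in range(len(d) - 1):
        delta = d[x + 1] - d[x]
        if delta < 0:
            prev = "toward"
        elif delta > 0:
            prev = "away"
        labels[x] = prev
    labels[-1] = labels[-2]
    return labels


# ---------------------------------------------------------------------------
# free space


def temporal_tunnel(frames: FrameSet, traj: LigandTrajectory) -> TunnelProfile:
    """Per-step free-space sphere when no computed tunnel is available.

    The centre is the unweighted mean of the ten protein atoms nearest to
    the ligand reference point; the radius is the minimum distance from
    that centre to any protein atom.
    """
    if frames.n_atoms < 10:
        raise ValidationError("temporal tunnel needs at least 10 protein atoms")
    if frames.n_frames != len(traj):
        raise ValidationError("trajectory and frame counts differ")
    spheres: dict[int, np.ndarray] = {}
    for x in range(frames.n_frames):
        coords = frames.coords[x]
        d_lig = np.linalg.norm(coords - traj.positions[x], axis=1)
        nearest = np.argsort(d_lig, kind="stable")[:10]
        center = coords[nearest].mean(axis=0)
        radius = float(np.linalg.norm(coords - center, axis=1).min())
        spheres[x] = np.array([[center[0], center[1], center[2], radius]])
    return TunnelProfile(spheres=spheres, source="temporal")


def free_space_from_tunnel(
    tunnel: TunnelProfile, traj: LigandTrajectory, x: int
) -> tuple[float, bool]:
    """Free-space radius at step x from a sphere profile.

    Among spheres of frame x containing P(x), returns the radius of the one
    whose centre is nearest to P(x).  If no sphere contains the ligand the
    nearest sphere's radius is returned with ``outside_tunnel=True``.
    """
    if x not in tunnel:
        raise KeyError(x)
    arr = tunnel.spheres[x]
    if len(arr) == 0:
        raise KeyError(x)
    p = traj.positions[x]
    center_dist = np.linalg.norm(arr[:, :3] - p, axis=1)
    containing = center_dist <= arr[:, 3]
    if containing.any():
        cand = np.flatnonzero(containing)
        best = cand[np.argmin(center_dist[cand])]
        return float(arr[best, 3]), False
    nearest = int(np.argmin(center_dist))
    return float(arr[nearest, 3]), True


def free_space_series(
    traj: LigandTrajectory,
    frames: FrameSet,
    tunnel: TunnelProfile | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-step (radius, source, outside_flag).

    Uses the imported tunnel where available; steps absent from it (or an
    entirely missing tunnel) fall back to the temporal tunnel.
    """
    n = len(traj)
    radius = np.empty(n)
    source = np.empty(n, dtype=object)
    outside = np.zeros(n, dtype=bool)
    fallback: TunnelProfile | None = None
    missing = [
        x
        for x in range(n)
        if tunnel is None or x not in tunnel or len(tunnel.spheres[x]) == 0
    ]
    if missing:
        fallback = temporal_tunnel(frames, traj)
        if tunnel is not None:
            logger.info(
                "%d/%d steps absent from imported tunnel; using temporal tunnel",
                len(missing), n,
            )
    for x in range(n):
        if tunnel is not None and x in tunnel and len(tunnel.spheres[x]) > 0:
            radius[x], outside[x] = free_space_from_tunnel(tunnel, traj, x)
            source[x] = "tunnel"
        else:
            radius[x], outside[x] = free_space_from_tunnel(fallback, traj, x)
            source[x] = "temporal"
    return radius, source, outside


# ---------------------------------------------------------------------------
# lining residues and profiles


def _surface_distance_matrix(
    frames: FrameSet, x: int, ligand_atoms: np.ndarray,
    ligand_elements: np.ndarray | None, surface: bool = True,
) -> np.ndarray:
    """Per-protein-atom minimal distance to any ligand atom at frame x."""
    coords = frames.coords[x]
    lig = np.atleast_2d(np.asarray(ligand_atoms, dtype=float))
    diff = coords[:, None, :] - lig[None, :, :]
    center = np.linalg.norm(diff, axis=2)  # (n_atoms, n_lig)
    if not surface:
        return center.min(axis=1)
    prot_r = frames.vdw_radii[:, None]
    if ligand_elements is not None:
        lig_r = np.array([vdw_radius(el) for el in ligand_elements])[None, :]
    else:
        lig_r = np.full((1, lig.shape[0]), 1.70)
    return np.clip(center - prot_r - lig_r, 0.0, None).min(axis=1)


def lining_residues(
    frames: FrameSet,
    ligand_atoms: np.ndarray,
    x: int,
    k: int = 3,
    cutoff: float | None = None,
    ligand_elements: np.ndarray | None = None,
    surface: bool = True,
) -> list[tuple[str, float]]:
    """Up to k residues closest to the ligand at frame x, sorted by their
    minimal (surface) distance over all atom pairs.

    ``cutoff`` switches to lining-set semantics: all residues within the
    cutoff are returned (still sorted), regardless of k.
    """
    dists = _surface_distance_matrix(frames, x, ligand_atoms, ligand_elements, surface)
    labels = frames.residue_labels()
    per_res: dict[str, float] = {}
    for lab, d in zip(labels, dists):
        if lab not in per_res or d < per_res[lab]:
            per_res[lab] = float(d)
    ordered = sorted(per_res.items(), key=lambda kv: (kv[1], kv[0]))
    if cutoff is not None:
        return [(lab, d) for lab, d in ordered if d <= cutoff]
    return ordered[:k]


def hydrophobicity_profile(
    frames: FrameSet,
    ligand_atoms: np.ndarray,
    x: int,
    cutoff: float = 2.0,
    scale: dict[str, float] | str = "kyte-doolittle",
    ligand_elements: np.ndarray | None = None,
) -> float:
    """Mean hydrophobicity of residues lining the ligand (surface distance
    <= cutoff); NaN when the lining set is empty."""
    if isinstance(scale, str):
        scale = hydrophobicity_scale(scale)
    lining = lining_residues(
        frames, ligand_atoms, x, cutoff=cutoff, ligand_elements=ligand_elements
    )
    name_map = frames.residue_name_map()
    values = []
    for lab, _ in sorted(lining):
        name = name_map[lab].upper()
        if name in scale:
            values.append(scale[name])
        else:
            logger.warning("residue %s (%s) missing from hydrophobicity scale", lab, name)
    return float(np.mean(values)) if values else float("nan")


def charge_profile(
    frames: FrameSet,
    ligand_atoms: np.ndarray,
    x: int,
    cutoff: float = 2.0,
    ligand_elements: np.ndarray | None = None,
) -> float:
    """Mean partial charge of protein atoms within ``cutoff`` (surface
    distance) of any ligand atom; NaN when no atom is in range."""
    if frames.charges is None:
        raise ValidationError("FrameSet carries no partial charges")
    dists = _surface_distance_matrix(frames, x, ligand_atoms, ligand_elements)
    in_range = dists <= cutoff
    if not in_range.any():
        return float("nan")
    return float(frames.charges[in_range].mean())


def residue_turnover(lining_a, lining_b) -> int:
    """Symmetric-difference size of two lining residue-id sets.

    Accepts bare residue labels or ``(label, distance)`` pairs as produced
    by :func:`lining_residues`.
    """

    def as_set(lining) -> set:
        return {item[0] if isinstance(item, tuple) else item for item in lining}

    return len(as_set(lining_a) ^ as_set(lining_b))


# ---------------------------------------------------------------------------
# speed


def speed_series(traj: LigandTrajectory, dt: float = 2.0) -> np.ndarray:
    """|P(x+1) - P(x)| / dt per step (A/fs); the last step repeats its
    predecessor so the series has one value per time step."""
    if len(traj) < 2:
        raise ValidationError("speed needs at least 2 steps")
    if dt <= 0:
        raise ValidationError("dt must be positive")
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1) / dt
    return np.concatenate([steps, steps[-1:]])


# ---------------------------------------------------------------------------
# positional classification


def classify_position(
    frames: FrameSet,
    traj: LigandTrajectory,
    spec: ActiveSiteSpec,
    thresholds: CategoryThresholds | None = None,
    x: int | None = None,
    d_as: np.ndarray | None = None,
) -> np.ndarray | str:
    """Four-way positional category per step.

    Priority: active-site (d_AS <= active_site_radius), else outside (min
    surface distance > outside_clearance), else inside (>= burial_contacts
    protein atoms within contact_shell of P(x)), else surface.  Pass ``x``
    for a single step, otherwise the whole series is returned.
    """
    thresholds = thresholds or CategoryThresholds()
    if d_as is None:
        d_as = distance_series(traj, frames, spec)
    steps = range(len(traj)) if x is None else [x]
    out = []
    for i in steps:
        if d_as[i] <= thresholds.active_site_radius:
            out.append("active-site")
            continue
        lig = traj.ligand_atoms(i)
        surf = _surface_distance_matrix(frames, i, lig, traj.atom_elements)
        if surf.min() > thresholds.outside_clearance:
            out.append("outside")
            continue
        center_d = np.linalg.norm(frames.coords[i] - traj.positions[i], axis=1)
        if int((center_d <= thresholds.contact_shell).sum()) >= thresholds.burial_contacts:
            out.append("inside")
        else:
            out.append("surface")
    if x is not None:
        return out[0]
    return np.array(out, dtype=object)


# ---------------------------------------------------------------------------
# smoothing / aggregation helpers


def sliding_window(series, w: int) -> np.ndarray:
    """Centred moving mean with window ``w`` (odd), clipped at the ends;
    missing values are excluded (an all-missing window stays missing)."""
    if w < 1 or w % 2 == 0:
        raise ValidationError("window must be an odd count >= 1")
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(window=w, center=True, min_periods=1).mean().to_numpy()


def aggregate_bars(
    series, n_bins: int, categories=None
) -> pd.DataFrame:
    """Uniform bar aggregation: near-equal half-open index bins (remainder
    spread over the leading bins), per-bin mean of non-missing values and,
    when given, the modal category (ties broken by classification
    priority)."""
    values = np.asarray(series, dtype=float)
    n = len(values)
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    n_eff = min(n_bins, n)
    splits = np.array_split(np.arange(n), n_eff)
    rows = []
    rank = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}
    for idx in splits:
        chunk = values[idx]
        finite = chunk[np.isfinite(chunk)]
        mean = float(finite.mean()) if len(finite) else float("nan")
        row = {"start": int(idx[0]), "end": int(idx[-1]) + 1, "mean": mean}
        if categories is not None:
            cats = [categories[i] for i in idx]
            counts: dict[str, int] = {}
            for c in cats:
                counts[c] = counts.get(c, 0) + 1
            best = sorted(
                counts.items(), key=lambda kv: (-kv[1], rank.get(kv[0], 99))
            )[0][0]
            row["category"] = best
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full table


def compute_attribute_table(
    frames: FrameSet,
    traj: LigandTrajectory,
    spec: ActiveSiteSpec,
    tunnel: TunnelProfile | None = None,
    stuck_params: StucknessParams | None = None,
    thresholds: CategoryThresholds | None = None,
    lining_cutoff: float = 2.0,
    k_lining: int = 3,
    scale: str | dict = "kyte-doolittle",
) -> AttributeTable:
    """Derive every per-step attribute plus the positional category.

    Charge-dependent columns are emitted as missing (NaN) when the frames
    carry no partial charges.
    """
    n = len(traj)
    if frames.n_frames != n:
        raise ValidationError("trajectory and frame counts differ")
    stuck_params = stuck_params or StucknessParams()
    thresholds = thresholds or CategoryThresholds()
    if isinstance(scale, str):
        scale = hydrophobicity_scale(scale)

    stuck = stuckness_series(traj, stuck_params)
    d_as = distance_series(traj, frames, spec)
    direction = direction_series(d_as)
    speed = speed_series(traj, frames.dt)
    radius, fs_source, fs_outside = free_space_series(traj, frames, tunnel)
    categories = classify_position(frames, traj, spec, thresholds, d_as=d_as)

    name_map = frames.residue_name_map()
    has_charges = frames.charges is not None
    if not has_charges:
        logger.info("no partial charges loaded; charge profile reported missing")

    lining_cols: dict[str, list] = {}
    for j in range(k_lining):
        lining_cols[f"lining{j + 1}"] = []
        lining_cols[f"lining{j + 1}_dist"] = []
    hydro = np.full(n, np.nan)
    charge = np.full(n, np.nan)
    turnover = np.zeros(n, dtype=int)
    prev_set: set[str] | None = None
    for x in range(n):
        lig = traj.ligand_atoms(x)
        lin = lining_residues(
            frames, lig, x, k=k_lining, ligand_elements=traj.atom_elements
        )
        for j in range(k_lining):
            if j < len(lin):
                lining_cols[f"lining{j + 1}"].append(lin[j][0])
                lining_cols[f"lining{j + 1}_dist"].append(lin[j][1])
            else:
                lining_cols[f"lining{j + 1}"].append(None)
                lining_cols[f"lining{j + 1}_dist"].append(float("nan"))
        cur_set = {lab for lab, _ in lin}
        turnover[x] = len(prev_set ^ cur_set) if prev_set is not None else 0
        prev_set = cur_set

        dists = _surface_distance_matrix(frames, x, lig, traj.atom_elements)
        in_range = dists <= lining_cutoff
        labels = frames.residue_labels()[in_range]
        hv = [
            scale[name_map[lab].upper()]
            for lab in sorted(set(labels))  # sorted: order-stable summation
            if name_map[lab].upper() in scale
        ]
        hydro[x] = float(np.mean(hv)) if hv else float("nan")
        if has_charges and in_range.any():
            charge[x] = float(frames.charges[in_range].mean())

    data = pd.DataFrame(
        {
            "step": np.arange(n),
            "straightness": stuck["straightness"],
            "stuckness": stuck["stuckness"],
            "frozen": stuck["frozen"],
            "dist_active_site": d_as,
            "direction": direction,
            "free_space": radius,
            "free_space_source": fs_source,
            "outside_tunnel": fs_outside,
            **lining_cols,
            "hydrophobicity": hydro,
            "charge": charge,
            "speed": speed,
            "turnover": turnover,
            "category": categories,
        }
    )
    return AttributeTable(data=data, dt=frames.dt)
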