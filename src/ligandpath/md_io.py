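"""Readers and writers for trajectories, charges, tunnels and attribute tables.

The baseline trajectory dialect is multi-model PDB (read and written through
biotite); binary trajectory formats (DCD/XTC/TRR...) are read through
MDAnalysis and require a topology file.  Partial charges come from PQR files
(occupancy-column convention, read through MDAnalysis).  Tunnel profiles are
CAVER-style CSV with a ``frame,x,y,z,r`` header.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    ActiveSiteSpec,
    AttributeTable,
    ConsistencyError,
    FormatError,
    FrameSet,
    LigandTrajectory,
    SelectionError,
    TunnelProfile,
    ValidationError,
)
from .scales import atomic_mass

logger = logging.getLogger(__name__)

_PDB_SUFFIXES = {".pdb", ".ent", ".pdb1"}


# ---------------------------------------------------------------------------
# trajectory loading


def load_frameset(
    trajectory_path: str | Path,
    topology_path: str | Path | None = None,
    ligand_selector: str = "LIG",
    charges_path: str | Path | None = None,
    dt: float = 2.0,
    ligand_reference: str = "geometry",
) -> tuple[FrameSet, LigandTrajectory]:
    """Load a protein+ligand trajectory into a protein :class:`FrameSet` and
    the ligand's reference-point :class:`LigandTrajectory`.

    Parameters
    ----------
    trajectory_path:
        Multi-model PDB, or a binary trajectory when ``topology_path`` is
        given.
    ligand_selector:
        Residue name (``"LIG"``) or ``"CHAIN:RESID"``; must match exactly
        one residue.
    charges_path:
        Optional PQR file carrying per-atom partial charges (and radii).
    ligand_reference:
        ``"geometry"`` (unweighted centroid, default) or ``"mass"``
        (mass-weighted centre) for the ligand reference point.
    """
    trajectory_path = Path(trajectory_path)
    if not trajectory_path.exists():
        raise FileNotFoundError(trajectory_path)
    if ligand_reference not in ("geometry", "mass"):
        raise ValidationError(f"unknown ligand_reference {ligand_reference!r}")

    if trajectory_path.suffix.lower() in _PDB_SUFFIXES:
        coords, elements, atom_names, res_names, res_ids, chain_ids = _read_pdb_stack(
            trajectory_path
        )
    else:
        if topology_path is None:
            raise ValidationError(
                f"binary trajectory {trajectory_path.name} requires a topology file"
            )
        coords, elements, atom_names, res_names, res_ids, chain_ids = _read_binary(
            trajectory_path, Path(topology_path)
        )

    ligand_mask = _ligand_mask(
        ligand_selector, res_names, res_ids, chain_ids
    )
    protein_mask = ~ligand_mask

    lig_coords = coords[:, ligand_mask, :]
    lig_elements = elements[ligand_mask]
    if ligand_reference == "mass":
        w = np.array([atomic_mass(el) for el in lig_elements])
        ref = (lig_coords * w[None, :, None]).sum(axis=1) / w.sum()
    else:
        ref = lig_coords.mean(axis=1)

    charges = None
    radii = None
    if charges_path is not None:
        charges, radii = _read_pqr_charges(
            Path(charges_path), protein_mask, ligand_mask, res_names
        )

    frames = FrameSet(
        coords=coords[:, protein_mask, :],
        elements=elements[protein_mask],
        atom_names=atom_names[protein_mask],
        res_names=res_names[protein_mask],
        res_ids=res_ids[protein_mask],
        chain_ids=chain_ids[protein_mask],
        charges=charges,
        radii=radii,
        dt=dt,
    )
    traj = LigandTrajectory(
        positions=ref,
        provenance="raw",
        atom_coords=lig_coords,
        atom_elements=lig_elements,
    )
    return frames, traj


def _read_pdb_stack(path: Path):
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # biotite raises various parse errors
        raise FormatError(f"cannot parse {path} as multi-model PDB: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    coords = np.asarray(stack.coord, dtype=float)
    return (
        coords,
        np.asarray(stack.element).astype(str),
        np.asarray(stack.atom_name).astype(str),
        np.asarray(stack.res_name).astype(str),
        np.asarray(stack.res_id).astype(int),
        np.asarray(stack.chain_id).astype(str),
    )


def _read_binary(traj_path: Path, top_path: Path):
    import MDAnalysis as mda

    try:
        u = mda.Universe(str(top_path), str(traj_path))
    except Exception as exc:
        raise FormatError(
            f"cannot load {traj_path} with topology {top_path}: {exc}"
        ) from exc
    n_atoms = len(u.atoms)
    coords = np.empty((len(u.trajectory), n_atoms, 3), dtype=float)
    for i, _ in enumerate(u.trajectory):
        frame_coords = u.atoms.positions
        if frame_coords.shape != (n_atoms, 3):
            raise ConsistencyError(
                f"frame {i} has {frame_coords.shape[0]} atoms, expected {n_atoms}"
            )
        coords[i] = frame_coords  # MDAnalysis positions are already Angstrom
    elements = (
        np.asarray(u.atoms.elements).astype(str)
        if hasattr(u.atoms, "elements")
        else np.array([_guess_element(n) for n in u.atoms.names])
    )
    chains = (
        np.asarray(u.atoms.chainIDs).astype(str)
        if hasattr(u.atoms, "chainIDs")
        else np.array(["A"] * n_atoms)
    )
    return (
        coords,
        elements,
        np.asarray(u.atoms.names).astype(str),
        np.asarray(u.atoms.resnames).astype(str),
        np.asarray(u.atoms.resids).astype(int),
        chains,
    )


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return (stripped[:1] or "C").upper()


def _ligand_mask(selector, res_names, res_ids, chain_ids) -> np.ndarray:
    if ":" in selector:
        chain, _, resid = selector.partition(":")
        try:
            resid_i = int(resid)
        except ValueError as exc:
            raise SelectionError(f"bad ligand selector {selector!r}") from exc
        mask = (chain_ids == chain) & (res_ids == resid_i)
    else:
        mask = res_names == selector
    if not mask.any():
        raise SelectionError(f"ligand selector {selector!r} matched no residue")
    keys = {(c, int(r)) for c, r in zip(chain_ids[mask], res_ids[mask])}
    if len(keys) != 1:
        raise SelectionError(
            f"ligand selector {selector!r} matched {len(keys)} residues; "
            "expected exactly one"
        )
    return mask


def _read_pqr_charges(path: Path, protein_mask, ligand_mask, res_names):
    """Read per-atom charges/radii from PQR; rows must match the protein
    atoms, either directly or after dropping the ligand residue."""
    import MDAnalysis as mda

    try:
        u = mda.Universe(str(path))
        pqr_charges = np.asarray(u.atoms.charges, dtype=float)
        pqr_radii = np.asarray(u.atoms.radii, dtype=float)
        pqr_resnames = np.asarray(u.atoms.resnames).astype(str)
    except Exception as exc:
        raise FormatError(f"cannot parse {path} as PQR: {exc}") from exc

    n_protein = int(protein_mask.sum())
    if len(pqr_charges) == n_protein:
        return pqr_charges, pqr_radii
    lig_names = set(res_names[ligand_mask])
    keep = ~np.isin(pqr_resnames, sorted(lig_names))
    if keep.sum() == n_protein:
        return pqr_charges[keep], pqr_radii[keep]
    raise ConsistencyError(
        f"PQR has {len(pqr_charges)} atoms; cannot match {n_protein} protein atoms"
    )


# ---------------------------------------------------------------------------
# tunnel profiles


def load_tunnel_profile(path: str | Path) -> TunnelProfile:
    """Load a CAVER-style per-frame sphere list (CSV ``frame,x,y,z,r``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"cannot read tunnel CSV {path}: {exc}") from exc
    required = ["frame", "x", "y", "z", "r"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"tunnel CSV {path} lacks columns {missing}")
    if len(df) == 0:
        return TunnelProfile(spheres={}, source="imported")
    try:
        frames = df["frame"].astype(int)
        values = df[["x", "y", "z", "r"]].astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in tunnel CSV {path}: {exc}") from exc
    if values["r"].lt(0).any():
        bad = df.loc[values["r"] < 0].index[0]
        raise ValidationError(f"negative tunnel radius at {path} row {bad}")
    spheres = {
        int(frame): grp[["x", "y", "z", "r"]].to_numpy(dtype=float)
        for frame, grp in pd.concat([frames, values], axis=1).groupby("frame")
    }
    return TunnelProfile(spheres=spheres, source="imported")


def write_tunnel_profile(tunnel: TunnelProfile, path: str | Path) -> None:
    rows = []
    for frame in sorted(tunnel.spheres):
        for x, y, z, r in tunnel.spheres[frame]:
            rows.append((frame, x, y, z, r))
    pd.DataFrame(rows, columns=["frame", "x", "y", "z", "r"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# active site specs


def load_active_site(path: str | Path) -> ActiveSiteSpec:
    """Active-site spec: YAML/JSON list of ``{chain, resid}`` mappings."""
    path = Path(path)
    text = path.read_text()
    try:
        data = yaml.safe_load(text)  # YAML superset also parses JSON
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse active-site spec {path}: {exc}") from exc
    if not isinstance(data, list) or not data:
        raise ValidationError(f"active-site spec {path} must be a non-empty list")
    residues = []
    for item in data:
        try:
            residues.append((str(item["chain"]), int(item["resid"])))
        except (TypeError, KeyError, ValueError) as exc:
            raise FormatError(
                f"active-site entries need 'chain' and 'resid': {item!r}"
            ) from exc
    return ActiveSiteSpec(residues=residues)


def write_active_site(spec: ActiveSiteSpec, path: str | Path) -> None:
    data = [{"chain": c, "resid": r} for c, r in spec.residues]
    Path(path).write_text(yaml.safe_dump(data))


# ---------------------------------------------------------------------------
# attribute tables


def write_attribute_table(
    table: AttributeTable, path: str | Path, format: str = "csv"
) -> None:
    """Write one row per time step (columns: step, attributes, category)."""
    df: pd.DataFrame = table.data
    if len(df) == 0:
        raise ValidationError("attribute table is empty")
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        records = json.loads(df.to_json(orient="records", double_precision=15))
        path.write_text(json.dumps({"dt": table.dt, "steps": records}, indent=1))
    else:
        raise ValidationError(f"unknown attribute table format {format!r}")


def read_attribute_table(path: str | Path, format: str = "csv") -> AttributeTable:
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
        return AttributeTable(data=df, dt=2.0)
    elif format == "json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["steps"])
        return AttributeTable(data=df, dt=float(payload.get("dt", 2.0)))
    raise ValidationError(f"unknown attribute table format {format!r}")


# ---------------------------------------------------------------------------
# trajectory writing


def write_trajectory_csv(traj: LigandTrajectory, path: str | Path) -> None:
    """Simplified/raw trajectory as one ``step,x,y,z`` row per vertex; the
    ``step`` column carries original step indices for decimated output."""
    idx = (
        traj.indices
        if traj.indices is not None
        else np.arange(len(traj.positions))
    )
    df = pd.DataFrame(
        {
            "step": idx,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "z": traj.positions[:, 2],
        }
    )
    df.to_csv(path, index=False)


def write_trajectory_pdb(traj: LigandTrajectory, path: str | Path) -> None:
    """Trajectory as a multi-model PDB with one pseudo-atom per frame."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = len(traj.positions)
    stack = struc.AtomArrayStack(n, 1)
    stack.coord = traj.positions[:, None, :]
    stack.chain_id = np.array(["X"])
    stack.res_id = np.array([1])
    stack.res_name = np.array(["TRJ"])
    stack.atom_name = np.array(["C1"])
    stack.element = np.array(["C"])
    stack.hetero = np.array([True])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_frameset_pdb(
    frames: FrameSet, path: str | Path, ligand: LigandTrajectory | None = None,
    ligand_res_name: str = "LIG", ligand_chain: str = "L",
) -> None:
    """Write protein frames (optionally with ligand atoms appended) as a
    multi-model PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames = frames.n_frames
    n_prot = frames.n_atoms
    n_lig = 0
    if ligand is not None:
        if ligand.atom_coords is None:
            raise ValidationError("ligand has no per-atom coordinates to write")
        if len(ligand) != n_frames:
            raise ConsistencyError("ligand/frame count mismatch")
        n_lig = ligand.atom_coords.shape[1]

    stack = struc.AtomArrayStack(n_frames, n_prot + n_lig)
    coords = np.concatenate(
        [frames.coords] + ([ligand.atom_coords] if n_lig else []), axis=1
    )
    stack.coord = coords
    stack.chain_id = np.concatenate(
        [frames.chain_ids, np.array([ligand_chain] * n_lig)]
    )
    max_res = int(frames.res_ids.max()) if n_prot else 0
    stack.res_id = np.concatenate(
        [frames.res_ids, np.array([max_res + 1] * n_lig, dtype=int)]
    )
    stack.res_name = np.concatenate(
        [frames.res_names, np.array([ligand_res_name] * n_lig)]
    )
    lig_elements = (
        ligand.atom_elements
        if (ligand is not None and ligand.atom_elements is not None)
        else np.array(["C"] * n_lig)
    )
    lig_names = np.array(
        [f"{el}{i + 1}" for i, el in enumerate(lig_elements)]
    ) if n_lig else np.empty(0, dtype=str)
    stack.atom_name = np.concatenate([frames.atom_names, lig_names])
    stack.element = np.concatenate([frames.elements, lig_elements])
    stack.hetero = np.concatenate(
        [np.zeros(n_prot, dtype=bool), np.ones(n_lig, dtype=bool)]
    )
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def write_pqr(
    frames: FrameSet,
    path: str | Path,
    frame: int = 0,
    ligand: LigandTrajectory | None = None,
    ligand_res_name: str = "LIG",
) -> None:
    """Write a single frame as PQR (charge and radius in the occupancy /
    B-factor columns).  Atoms with no charge get 0.0."""
    charges = (
        frames.charges
        if frames.charges is not None
        else np.zeros(frames.n_atoms)
    )
    radii = frames.vdw_radii
    lines = []
    serial = 1
    for i in range(frames.n_atoms):
        x, y, z = frames.coords[frame, i]
        lines.append(
            f"ATOM  {serial:>5d} {frames.atom_names[i]:<4s} "
            f"{frames.res_names[i]:<4s}{frames.chain_ids[i]:1s}"
            f"{int(frames.res_ids[i]):>4d}    "
            f"{x:8.3f} {y:8.3f} {z:8.3f} {charges[i]:7.4f} {radii[i]:6.4f}"
        )
        serial += 1
    if ligand is not None and ligand.atom_coords is not None:
        max_res = int(frames.res_ids.max()) + 1
        elements = (
            ligand.atom_elements
            if ligand.atom_elements is not None
            else ["C"] * ligand.atom_coords.shape[1]
        )
        for j in range(ligand.atom_coords.shape[1]):
            x, y, z = ligand.atom_coords[frame, j]
            lines.append(
                f"ATOM  {serial:>5d} {elements[j]}{j + 1:<3d} "
                f"{ligand_res_name:<4s}L{max_res:>4d}    "
                f"{x:8.3f} {y:8.3f} {z:8.3f} {0.0:7.4f} {1.7:6.4f}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
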