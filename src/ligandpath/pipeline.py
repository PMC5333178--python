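"""End-to-end orchestration: load -> attributes -> auto-simplify -> report.

Every stage communicates through files so each CLI subcommand is
independently usable; ``run_all`` writes a manifest with content hashes of
every artifact (CSV/JSON artifacts are bitwise-deterministic for a fixed
config and seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import md_io, report, synthetic
from .attributes import compute_attribute_table
from .model import (
    AttributeTable,
    CategoryThresholds,
    StucknessParams,
    ValidationError,
)
from .simplify import AutoSimplifyConfig, simplify_auto

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of the full pipeline.

    When ``trajectory`` is unset a synthetic scenario (``preset``,
    ``n_steps``, ``seed``) is generated into the output directory and then
    consumed through the regular file loaders.
    """

    outdir: str = "ligandpath_run"
    seed: int = 42
    # inputs (all optional; defaults come from the synthetic scenario)
    trajectory: str | None = None
    topology: str | None = None
    ligand: str = "LIG"
    charges: str | None = None
    active_site: str | None = None
    tunnel: str | None = None
    preset: str = "binding"
    n_steps: int = 2000
    dt: float = 2.0
    # attribute parameters
    stuck_n: int = 4
    lining_cutoff: float = 2.0
    k_lining: int = 3
    scale: str = "kyte-doolittle"
    active_site_radius: float = 4.0
    outside_clearance: float = 5.0
    burial_contacts: int = 40
    contact_shell: float = 8.0
    # simplification parameters
    backend: str = "smooth"
    tau: float = 1.0
    eps_frac: float = 0.01
    nu: float = 2.0
    window: int = 9
    order: int = 2
    dp_base_tol: float = 0.5
    # report parameters
    smooth_window: int = 9
    scatter: str = "dist_active_site:stuckness"
    timeline_property: str = "hydrophobicity"

    def __post_init__(self) -> None:
        # constructing the component configs performs their validation
        self.stuckness_params()
        self.thresholds()
        self.simplify_config()
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValidationError("smooth_window must be an odd count >= 1")
        if ":" not in self.scatter:
            raise ValidationError("scatter must be 'X_ATTR:Y_ATTR'")

    def stuckness_params(self) -> StucknessParams:
        return StucknessParams(n=self.stuck_n)

    def thresholds(self) -> CategoryThresholds:
        return CategoryThresholds(
            active_site_radius=self.active_site_radius,
            outside_clearance=self.outside_clearance,
            burial_contacts=self.burial_contacts,
            contact_shell=self.contact_shell,
        )

    def simplify_config(self) -> AutoSimplifyConfig:
        return AutoSimplifyConfig(
            tau=self.tau,
            eps_frac=self.eps_frac,
            nu=self.nu,
            backend=self.backend,
            window=self.window,
            order=self.order,
            dp_base_tol=self.dp_base_tol,
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config {path} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest mapping artifact
    names to content hashes.  On error, partially written outputs are
    removed and the failing stage is named."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def track(path: Path) -> Path:
        written.append(path)
        return path

    stage = "setup"
    try:
        # stage 1: inputs (generated if no trajectory given)
        stage = "synthesize"
        traj_path = config.trajectory
        charges_path = config.charges
        site_path = config.active_site
        if traj_path is None:
            fixture_dir = outdir / "fixture"
            spec = synthetic.ScenarioSpec.preset(
                config.preset, seed=config.seed, n_steps=config.n_steps, dt=config.dt
            )
            synthetic.generate(spec, outdir=fixture_dir)
            for name in ("trajectory.pdb", "system.pqr", "active_site.yaml",
                         "ground_truth.json"):
                track(fixture_dir / name)
            traj_path = str(fixture_dir / "trajectory.pdb")
            charges_path = str(fixture_dir / "system.pqr")
            site_path = str(fixture_dir / "active_site.yaml")
        if site_path is None:
            raise ValidationError("an active-site spec is required")

        stage = "load"
        frames, traj = md_io.load_frameset(
            traj_path,
            topology_path=config.topology,
            ligand_selector=config.ligand,
            charges_path=charges_path,
            dt=config.dt,
        )
        site = md_io.load_active_site(site_path)
        tunnel = (
            md_io.load_tunnel_profile(config.tunnel)
            if config.tunnel is not None
            else None
        )

        stage = "attributes"
        table = compute_attribute_table(
            frames,
            traj,
            site,
            tunnel=tunnel,
            stuck_params=config.stuckness_params(),
            thresholds=config.thresholds(),
            lining_cutoff=config.lining_cutoff,
            k_lining=config.k_lining,
            scale=config.scale,
        )
        md_io.write_attribute_table(table, track(outdir / "attrs.csv"), "csv")
        md_io.write_attribute_table(table, track(outdir / "attrs.json"), "json")

        stage = "simplify"
        simplified, state, trace = simplify_auto(traj, config.simplify_config())
        md_io.write_trajectory_pdb(simplified, track(outdir / "simplified.pdb"))
        md_io.write_trajectory_csv(simplified, track(outdir / "simplified.csv"))
        track(outdir / "state.json").write_text(
            json.dumps(
                {"state": state.to_dict(), "trace": trace.to_dict()},
                indent=1,
                sort_keys=True,
            )
        )

        stage = "report"
        report.build_overview(
            table,
            png_path=track(outdir / "overview.png"),
            csv_path=track(outdir / "overview.csv"),
        )
        report.build_residue_timelines(
            table,
            property=config.timeline_property,
            frames=frames,
            png_path=track(outdir / "timelines.png"),
            json_path=track(outdir / "timelines.json"),
        )
        x_attr, _, y_attr = config.scatter.partition(":")
        report.export_scatter_data(
            table,
            x_attr,
            y_attr,
            window=config.smooth_window,
            csv_path=track(outdir / "scatter.csv"),
            png_path=track(outdir / "scatter.png"),
        )

        stage = "manifest"
        manifest = {
            str(p.relative_to(outdir)): _sha256(p) for p in written if p.exists()
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
        return manifest
    except Exception as exc:
        for p in written:
            try:
                if p.exists():
                    p.unlink()
            except OSError:  # pragma: no cover
                pass
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
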