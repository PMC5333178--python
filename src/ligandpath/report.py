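"""Static visual/tabular exports: trajectory overview, lining-residue
timelines and scatter data.

Images are best-effort renderings; all correctness-relevant content also
goes to CSV/JSON so exports are pure, bitwise-reproducible functions of the
attribute table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

from .attributes import sliding_window
from .model import AttributeTable, FrameSet, ValidationError
from .scales import DONOR_ACCEPTOR, KYTE_DOOLITTLE

logger = logging.getLogger(__name__)

#: Category colors of the 1D trajectory overview.
CATEGORY_COLORS = {
    "outside": "white",
    "surface": "tab:blue",
    "inside": "tab:orange",
    "active-site": "tab:red",
}

TIMELINE_PROPERTIES = ("hydrophobicity", "charge", "donor-acceptor")


@dataclass
class OverviewTrack:
    """Per-step positional category plus its color map."""

    categories: np.ndarray
    colors: dict = None

    def __post_init__(self):
        if self.colors is None:
            self.colors = dict(CATEGORY_COLORS)

    def run_lengths(self) -> list[tuple[str, int, int]]:
        """(category, start, end) runs, half-open."""
        runs = []
        cats = self.categories
        start = 0
        for i in range(1, len(cats) + 1):
            if i == len(cats) or cats[i] != cats[start]:
                runs.append((str(cats[start]), start, i))
                start = i
        return runs


@dataclass
class ResidueTimeline:
    """Per-residue presence intervals among the k closest residues, each
    with a property value used for coloring."""

    intervals: dict  # residue label -> list of (start, end, value)
    property: str


# ---------------------------------------------------------------------------


def build_overview(
    table: AttributeTable,
    png_path: str | Path | None = None,
    csv_path: str | Path | None = None,
) -> OverviewTrack:
    """1D category-per-step track; optional horizontal color-bar PNG and
    (step, category) CSV."""
    df = table.data
    if len(df) == 0:
        raise ValidationError("attribute table is empty")
    cats = df["category"].to_numpy(dtype=object)
    track = OverviewTrack(categories=cats)
    if csv_path is not None:
        pd.DataFrame({"step": df["step"], "category": cats}).to_csv(
            csv_path, index=False
        )
    if png_path is not None:
        fig, ax = plt.subplots(figsize=(10, 1.2))
        for cat, start, end in track.run_lengths():
            ax.axvspan(start, end, color=track.colors.get(cat, "gray"))
        ax.set_xlim(0, len(cats))
        ax.set_yticks([])
        ax.set_xlabel("time step")
        fig.tight_layout()
        fig.savefig(png_path, dpi=110)
        plt.close(fig)
    return track


def _lining_sets(table: AttributeTable) -> list[set]:
    df = table.data
    cols = sorted(
        c for c in df.columns if c.startswith("lining") and not c.endswith("_dist")
    )
    sets = []
    for _, row in df[cols].iterrows():
        sets.append({v for v in row.tolist() if isinstance(v, str) and v})
    return sets


def _residue_property(
    label: str, prop: str, name_map: dict, frames: FrameSet | None
):
    name = name_map.get(label, "").upper()
    if prop == "hydrophobicity":
        return KYTE_DOOLITTLE.get(name, float("nan"))
    if prop == "charge":
        if frames is None or frames.charges is None:
            return float("nan")
        mask = frames.residue_labels() == label
        return float(frames.charges[mask].mean()) if mask.any() else float("nan")
    if prop == "donor-acceptor":
        return DONOR_ACCEPTOR.get(name, "none")
    raise ValidationError(
        f"unknown timeline property {prop!r}; options: {TIMELINE_PROPERTIES}"
    )


def build_residue_timelines(
    table: AttributeTable,
    property: str = "hydrophobicity",
    frames: FrameSet | None = None,
    name_map: dict | None = None,
    png_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> ResidueTimeline:
    """Presence intervals of every residue that ever appears among the k
    closest; interruptions appear exactly where the residue drops out."""
    if property not in TIMELINE_PROPERTIES:
        raise ValidationError(
            f"unknown timeline property {property!r}; options: {TIMELINE_PROPERTIES}"
        )
    sets = _lining_sets(table)
    if name_map is None:
        name_map = frames.residue_name_map() if frames is not None else {}
    residues = sorted({lab for s in sets for lab in s})
    intervals: dict[str, list] = {}
    for lab in residues:
        runs = []
        start = None
        for i, s in enumerate(sets):
            present = lab in s
            if present and start is None:
                start = i
            elif not present and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(sets)))
        value = _residue_property(lab, property, name_map, frames)
        intervals[lab] = [(a, b, value) for a, b in runs]
    timeline = ResidueTimeline(intervals=intervals, property=property)

    if json_path is not None:
        payload = {
            "property": property,
            "residues": {
                lab: [
                    {"start": a, "end": b, "value": v if v == v else None}
                    if not isinstance(v, str)
                    else {"start": a, "end": b, "value": v}
                    for a, b, v in runs
                ]
                for lab, runs in intervals.items()
            },
        }
        import json as _json

        Path(json_path).write_text(_json.dumps(payload, indent=1, sort_keys=True))

    if png_path is not None:
        fig, ax = plt.subplots(figsize=(10, max(2, 0.25 * len(residues))))
        numeric = property != "donor-acceptor"
        if numeric:
            vals = [
                v
                for runs in intervals.values()
                for _, _, v in runs
                if isinstance(v, float) and v == v
            ]
            vmax = max((abs(v) for v in vals), default=1.0) or 1.0
            cmap = plt.get_cmap("coolwarm")
        role_colors = {"donor": "tab:blue", "acceptor": "tab:red",
                       "both": "tab:purple", "none": "lightgray"}
        for row, lab in enumerate(residues):
            for a, b, v in intervals[lab]:
                if numeric:
                    color = cmap(0.5 + 0.5 * (v / vmax)) if v == v else "lightgray"
                else:
                    color = role_colors.get(v, "lightgray")
                ax.broken_barh([(a, b - a)], (row - 0.4, 0.8), color=color)
        ax.set_yticks(range(len(residues)))
        ax.set_yticklabels(
            [f"{lab} {name_map.get(lab, '')}" for lab in residues], fontsize=6
        )
        ax.set_xlabel("time step")
        ax.set_xlim(0, len(sets))
        fig.tight_layout()
        fig.savefig(png_path, dpi=110)
        plt.close(fig)
    return timeline


def export_scatter_data(
    table: AttributeTable,
    x_attr: str,
    y_attr: str,
    window: int = 9,
    csv_path: str | Path | None = None,
    png_path: str | Path | None = None,
) -> pd.DataFrame:
    """Raw and sliding-window-smoothed (x, y) series for a scatter pair.

    ``time`` (the step index) is accepted as an attribute name.  Returns a
    DataFrame with columns x, y, x_smooth, y_smooth.
    """
    df = table.data

    def series(attr: str) -> np.ndarray:
        if attr == "time":
            return df["step"].to_numpy(dtype=float)
        if attr not in df.columns:
            numeric = [
                c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])
            ]
            raise ValidationError(
                f"attribute {attr!r} not in table; available: {['time'] + numeric}"
            )
        return df[attr].to_numpy(dtype=float)

    x = series(x_attr)
    y = series(y_attr)
    out = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "x_smooth": sliding_window(x, window),
            "y_smooth": sliding_window(y, window),
        }
    )
    if csv_path is not None:
        out.to_csv(csv_path, index=False)
    if png_path is not None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True, sharey=True)
        axes[0].scatter(out["x"], out["y"], s=3, alpha=0.5)
        axes[0].set_title("raw")
        axes[1].scatter(out["x_smooth"], out["y_smooth"], s=3, alpha=0.5, color="tab:orange")
        axes[1].set_title(f"smoothed (w={window})")
        for ax in axes:
            ax.set_xlabel(x_attr)
        axes[0].set_ylabel(y_attr)
        fig.tight_layout()
        fig.savefig(png_path, dpi=110)
        plt.close(fig)
    return out
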