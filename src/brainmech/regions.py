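"""Region-wise statistics of biomechanical fields over a brain atlas.

A 133-label whole-brain segmentation (BrainCOLOR naming convention, the
protocol used by SLANT-style segmenters) maps voxelwise strain/stress onto
functional regions.  The bundled lookup table is a synthetic reconstruction
of that naming convention — id, name and coarse tissue class per label —
shipped as a static CSV so no external segmentation tool is needed to
interpret atlas ids.

Summaries report per-region sample count, mean, sample SD (n-1), median and
5th/95th percentiles over valid voxels, and long-format CSV export suitable
for violin plots.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .imageio import LabelEntry, LabelVolume, ScalarField, TissueClass

__all__ = [
    "RegionSummary",
    "RegionSet",
    "atlas_lookup",
    "summarize_regions",
    "builtin_region_set",
    "export_violin_data",
    "plot_violins",
]

logger = logging.getLogger("brainmech")

_ATLAS_CSV = "atlas_labels_133.csv"

#: BrainCOLOR ids for the 12 areas implicated in vascular dementia:
#: left/right caudate, cerebral white matter, hippocampus, pallidum,
#: putamen, and thalamus proper.
VASCULAR_DEMENTIA_LABELS = (36, 37, 44, 45, 47, 48, 55, 56, 57, 58, 59, 60)


@dataclass
class RegionSummary:
    """Distribution of a scalar quantity over one labeled region."""

    label: int
    name: str
    quantity: str
    frame: int | str
    values: np.ndarray
    n_voxels: int = field(init=False)
    mean: float = field(init=False)
    sd: float = field(init=False)
    median: float = field(init=False)
    p5: float = field(init=False)
    p95: float = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        v = v[np.isfinite(v)]
        self.values = v
        self.n_voxels = int(v.size)
        if v.size == 0:
            self.mean = self.sd = self.median = self.p5 = self.p95 = float("nan")
        else:
            self.mean = float(v.mean())
            # sample SD (n-1); a single voxel has undefined spread
            self.sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
            self.median = float(np.median(v))
            self.p5 = float(np.percentile(v, 5))
            self.p95 = float(np.percentile(v, 95))


@dataclass(frozen=True)
class RegionSet:
    """Named collection of atlas label ids."""

    name: str
    labels: tuple[int, ...]


def atlas_lookup() -> dict[int, LabelEntry]:
    """The bundled 133-entry whole-brain label lookup (incl. background 0)."""
    text = resources.files("brainmech.data").joinpath(_ATLAS_CSV).read_text()
    lookup: dict[int, LabelEntry] = {}
    for row in csv.DictReader(text.splitlines()):
        lookup[int(row["id"])] = LabelEntry(row["name"], TissueClass(row["tissue_class"]))
    return lookup


_BUILTIN_SETS = {
    "vascular_dementia": VASCULAR_DEMENTIA_LABELS,
}


def builtin_region_set(name: str) -> RegionSet:
    """Look up a built-in region set by name.

    ``vascular_dementia``: the 12 areas (six structures, left and right)
    whose impairment is characteristic of vascular dementia — caudate,
    cerebral white matter, hippocampus, pallidum, putamen, thalamus proper.
    """
    try:
        return RegionSet(name, tuple(_BUILTIN_SETS[name]))
    except KeyError:
        raise ValueError(
            f"unknown region set {name!r}; available: {sorted(_BUILTIN_SETS)}"
        ) from None


def summarize_regions(
    field_: ScalarField,
    atlas: LabelVolume,
    regions: RegionSet | Sequence[int] | None = None,
) -> list[RegionSummary]:
    """One :class:`RegionSummary` per requested label (all present nonzero
    labels by default), pooling valid voxels over the field's frames.

    A region with no valid voxels yields ``n_voxels=0`` with NaN statistics
    and a warning rather than an error.
    """
    if atlas.geometry.shape != field_.geometry.shape:
        raise ValueError("atlas grid does not match field grid")
    if regions is None:
        ids = [int(x) for x in np.unique(atlas.labels) if x != 0]
    elif isinstance(regions, RegionSet):
        ids = list(regions.labels)
    else:
        ids = [int(x) for x in regions]

    if field_.frame_indices is not None and len(field_.frame_indices) == 1:
        frame_tag: int | str = int(field_.frame_indices[0])
    elif field_.geometry.frames == 1:
        frame_tag = 0
    else:
        frame_tag = "all"

    out = []
    for lab in ids:
        name = atlas.lookup[lab].name if lab in atlas.lookup else f"label {lab}"
        in_region = field_.values[atlas.labels == lab]  # (n_region, nt)
        summ = RegionSummary(lab, name, field_.quantity, frame_tag, in_region.ravel())
        if summ.n_voxels == 0:
            warnings.warn(f"region {name!r} (label {lab}) has no valid voxels")
        out.append(summ)
    return out


def export_violin_data(
    summaries: Sequence[RegionSummary],
    path: str | Path,
    subject: str = "subject",
    summary_path: str | Path | None = None,
) -> None:
    """Write long-format per-voxel rows plus a companion summary table.

    The long CSV has columns (subject, region, quantity, frame, value) — one
    row per valid voxel sample, ready for violin plotting.  The summary CSV
    (default: same path with ``_summary`` suffix) has one row per region
    with n, mean, sd, median, p5, p95.
    """
    if not summaries:
        raise ValueError("no summaries to export")
    path = Path(path)
    rows = [
        {"subject": subject, "region": s.name, "quantity": s.quantity,
         "frame": s.frame, "value": v}
        for s in summaries
        for v in s.values
    ]
    pd.DataFrame(rows, columns=["subject", "region", "quantity", "frame", "value"]).to_csv(
        path, index=False
    )
    if summary_path is None:
        summary_path = path.with_name(path.stem + "_summary" + path.suffix)
    pd.DataFrame(
        [
            {"subject": subject, "region": s.name, "label": s.label,
             "quantity": s.quantity, "frame": s.frame, "n_voxels": s.n_voxels,
             "mean": s.mean, "sd": s.sd, "median": s.median, "p5": s.p5, "p95": s.p95}
            for s in summaries
        ]
    ).to_csv(summary_path, index=False)
    logger.info("export_violin_data: wrote %d rows for %d regions to %s",
                len(rows), len(summaries), path)


def plot_violins(summaries: Sequence[RegionSummary], path: str | Path,
                 title: str | None = None) -> None:
    """Render a violin plot of the per-region distributions (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    populated = [s for s in summaries if s.n_voxels > 0]
    if not populated:
        raise ValueError("no populated regions to plot")
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(populated)), 4))
    ax.violinplot([s.values for s in populated], showmedians=True)
    ax.set_xticks(range(1, len(populated) + 1))
    ax.set_xticklabels([s.name for s in populated], rotation=60, ha="right", fontsize=7)
    ax.set_ylabel(populated[0].quantity)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
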