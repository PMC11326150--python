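"""Grid alignment, brain trimming, amplitude downscaling, frame selection.

Amplified-MRI displacement fields exaggerate true brain motion by a large
factor (up to 25x), so before any mechanics the field is rescaled by one
global factor chosen so the maximum displacement over all voxels,
orientations and cardiac phases equals a physiological target (187 um by
default).  Label volumes arriving on a different grid are resliced onto the
displacement grid by nearest-neighbour interpolation through a supplied
world-to-world affine, and the field is trimmed to the brain mask before
gradients are taken.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from .imageio import (
    DisplacementField,
    GridGeometry,
    LabelVolume,
    ScalarField,
    TensorField,
)

__all__ = [
    "PipelineConfig",
    "resample_labels",
    "trim_to_mask",
    "downscale_displacement",
    "select_timepoint",
]

logger = logging.getLogger("brainmech")

#: physiological peak brain displacement over the cardiac cycle, mm (187 um)
DEFAULT_TARGET_MAX_DISPLACEMENT_MM = 0.187


@dataclass
class PipelineConfig:
    """Tunable knobs of the pre-processing and mechanics pipeline.

    Parameters
    ----------
    target_max_displacement
        Peak in-brain displacement after downscaling, in mm (default
        0.187 mm = 187 um, the literature peak over the cardiac cycle).
    cycle_duration
        Cardiac cycle length in seconds; sets the frame interval
        ``cycle_duration / n_t``.
    temporal_mode
        ``"full_history"`` computes every cardiac phase;
        ``"single_timepoint"`` restricts output to one automatically
        selected phase.
    selection_metric
        Metric ranking frames in single-timepoint mode: the in-mask 90th
        percentile of displacement magnitude (``"displacement_p90"``) or of
        von Mises strain (``"strain_p90"``).
    percentile
        Percentile used by the selection metric (default 90).
    downscale_norm
        How "maximum displacement over all orientations" is measured:
        Euclidean vector magnitude (default) or largest absolute component.
    strain_convention
        ``"standard"`` uses E = (F^T F - I)/2; ``"paper"`` omits the half.
    components
        Displacement component convention on read: world mm or voxel index.
    """

    target_max_displacement: float = DEFAULT_TARGET_MAX_DISPLACEMENT_MM
    cycle_duration: float = 1.0
    temporal_mode: str = "full_history"
    selection_metric: str = "displacement_p90"
    percentile: float = 90.0
    downscale_norm: str = "vector_magnitude"
    strain_convention: str = "standard"
    components: str = "world"
    include_csf: bool = False
    det_floor: float = 1e-8
    cond_ceiling: float = 1e8

    def __post_init__(self) -> None:
        if self.target_max_displacement <= 0:
            raise ValueError("target_max_displacement must be positive")
        if not (0.0 < self.percentile < 100.0):
            raise ValueError("percentile must lie in (0, 100)")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")
        if self.temporal_mode not in ("full_history", "single_timepoint"):
            raise ValueError(f"unknown temporal_mode {self.temporal_mode!r}")
        if self.selection_metric not in ("displacement_p90", "strain_p90"):
            raise ValueError(f"unknown selection_metric {self.selection_metric!r}")
        if self.downscale_norm not in ("vector_magnitude", "component_max"):
            raise ValueError(f"unknown downscale_norm {self.downscale_norm!r}")
        if self.strain_convention not in ("standard", "paper"):
            raise ValueError(f"unknown strain_convention {self.strain_convention!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# label reslicing
# ---------------------------------------------------------------------------


def resample_labels(
    labels: LabelVolume,
    affine_to_target: np.ndarray,
    target: GridGeometry,
) -> LabelVolume:
    """Nearest-neighbour reslice of a label volume onto a target grid.

    ``affine_to_target`` maps *source world* coordinates onto *target world*
    coordinates (a FLIRT-style transform).  Target voxels falling outside
    the source extent become background 0.
    """
    affine_to_target = np.asarray(affine_to_target, dtype=float)
    if affine_to_target.shape != (4, 4):
        raise ValueError("affine_to_target must be 4x4")
    if abs(np.linalg.det(affine_to_target[:3, :3])) < 1e-12:
        raise ValueError("singular affine")

    # target index -> target world -> source world -> source index
    chain = (
        np.linalg.inv(labels.geometry.affine)
        @ np.linalg.inv(affine_to_target)
        @ target.affine
    )
    idx = np.indices(target.shape, dtype=float).reshape(3, -1)
    src = chain[:3, :3] @ idx + chain[:3, 3:4]
    out = ndimage.map_coordinates(
        labels.labels.astype(np.float64), src, order=0, mode="constant", cval=0.0
    )
    resampled = np.rint(out).astype(labels.labels.dtype).reshape(target.shape)
    geom = GridGeometry(target.shape, target.affine, frames=1)
    return LabelVolume(resampled, geom, dict(labels.lookup))


# ---------------------------------------------------------------------------
# brain trimming
# ---------------------------------------------------------------------------


def trim_to_mask(field: DisplacementField, mask: LabelVolume) -> DisplacementField:
    """NaN out displacements outside the brain mask (label 0).

    The bounding box of nonzero labels is recorded on the returned field for
    cropping of downstream exports.
    """
    if not field.geometry.same_grid(mask.geometry):
        raise ValueError("mask grid does not match displacement grid")
    inside = mask.brain_mask
    data = field.data.copy()
    data[~inside] = np.nan
    if not inside.any():
        logger.warning("trim_to_mask: mask is empty; entire field invalidated")
        bbox = None
    else:
        bbox = tuple(
            slice(int(ax.min()), int(ax.max()) + 1) for ax in np.nonzero(inside)
        )
    return dataclasses.replace(field, data=data, mask_bbox=bbox)


# ---------------------------------------------------------------------------
# amplitude downscaling
# ---------------------------------------------------------------------------


def downscale_displacement(
    field: DisplacementField, config: PipelineConfig | None = None
) -> tuple[DisplacementField, float]:
    """Scale the whole series so its peak displacement hits the target.

    One scalar ``s = target / M`` multiplies every component of every frame,
    where ``M`` is the maximum over all finite voxels and frames of the
    displacement magnitude (Euclidean norm by default, largest absolute
    component with ``downscale_norm="component_max"``).  Returns the scaled
    field and ``s``.
    """
    config = config or PipelineConfig()
    if config.downscale_norm == "vector_magnitude":
        metric = field.magnitude()
    else:
        metric = np.nanmax(np.abs(field.data), axis=-1)
    peak = np.nanmax(metric, initial=np.nan) if np.isfinite(metric).any() else np.nan
    if not np.isfinite(peak) or peak <= 0.0:
        raise ValueError("cannot downscale zero field: no finite, nonzero displacement")
    s = config.target_max_displacement / float(peak)
    logger.info("downscale_displacement: peak %.6g mm, scale factor %.6g", peak, s)
    return dataclasses.replace(field, data=field.data * s), s


# ---------------------------------------------------------------------------
# frame selection
# ---------------------------------------------------------------------------


def select_timepoint(
    field: DisplacementField,
    strain: TensorField | ScalarField | None = None,
    config: PipelineConfig | None = None,
) -> int:
    """Pick the cardiac phase with the largest in-mask percentile metric.

    With ``selection_metric="displacement_p90"`` the metric is the 90th
    percentile (configurable) of the displacement magnitude per frame; with
    ``"strain_p90"`` it is the same percentile of the von Mises strain,
    which must be supplied (as a tensor field, reduced internally, or an
    already-reduced scalar field).  Ties break to the earliest frame.
    """
    config = config or PipelineConfig()
    if config.selection_metric == "displacement_p90":
        per_voxel = field.magnitude()
    else:
        if strain is None:
            raise ValueError("strain_p90 selection requires a strain field")
        if isinstance(strain, TensorField):
            from .mechanics import von_mises

            per_voxel = von_mises(strain).values
        else:
            per_voxel = strain.values
    n_t = per_voxel.shape[3]
    scores = np.full(n_t, -np.inf)
    for t in range(n_t):
        frame = per_voxel[..., t]
        finite = frame[np.isfinite(frame)]
        if finite.size:
            scores[t] = np.percentile(finite, config.percentile)
    if not np.isfinite(scores).any():
        raise ValueError("no finite in-mask values in any frame")
    return int(np.argmax(scores))
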