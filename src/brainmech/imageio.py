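"""Image containers and NIfTI/VTK/CSV input-output.

Everything downstream (gradients, strain, stress, region statistics) runs on
the containers defined here: a time-resolved vector field on a regular voxel
grid (:class:`DisplacementField`), an integer label volume with a tissue
lookup (:class:`LabelVolume`), and per-voxel 3x3 tensor / scalar fields
(:class:`TensorField`, :class:`ScalarField`).  Grid geometry travels with
every container as a :class:`GridGeometry` so physical spacing and the
voxel-index -> world-mm affine are never lost between stages.

Conventions
-----------
* NaN marks an invalid voxel in every floating-point volume written or held
  in memory; statistics and gradients skip NaNs.
* A 4D displacement series is stored as a 5D NIfTI ``(nx, ny, nz, nt, 3)``
  with the vector components on the trailing (5th) dimension; three separate
  4D component files are also accepted on read.
* Displacement components are interpreted in world (scanner) millimetres by
  default; ``components="voxel"`` on read applies the affine's 3x3 block to
  rotate/scale voxel-index displacements into world mm.
* Symmetric tensors are packed on a trailing dimension of 6 in the order
  ``xx, yy, zz, xy, xz, yz``; general tensors use 9 components (row-major).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import nibabel as nib

__all__ = [
    "TissueClass",
    "GridGeometry",
    "DisplacementField",
    "LabelEntry",
    "LabelVolume",
    "TensorField",
    "ScalarField",
    "read_displacement_field",
    "write_displacement_field",
    "read_label_volume",
    "write_label_volume",
    "read_affine_matrix",
    "write_tensor_field",
    "read_tensor_field",
    "write_scalar_field",
    "SYMMETRIC_COMPONENT_ORDER",
]

#: component order used when packing a symmetric 3x3 tensor into 6 channels
SYMMETRIC_COMPONENT_ORDER = ("xx", "yy", "zz", "xy", "xz", "yz")
_SYM_IDX = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))

MAX_FRAMES = 64


class TissueClass(str, Enum):
    """Coarse tissue classes used for material assignment."""

    BACKGROUND = "background"
    CSF = "CSF"
    GM = "GM"
    WM = "WM"


# ---------------------------------------------------------------------------
# grid geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridGeometry:
    """Regular voxel grid with physical placement and a cardiac time axis.

    Parameters
    ----------
    shape
        Number of voxels along each spatial axis ``(nx, ny, nz)``.
    affine
        4x4 matrix mapping voxel indices to world coordinates in mm.
    frames
        Number of cardiac phases (1 for static volumes, at most 64).
    frame_interval
        Seconds per cardiac phase.  Defaults to ``cycle_duration / frames``
        with a 1 s cycle when not given.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray
    frames: int = 1
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        if not (1 <= self.frames <= MAX_FRAMES):
            raise ValueError(f"frames must lie in [1, {MAX_FRAMES}], got {self.frames}")
        if abs(np.linalg.det(affine[:3, :3])) <= 0.0:
            raise ValueError("affine spatial block is singular")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if self.frame_interval is None:
            object.__setattr__(self, "frame_interval", 1.0 / self.frames)
        elif self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing ``(dx, dy, dz)`` in mm: column norms of the affine block."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @classmethod
    def axis_aligned(
        cls,
        shape: Sequence[int],
        spacing: Sequence[float] = (1.0, 1.0, 1.0),
        origin: Sequence[float] = (0.0, 0.0, 0.0),
        frames: int = 1,
        frame_interval: float | None = None,
    ) -> "GridGeometry":
        """Build a geometry with an axis-aligned (diagonal) affine."""
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = origin
        return cls(tuple(shape), affine, frames=frames, frame_interval=frame_interval)

    def with_frames(self, frames: int, frame_interval: float | None = None) -> "GridGeometry":
        return GridGeometry(self.shape, self.affine, frames=frames, frame_interval=frame_interval)

    def same_grid(self, other: "GridGeometry", atol: float = 1e-6) -> bool:
        """Spatial-grid equality (shape and affine); time axis not compared."""
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)

    def world_coordinates(self) -> np.ndarray:
        """World-mm coordinates of every voxel centre, shape ``shape + (3,)``."""
        idx = np.indices(self.shape, dtype=float)
        pts = np.stack([idx[0], idx[1], idx[2], np.ones(self.shape)], axis=-1)
        return pts @ self.affine.T[:, :3]


# ---------------------------------------------------------------------------
# field containers
# ---------------------------------------------------------------------------


@dataclass
class DisplacementField:
    """Time-resolved 3-vector displacement per voxel, in mm.

    ``data`` has shape ``(nx, ny, nz, nt, 3)``.  Frame
    ``reference_frame_index`` (diastole by convention) is the reference
    configuration: displacements are measured from it.  NaN marks voxels
    outside the brain mask.
    """

    data: np.ndarray
    geometry: GridGeometry
    reference_frame_index: int = 0
    mask_bbox: tuple[slice, slice, slice] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        expected = self.geometry.shape + (self.geometry.frames, 3)
        if self.data.shape != expected:
            raise ValueError(
                f"displacement data shape {self.data.shape} does not match geometry {expected}"
            )
        if not (0 <= self.reference_frame_index < self.geometry.frames):
            raise ValueError("reference_frame_index out of range")

    @property
    def n_frames(self) -> int:
        return self.geometry.frames

    @property
    def valid(self) -> np.ndarray:
        """Boolean (nx,ny,nz,nt): all three components finite."""
        return np.isfinite(self.data).all(axis=-1)

    def magnitude(self) -> np.ndarray:
        """Euclidean norm of the displacement vector, shape (nx,ny,nz,nt)."""
        return np.linalg.norm(self.data, axis=-1)

    def copy(self) -> "DisplacementField":
        return dataclasses.replace(self, data=self.data.copy())


@dataclass(frozen=True)
class LabelEntry:
    name: str
    tissue_class: TissueClass = TissueClass.BACKGROUND


#: FAST-style 3-label lookup (1=CSF, 2=GM, 3=WM)
DEFAULT_TISSUE_LOOKUP: Mapping[int, LabelEntry] = {
    0: LabelEntry("background", TissueClass.BACKGROUND),
    1: LabelEntry("cerebrospinal fluid", TissueClass.CSF),
    2: LabelEntry("gray matter", TissueClass.GM),
    3: LabelEntry("white matter", TissueClass.WM),
}


@dataclass
class LabelVolume:
    """Integer label per voxel plus a lookup from id to name/tissue class.

    Label 0 is always background.  Every nonzero label present in the volume
    must have a lookup entry.
    """

    labels: np.ndarray
    geometry: GridGeometry
    lookup: Mapping[int, LabelEntry] = field(default_factory=lambda: dict(DEFAULT_TISSUE_LOOKUP))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.shape != self.geometry.shape:
            raise ValueError(
                f"label shape {self.labels.shape} does not match geometry {self.geometry.shape}"
            )
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        orphans = sorted(present - set(self.lookup))
        if orphans:
            raise ValueError(f"labels present with no lookup entry: {orphans}")

    def tissue_of(self, label: int) -> TissueClass:
        if label == 0:
            return TissueClass.BACKGROUND
        return self.lookup[label].tissue_class

    def tissue_class_map(self) -> dict[TissueClass, np.ndarray]:
        """Boolean mask per tissue class, covering present labels only."""
        out: dict[TissueClass, np.ndarray] = {}
        for lab in np.unique(self.labels):
            lab = int(lab)
            tc = self.tissue_of(lab)
            m = self.labels == lab
            out[tc] = out.get(tc, np.zeros(self.labels.shape, bool)) | m
        return out

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class TensorField:
    """3x3 tensor per voxel per frame; NaN-filled tensors are invalid.

    ``values`` has shape ``(nx, ny, nz, nt, 3, 3)``.  ``frame_indices`` maps
    the local time axis back to cardiac phases of the source displacement
    field (used in single-timepoint mode, where ``nt == 1``).
    """

    values: np.ndarray
    geometry: GridGeometry
    quantity: str = ""
    units: str = ""
    symmetric: bool = False
    frame_indices: tuple[int, ...] | None = None

    SYMMETRY_ATOL = 1e-10

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = self.geometry.shape + (self.geometry.frames, 3, 3)
        if self.values.shape != expected:
            raise ValueError(
                f"tensor values shape {self.values.shape} does not match geometry {expected}"
            )
        if self.frame_indices is not None and len(self.frame_indices) != self.geometry.frames:
            raise ValueError("frame_indices length must equal number of frames")
        if self.symmetric:
            v = self.values
            asym = np.nanmax(np.abs(v - np.swapaxes(v, -1, -2)), initial=0.0)
            if asym > self.SYMMETRY_ATOL:
                raise ValueError(f"tensor declared symmetric but max |T - T^T| = {asym:.3e}")

    @property
    def valid(self) -> np.ndarray:
        """Boolean (nx,ny,nz,nt): all nine components finite."""
        return np.isfinite(self.values).all(axis=(-1, -2))

    def det(self) -> "ScalarField":
        with np.errstate(invalid="ignore"):
            d = np.linalg.det(self.values)
        return ScalarField(d, self.geometry, quantity="det",
                           frame_indices=self.frame_indices)


@dataclass
class ScalarField:
    """Scalar per voxel per frame; NaN marks invalid voxels."""

    values: np.ndarray
    geometry: GridGeometry
    quantity: str = ""
    units: str = ""
    frame_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        expected = self.geometry.shape + (self.geometry.frames,)
        if self.values.shape != expected:
            raise ValueError(
                f"scalar values shape {self.values.shape} does not match geometry {expected}"
            )

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


# ---------------------------------------------------------------------------
# symmetric packing helpers
# ---------------------------------------------------------------------------


def pack_symmetric(values: np.ndarray) -> np.ndarray:
    """Pack (..., 3, 3) symmetric tensors into (..., 6) channels."""
    return np.stack([values[..., i, j] for i, j in _SYM_IDX], axis=-1)


def unpack_symmetric(channels: np.ndarray) -> np.ndarray:
    """Inverse of :func:`pack_symmetric`."""
    out = np.empty(channels.shape[:-1] + (3, 3), dtype=channels.dtype)
    for k, (i, j) in enumerate(_SYM_IDX):
        out[..., i, j] = channels[..., k]
        out[..., j, i] = channels[..., k]
    return out


# ---------------------------------------------------------------------------
# NIfTI readers / writers
# ---------------------------------------------------------------------------


def _geometry_from_img(img: nib.Nifti1Image, frames: int,
                       frame_interval: float | None = None) -> GridGeometry:
    shape = tuple(int(n) for n in img.shape[:3])
    return GridGeometry(shape, np.asarray(img.affine, float), frames=frames,
                        frame_interval=frame_interval)


def read_displacement_field(
    path: str | Path | Sequence[str | Path],
    layout: str = "5d",
    components: str = "world",
    frame_interval: float | None = None,
) -> DisplacementField:
    """Read a 4D displacement series from NIfTI.

    Parameters
    ----------
    path
        For ``layout="5d"``: one NIfTI whose 5th dimension holds the 3
        vector components (``(nx,ny,nz,nt,3)``; a 4th-dim size-3 static
        field ``(nx,ny,nz,3)`` is also accepted).  For
        ``layout="component-files"``: a sequence of three 4D NIfTI paths in
        (x, y, z) component order.
    components
        ``"world"`` (default): values already in world mm.  ``"voxel"``:
        values are voxel-index offsets; the affine's 3x3 block is applied.
    """
    if layout == "5d":
        p = Path(path)  # type: ignore[arg-type]
        if not p.exists():
            raise FileNotFoundError(p)
        img = nib.load(str(p))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.ndim == 4 and arr.shape[-1] == 3:
            arr = arr[:, :, :, None, :]
        if arr.ndim != 5 or arr.shape[-1] != 3:
            raise ValueError(
                f"expected a 5D NIfTI with trailing vector dimension 3, got shape {arr.shape}"
            )
    elif layout == "component-files":
        paths = [Path(p) for p in path]  # type: ignore[union-attr]
        if len(paths) != 3:
            raise ValueError("component-files layout needs exactly three paths")
        imgs = []
        for p in paths:
            if not p.exists():
                raise FileNotFoundError(p)
            imgs.append(nib.load(str(p)))
        shapes = {im.shape for im in imgs}
        affines_equal = all(np.allclose(im.affine, imgs[0].affine, atol=1e-6) for im in imgs)
        if len(shapes) != 1 or not affines_equal:
            raise ValueError("inconsistent component geometry across component files")
        comps = [np.asarray(im.dataobj, dtype=np.float64) for im in imgs]
        comps = [c[..., None] if c.ndim == 3 else c for c in comps]
        arr = np.stack(comps, axis=-1)
        img = imgs[0]
    else:
        raise ValueError(f"unknown layout {layout!r}")

    geom = _geometry_from_img(img, frames=arr.shape[3], frame_interval=frame_interval)
    if components == "voxel":
        arr = arr @ geom.affine[:3, :3].T
    elif components != "world":
        raise ValueError(f"unknown components convention {components!r}")
    return DisplacementField(arr, geom)


def write_displacement_field(field_: DisplacementField, path: str | Path) -> None:
    """Write as a 5D NIfTI ``(nx,ny,nz,nt,3)``, float32, NaN for invalid."""
    img = nib.Nifti1Image(field_.data.astype(np.float32), field_.geometry.affine)
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_label_lookup(path: str | Path) -> dict[int, LabelEntry]:
    """Read a CSV/TSV lookup table with columns (id, name, tissue_class)."""
    import csv

    lookup: dict[int, LabelEntry] = {0: LabelEntry("background", TissueClass.BACKGROUND)}
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.reader(fh, delimiter=delim)
        rows = list(reader)
    start = 1 if rows and not rows[0][0].strip().lstrip("-").isdigit() else 0
    for row in rows[start:]:
        if not row or not row[0].strip():
            continue
        lab = int(row[0])
        name = row[1].strip() if len(row) > 1 else str(lab)
        tc = TissueClass(row[2].strip()) if len(row) > 2 and row[2].strip() else TissueClass.BACKGROUND
        lookup[lab] = LabelEntry(name, tc)
    return lookup


INTEGER_TOLERANCE = 1e-6


def read_label_volume(
    path: str | Path,
    lookup_path: str | Path | None = None,
    lookup: Mapping[int, LabelEntry] | None = None,
) -> LabelVolume:
    """Read an integer label NIfTI; voxel values within 1e-6 of an integer
    are rounded, anything farther raises.  Without a lookup, the FAST-style
    default {1: CSF, 2: GM, 3: WM} applies."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    img = nib.load(str(p))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"label volume must be 3D, got shape {arr.shape}")
    rounded = np.rint(arr)
    if np.nanmax(np.abs(arr - rounded), initial=0.0) > INTEGER_TOLERANCE:
        raise ValueError("non-integer voxel values in label volume beyond tolerance 1e-6")
    labels = rounded.astype(np.int32)
    if lookup is None:
        lookup = read_label_lookup(lookup_path) if lookup_path else dict(DEFAULT_TISSUE_LOOKUP)
    return LabelVolume(labels, _geometry_from_img(img, frames=1), dict(lookup))


def write_label_volume(vol: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.labels.astype(np.int16), vol.geometry.affine)
    nib.save(img, str(path))


def read_affine_matrix(path: str | Path) -> np.ndarray:
    """Read a FLIRT-style whitespace-separated row-major 4x4 matrix."""
    mat = np.loadtxt(path, dtype=float)
    if mat.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}, got shape {mat.shape}")
    return mat


# ---------------------------------------------------------------------------
# tensor / scalar field export
# ---------------------------------------------------------------------------


def write_tensor_field(field_: TensorField, path: str | Path, format: str = "nifti") -> None:
    """Write a tensor field to NIfTI (6 or 9 trailing channels) or legacy VTK.

    NIfTI layout: ``(nx, ny, nz, nt, c)`` with c = 6 for symmetric fields
    (order xx, yy, zz, xy, xz, yz) and c = 9 (row-major) otherwise.  Invalid
    voxels are NaN.  VTK export writes one frame per file as an ASCII
    STRUCTURED_POINTS dataset with a 9-component ``TENSORS`` array.
    """
    if format == "nifti":
        if field_.symmetric:
            arr = pack_symmetric(field_.values)
        else:
            arr = field_.values.reshape(field_.values.shape[:-2] + (9,))
        img = nib.Nifti1Image(arr.astype(np.float32), field_.geometry.affine)
        nib.save(img, str(path))
    elif format == "vtk":
        if field_.geometry.frames != 1:
            raise ValueError("VTK export writes a single frame; slice the field first")
        _write_vtk_tensors(field_, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_tensor_field(path: str | Path, symmetric: bool | None = None,
                      quantity: str = "", units: str = "") -> TensorField:
    """Read a tensor field written by :func:`write_tensor_field` (NIfTI)."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    if arr.ndim == 4:  # single frame
        arr = arr[:, :, :, None, :]
    ncomp = arr.shape[-1]
    if ncomp == 6:
        values = unpack_symmetric(arr)
        sym = True
    elif ncomp == 9:
        values = arr.reshape(arr.shape[:-1] + (3, 3))
        sym = False
    else:
        raise ValueError(f"expected 6 or 9 tensor channels, got {ncomp}")
    if symmetric is not None:
        sym = symmetric
    geom = _geometry_from_img(img, frames=arr.shape[3])
    return TensorField(values, geom, quantity=quantity, units=units, symmetric=sym)


def write_scalar_field(field_: ScalarField, path: str | Path, format: str = "nifti") -> None:
    """Write a scalar field as 4D NIfTI (or legacy VTK for one frame)."""
    if format == "nifti":
        img = nib.Nifti1Image(field_.values.astype(np.float32), field_.geometry.affine)
        nib.save(img, str(path))
    elif format == "vtk":
        if field_.geometry.frames != 1:
            raise ValueError("VTK export writes a single frame; slice the field first")
        _write_vtk_scalars(field_, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _vtk_header(geom: GridGeometry, title: str) -> list[str]:
    nx, ny, nz = geom.shape
    dx, dy, dz = geom.spacing
    ox, oy, oz = geom.affine[:3, 3]
    return [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"SPACING {dx:.9g} {dy:.9g} {dz:.9g}",
        f"ORIGIN {ox:.9g} {oy:.9g} {oz:.9g}",
        f"POINT_DATA {nx * ny * nz}",
    ]


def _write_vtk_tensors(field_: TensorField, path: str | Path) -> None:
    name = field_.quantity or "tensor"
    lines = _vtk_header(field_.geometry, f"brainmech {name}")
    lines.append(f"TENSORS {name} double")
    # VTK point order: x varies fastest
    vals = np.moveaxis(field_.values[:, :, :, 0], (0, 1, 2), (2, 1, 0))
    flat = vals.reshape(-1, 3, 3)
    for t in flat:
        for row in t:
            lines.append(f"{row[0]:.9g} {row[1]:.9g} {row[2]:.9g}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_vtk_scalars(field_: ScalarField, path: str | Path) -> None:
    name = field_.quantity or "scalar"
    lines = _vtk_header(field_.geometry, f"brainmech {name}")
    lines.append(f"SCALARS {name} double 1")
    lines.append("LOOKUP_TABLE default")
    vals = np.moveaxis(field_.values[:, :, :, 0], (0, 1, 2), (2, 1, 0)).ravel()
    lines.extend(f"{v:.9g}" for v in vals)
    Path(path).write_text("\n".join(lines) + "\n")
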