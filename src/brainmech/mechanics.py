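"""Finite-strain mechanics on voxel grids.

From a trimmed, downscaled displacement field the pipeline computes, per
voxel and cardiac phase:

* the Eulerian displacement gradient grad(U) by NaN-aware finite
  differences with physical spacing (second-order central in the interior,
  first-order one-sided at mask boundaries);
* the deformation gradient F = (I - grad U)^-1 and its determinant J — the
  displacement is measured on the deformed (current) configuration, so the
  inverse deformation gradient is the one the gradient gives directly;
* the Green-Lagrange strain E = (F^T F - I)/2 (a no-half variant is
  available), and its periodic time derivative over the cardiac cycle;
* the compressible, isotropic Mooney-Rivlin strain energy density
  W = (G/2)(I1_bar - 3) + K[(J^2 - 1)/4 - (ln J)/2] with the isochoric
  split I1_bar = J^(-2/3) tr(F^T F);
* the Cauchy stress from the analytic derivative of W:
  sigma = (G/J) dev(B_bar) + (K/2)(J - 1/J) I with B_bar = J^(-2/3) F F^T;
* von Mises scalar reductions of strain and stress.

Shear and bulk moduli are assigned per tissue class (white matter, gray
matter, CSF) from a material table; CSF is excluded from stress and energy
by default since displacement contrast within the ventricles is unreliable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .imageio import (
    DisplacementField,
    GridGeometry,
    LabelVolume,
    ScalarField,
    TensorField,
    TissueClass,
)
from .preprocess import PipelineConfig, select_timepoint

__all__ = [
    "MaterialTable",
    "displacement_gradient",
    "deformation_gradient",
    "green_lagrange_strain",
    "strain_rate",
    "strain_energy_density",
    "cauchy_stress",
    "von_mises",
    "mooney_rivlin_energy",
    "mooney_rivlin_cauchy_stress",
    "deviator",
    "run_mechanics",
]

logger = logging.getLogger("brainmech")

_I3 = np.eye(3)


# ---------------------------------------------------------------------------
# material properties
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaterialTable:
    """Per-tissue shear (G) and bulk (K) moduli in kPa.

    Defaults are the isotropic compressible Mooney-Rivlin constants used for
    brain tissue: WM G = 0.624 kPa, GM G = 1.10 kPa, CSF G = 0.50 kPa;
    WM/GM K = 5.00e4 kPa, CSF K = 2.1e6 kPa.  CSF is excluded from stress
    computation unless ``include_csf`` is set.
    """

    shear_kpa: dict[TissueClass, float] = dc_field(
        default_factory=lambda: {
            TissueClass.WM: 0.624,
            TissueClass.GM: 1.10,
            TissueClass.CSF: 0.50,
        }
    )
    bulk_kpa: dict[TissueClass, float] = dc_field(
        default_factory=lambda: {
            TissueClass.WM: 5.00e4,
            TissueClass.GM: 5.00e4,
            TissueClass.CSF: 2.1e6,
        }
    )
    include_csf: bool = False

    def __post_init__(self) -> None:
        for tc, g in self.shear_kpa.items():
            if g <= 0:
                raise ValueError(f"shear modulus for {tc} must be positive, got {g}")
        for tc, k in self.bulk_kpa.items():
            if k <= 0:
                raise ValueError(f"bulk modulus for {tc} must be positive, got {k}")

    def included_classes(self) -> set[TissueClass]:
        out = set(self.shear_kpa) & set(self.bulk_kpa)
        if not self.include_csf:
            out.discard(TissueClass.CSF)
        return out

    @classmethod
    def from_csv(cls, path, include_csf: bool = False) -> "MaterialTable":
        """Read a material table CSV with columns tissue_class, G_kPa, K_kPa."""
        import csv

        shear: dict[TissueClass, float] = {}
        bulk: dict[TissueClass, float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                tc = TissueClass(row["tissue_class"].strip())
                shear[tc] = float(row["G_kPa"])
                bulk[tc] = float(row["K_kPa"])
        return cls(shear, bulk, include_csf=include_csf)

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["tissue_class", "G_kPa", "K_kPa"])
            for tc in self.shear_kpa:
                w.writerow([tc.value, self.shear_kpa[tc], self.bulk_kpa[tc]])


def _moduli_maps(
    labels: LabelVolume, material: MaterialTable
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (G, K) maps in kPa; NaN on background and excluded classes."""
    shape = labels.geometry.shape
    G = np.full(shape, np.nan)
    K = np.full(shape, np.nan)
    included = material.included_classes()
    for lab in np.unique(labels.labels):
        lab = int(lab)
        if lab == 0:
            continue
        tc = labels.tissue_of(lab)
        if tc == TissueClass.BACKGROUND:
            continue
        if tc not in material.shear_kpa or tc not in material.bulk_kpa:
            raise ValueError(f"no material entry for tissue class {tc.value!r} (label {lab})")
        if tc not in included:
            continue  # excluded (CSF by default): voxels stay NaN
        m = labels.labels == lab
        G[m] = material.shear_kpa[tc]
        K[m] = material.bulk_kpa[tc]
    return G, K


# ---------------------------------------------------------------------------
# displacement gradient
# ---------------------------------------------------------------------------


def _nan_gradient_axis(u: np.ndarray, axis: int, h: float) -> np.ndarray:
    """NaN-aware d/dx along one axis of a (possibly multi-channel) volume.

    Central difference where both neighbours are finite, one-sided where
    only one is, NaN where the voxel or both neighbours are invalid.
    """
    pad = [(0, 0)] * u.ndim
    pad[axis] = (1, 1)
    up = np.pad(u, pad, constant_values=np.nan)

    def shifted(offset: int) -> np.ndarray:
        sl = [slice(None)] * u.ndim
        sl[axis] = slice(1 + offset, up.shape[axis] - 1 + offset)
        return up[tuple(sl)]

    plus, minus = shifted(1), shifted(-1)
    ok_p, ok_m, ok_0 = np.isfinite(plus), np.isfinite(minus), np.isfinite(u)

    out = np.full_like(u, np.nan)
    both = ok_p & ok_m
    np.copyto(out, (plus - minus) / (2.0 * h), where=both)
    fwd = ok_p & ~ok_m & ok_0
    np.copyto(out, (plus - u) / h, where=fwd)
    bwd = ok_m & ~ok_p & ok_0
    np.copyto(out, (u - minus) / h, where=bwd)
    return out


def displacement_gradient(
    field: DisplacementField, frame: int | None = None
) -> TensorField:
    """Spatial gradient (grad U)_ij = du_i/dx_j at each voxel.

    Derivatives are taken along voxel-index axes and mapped to world
    coordinates through the inverse of the affine's 3x3 block, so oblique
    grids are handled; for an axis-aligned grid this reduces to dividing by
    the voxel spacing.  A voxel with no finite neighbour along some axis is
    invalid (NaN).
    """
    frames = range(field.n_frames) if frame is None else [frame]
    if field.valid.any(axis=3).sum() <= 1:
        raise ValueError("mask contains at most one voxel; no gradient computable")
    inv_a3 = np.linalg.inv(field.geometry.affine[:3, :3])
    nt = len(list(frames))
    out = np.full(field.geometry.shape + (nt, 3, 3), np.nan)
    for k, t in enumerate(frames):
        u = field.data[:, :, :, t, :]  # (nx,ny,nz,3)
        g_index = np.stack(
            [_nan_gradient_axis(u, axis=a, h=1.0) for a in range(3)], axis=-1
        )  # (..., 3 comp, 3 index-axis)
        out[:, :, :, k] = g_index @ inv_a3
    geom = field.geometry.with_frames(nt, field.geometry.frame_interval)
    idxs = tuple(frames) if frame is not None else None
    n_invalid = int((~np.isfinite(out).all(axis=(-1, -2))).sum())
    logger.info("displacement_gradient: %d invalid voxel-frames", n_invalid)
    return TensorField(out, geom, quantity="gradU", units="mm/mm", frame_indices=idxs)


# ---------------------------------------------------------------------------
# deformation gradient
# ---------------------------------------------------------------------------


def deformation_gradient(
    gradU: TensorField,
    det_floor: float = 1e-8,
    cond_ceiling: float = 1e8,
) -> TensorField:
    """F = (I - grad U)^-1 per voxel; degenerate voxels are invalidated.

    Voxels where det(I - grad U) <= ``det_floor`` or the condition number
    exceeds ``cond_ceiling`` become NaN rather than raising.
    """
    A = _I3 - gradU.values
    flat = A.reshape(-1, 3, 3)
    finite = np.isfinite(flat).all(axis=(1, 2))
    F = np.full_like(flat, np.nan)
    if finite.any():
        sub = flat[finite]
        det = np.linalg.det(sub)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            cond = np.linalg.cond(sub)
        ok = (det > det_floor) & np.isfinite(cond) & (cond <= cond_ceiling)
        inv = np.full_like(sub, np.nan)
        if ok.any():
            inv[ok] = np.linalg.inv(sub[ok])
        F[finite] = inv
        n_degenerate = int((~ok).sum())
        if n_degenerate:
            logger.info("deformation_gradient: %d degenerate voxel-frames invalidated",
                        n_degenerate)
    return TensorField(
        F.reshape(A.shape), gradU.geometry, quantity="F", units="mm/mm",
        frame_indices=gradU.frame_indices,
    )


# ---------------------------------------------------------------------------
# strain
# ---------------------------------------------------------------------------


def green_lagrange_strain(F: TensorField, convention: str = "standard") -> TensorField:
    """Green-Lagrange strain from F.

    ``standard``: E = (F^T F - I)/2 (the conventional finite-strain
    definition).  ``paper``: E = F^T F - I, i.e. without the half factor.
    Both vanish for rigid motions.
    """
    if convention not in ("standard", "paper"):
        raise ValueError(f"unknown strain convention {convention!r}")
    C = np.swapaxes(F.values, -1, -2) @ F.values
    E = C - _I3
    if convention == "standard":
        E = 0.5 * E
    E = 0.5 * (E + np.swapaxes(E, -1, -2))  # enforce exact symmetry
    logger.info("green_lagrange_strain: convention=%s", convention)
    return TensorField(E, F.geometry, quantity="E", units="mm/mm", symmetric=True,
                       frame_indices=F.frame_indices)


def strain_rate(E_series: TensorField, geometry: GridGeometry | None = None) -> TensorField:
    """Time derivative of the strain tensor over the (periodic) cardiac cycle.

    Central differences with wrap-around:
    Edot(t_k) = (E(t_{k+1}) - E(t_{k-1})) / (2 dt), dt = frame interval.
    Needs at least three cardiac phases.
    """
    geometry = geometry or E_series.geometry
    n_t = E_series.values.shape[3]
    if n_t < 3:
        raise ValueError(f"strain rate needs at least 3 frames, got {n_t}")
    dt = geometry.frame_interval
    fwd = np.roll(E_series.values, -1, axis=3)
    bwd = np.roll(E_series.values, 1, axis=3)
    rate = (fwd - bwd) / (2.0 * dt)
    return TensorField(rate, E_series.geometry, quantity="E_rate", units="1/s",
                       symmetric=E_series.symmetric, frame_indices=E_series.frame_indices)


# ---------------------------------------------------------------------------
# Mooney-Rivlin constitutive law (array-level kernels)
# ---------------------------------------------------------------------------


def mooney_rivlin_energy(F: np.ndarray, G, K) -> np.ndarray:
    """Strain energy density W(F) of the compressible Mooney-Rivlin law, kPa.

    W = (G/2)(I1_bar - 3) + K[(J^2 - 1)/4 - (ln J)/2],
    I1_bar = J^(-2/3) tr(F^T F).  ``G``/``K`` broadcast against the leading
    axes of ``F`` (shape (..., 3, 3)).  NaN where J <= 0.
    """
    F = np.asarray(F, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        J = np.linalg.det(F)
    I1 = np.einsum("...ij,...ij->...", F, F)
    with np.errstate(invalid="ignore", divide="ignore"):
        Jsafe = np.where(J > 0, J, np.nan)
        I1_bar = Jsafe ** (-2.0 / 3.0) * I1
        W = 0.5 * np.asarray(G) * (I1_bar - 3.0) + np.asarray(K) * (
            (Jsafe**2 - 1.0) / 4.0 - 0.5 * np.log(Jsafe)
        )
    return W


def deviator(A: np.ndarray) -> np.ndarray:
    """dev(A) = A - (tr A / 3) I for stacked 3x3 tensors."""
    tr = np.einsum("...ii->...", A)
    return A - tr[..., None, None] / 3.0 * _I3


def mooney_rivlin_cauchy_stress(F: np.ndarray, G, K) -> np.ndarray:
    """Closed-form Cauchy stress of the compressible Mooney-Rivlin law, kPa.

    sigma = (G/J) dev(B_bar) + (K/2)(J - 1/J) I, with B_bar = J^(-2/3) F F^T.
    This is the analytic (1/J)(dW/dF) F^T of :func:`mooney_rivlin_energy`.
    """
    F = np.asarray(F, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        J = np.linalg.det(F)
    with np.errstate(invalid="ignore", divide="ignore"):
        Jsafe = np.where(J > 0, J, np.nan)
        B = F @ np.swapaxes(F, -1, -2)
        B_bar = Jsafe[..., None, None] ** (-2.0 / 3.0) * B
        iso = (np.asarray(G) / Jsafe)[..., None, None] * deviator(B_bar)
        vol = (0.5 * np.asarray(K) * (Jsafe - 1.0 / Jsafe))[..., None, None] * _I3
    sigma = iso + vol
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


# ---------------------------------------------------------------------------
# voxel-field wrappers
# ---------------------------------------------------------------------------


def strain_energy_density(
    F: TensorField, material: MaterialTable, labels: LabelVolume
) -> ScalarField:
    """Per-voxel strain energy density W in kPa (0 at the reference F = I)."""
    if not F.geometry.same_grid(labels.geometry):
        raise ValueError("label grid does not match tensor grid")
    G, K = _moduli_maps(labels, material)
    W = mooney_rivlin_energy(F.values, G[..., None], K[..., None])
    return ScalarField(W, F.geometry, quantity="W", units="kPa",
                       frame_indices=F.frame_indices)


def cauchy_stress(
    F: TensorField, material: MaterialTable, labels: LabelVolume
) -> TensorField:
    """Per-voxel Cauchy stress tensor in kPa.

    CSF voxels are invalid (NaN) unless the material table includes CSF.
    """
    if not F.geometry.same_grid(labels.geometry):
        raise ValueError("label grid does not match tensor grid")
    G, K = _moduli_maps(labels, material)
    sigma = mooney_rivlin_cauchy_stress(
        F.values, G[..., None], K[..., None]
    )
    n_invalid = int((~np.isfinite(sigma).all(axis=(-1, -2))).sum())
    logger.info("cauchy_stress: %d invalid voxel-frames", n_invalid)
    return TensorField(sigma, F.geometry, quantity="sigma", units="kPa",
                       symmetric=True, frame_indices=F.frame_indices)


_VM_KIND_BY_QUANTITY = {"sigma": "stress", "stress": "stress",
                        "E": "strain", "E_rate": "strain", "strain": "strain"}


def von_mises(field: TensorField, kind: str | None = None) -> ScalarField:
    """Von Mises scalar of a symmetric tensor field.

    stress: sqrt(3/2 dev:dev); strain (and strain rate): sqrt(2/3 dev:dev).
    The kind is inferred from the field's quantity when not given.
    """
    if not field.symmetric:
        raise ValueError("von Mises reduction requires a symmetric tensor field")
    if kind is None:
        kind = _VM_KIND_BY_QUANTITY.get(field.quantity)
        if kind is None:
            raise ValueError(
                f"cannot infer von Mises kind from quantity {field.quantity!r}; pass kind="
            )
    if kind not in ("stress", "strain"):
        raise ValueError(f"unknown von Mises kind {kind!r}")
    factor = 1.5 if kind == "stress" else 2.0 / 3.0
    d = deviator(field.values)
    vm = np.sqrt(factor * np.einsum("...ij,...ij->...", d, d))
    quantity = "vm_stress" if kind == "stress" else (
        "vm_strain_rate" if field.quantity == "E_rate" else "vm_strain")
    return ScalarField(vm, field.geometry, quantity=quantity, units=field.units,
                       frame_indices=field.frame_indices)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _slice_frame(tf: TensorField, k: int) -> TensorField:
    geom = tf.geometry.with_frames(1, tf.geometry.frame_interval)
    return dataclasses.replace(tf, values=tf.values[:, :, :, k : k + 1],
                               geometry=geom, frame_indices=(k,))


def run_mechanics(
    field: DisplacementField,
    labels3: LabelVolume,
    material: MaterialTable | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, TensorField | ScalarField]:
    """Full mechanics chain on a trimmed, downscaled displacement field.

    Returns a dict with tensor fields ``F``, ``E``, ``E_rate`` (when the
    series has >= 3 frames), ``sigma``, and scalar fields ``J``, ``W``,
    ``vm_strain``, ``vm_stress``, ``disp_magnitude``.  In single-timepoint
    mode every output is restricted to the automatically selected cardiac
    phase (its index is recorded on each field's ``frame_indices``).
    """
    config = config or PipelineConfig()
    material = material or MaterialTable(include_csf=config.include_csf)
    if not field.geometry.same_grid(labels3.geometry):
        raise ValueError("segmentation grid does not match displacement grid")

    gradU = displacement_gradient(field)
    F = deformation_gradient(gradU, det_floor=config.det_floor,
                             cond_ceiling=config.cond_ceiling)
    E = green_lagrange_strain(F, convention=config.strain_convention)
    vm_strain_all = von_mises(E)

    E_rate = None
    if field.n_frames >= 3:
        E_rate = strain_rate(E, field.geometry)

    if config.temporal_mode == "single_timepoint":
        if config.selection_metric == "strain_p90":
            k = select_timepoint(field, vm_strain_all, config)
        else:
            k = select_timepoint(field, None, config)
        logger.info("run_mechanics: single_timepoint mode selected frame %d", k)
        F = _slice_frame(F, k)
        E = _slice_frame(E, k)
        if E_rate is not None:
            E_rate = _slice_frame(E_rate, k)
        disp = dataclasses.replace(
            field, data=field.data[:, :, :, k : k + 1],
            geometry=field.geometry.with_frames(1, field.geometry.frame_interval),
        )
    else:
        disp = field

    sigma = cauchy_stress(F, material, labels3)
    W = strain_energy_density(F, material, labels3)
    out: dict[str, TensorField | ScalarField] = {
        "F": F,
        "J": F.det(),
        "E": E,
        "sigma": sigma,
        "W": W,
        "vm_strain": von_mises(E),
        "vm_stress": von_mises(sigma),
        "disp_magnitude": ScalarField(
            disp.magnitude(), disp.geometry, quantity="disp_magnitude", units="mm",
            frame_indices=F.frame_indices,
        ),
    }
    if E_rate is not None:
        out["E_rate"] = E_rate
        out["vm_strain_rate"] = von_mises(E_rate, kind="strain")
    return out
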