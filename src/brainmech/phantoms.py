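"""Synthetic displacement phantoms with closed-form strain and stress.

No subject imaging ships with this package, so every end-to-end check runs
on phantoms: displacement fields whose exact Eulerian gradient — and hence
deformation gradient, Green-Lagrange strain, and Mooney-Rivlin Cauchy
stress — is known analytically at every voxel and cardiac phase.

Displacements are defined on the *current* (deformed) configuration, so the
pipeline's F = (I - grad U)^-1 is exact for them by construction and the
ground truth carries no reference/current ambiguity.

Kinds
-----
zero
    No motion; every strain and stress vanishes.
rigid_rotation
    Rotation by ``amplitude`` degrees about the z-axis through the domain
    centre; displacements are nonzero but all strain measures vanish.
uniaxial_stretch
    u_x = a x (Eulerian gradient a = ``amplitude``), so
    F = diag(1/(1-a), 1, 1).
simple_shear
    u_x = a y, so F = I + a e_x (x) e_y and J = 1.
dilation
    u = a x, so F = I/(1-a), pure volume change.
pulsatile_composite
    Smooth trigonometric field with analytic gradient, optionally with
    seeded Gaussian noise (excluded from the ground truth).

For series with more than one cardiac phase the amplitude is modulated by
sin^2(pi t / T) across the cycle (frame 0, diastole, is motion-free),
emulating the pulsatile character of cardiac-driven brain motion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .imageio import (
    DEFAULT_TISSUE_LOOKUP,
    DisplacementField,
    GridGeometry,
    LabelEntry,
    LabelVolume,
    TissueClass,
)
from .mechanics import MaterialTable, _moduli_maps, mooney_rivlin_cauchy_stress

__all__ = ["PhantomSpec", "GroundTruth", "make_phantom", "make_amplified_phantom"]

PHANTOM_KINDS = (
    "zero",
    "rigid_rotation",
    "uniaxial_stretch",
    "simple_shear",
    "dilation",
    "pulsatile_composite",
)

DEFAULT_SEED = 20240801

#: atlas-style labels carved into the white-matter core of the phantom
_PHANTOM_ATLAS_IDS = (36, 37, 44, 45, 47, 48, 55, 56, 57, 58, 59, 60)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic displacement field.

    ``amplitude`` is the Eulerian gradient magnitude for the affine kinds
    (dimensionless), the rotation angle in degrees for ``rigid_rotation``,
    and the peak displacement in mm for ``pulsatile_composite``.
    """

    kind: str = "uniaxial_stretch"
    amplitude: float = 0.05
    n_t: int = 1
    shape: tuple[int, int, int] = (16, 16, 16)
    spacing: tuple[float, float, float] = (1.2, 1.2, 1.2)
    seed: int = DEFAULT_SEED
    noise_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}")
        if self.n_t < 1:
            raise ValueError("n_t must be >= 1")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


@dataclass
class GroundTruth:
    """Exact per-voxel, per-frame kinematics and stress of a phantom.

    ``E`` is the conventional Green-Lagrange strain (F^T F - I)/2; the
    no-half variant is exactly ``2 * E``.  ``sigma`` uses the default
    material table on the phantom's tissue shells (NaN outside the brain
    and in the excluded CSF shell).
    """

    gradU: np.ndarray  # (nx,ny,nz,nt,3,3)
    F: np.ndarray
    E: np.ndarray
    J: np.ndarray  # (nx,ny,nz,nt)
    sigma: np.ndarray
    atlas: LabelVolume


def _temporal_modulation(n_t: int) -> np.ndarray:
    """sin^2(pi k / n_t) per frame; [1.0] for a static phantom."""
    if n_t == 1:
        return np.ones(1)
    k = np.arange(n_t)
    return np.sin(np.pi * k / n_t) ** 2


def _tissue_shells(geom: GridGeometry) -> np.ndarray:
    """Concentric ellipsoidal shells: WM core, GM shell, CSF rim, background."""
    nx, ny, nz = geom.shape
    idx = np.indices(geom.shape, dtype=float)
    centre = (np.array(geom.shape) - 1) / 2.0
    semi = np.maximum(np.array(geom.shape) / 2.0, 1.0)
    r = np.sqrt(sum(((idx[a] - centre[a]) / semi[a]) ** 2 for a in range(3)))
    labels = np.zeros(geom.shape, dtype=np.int32)
    labels[r < 0.95] = 1  # CSF rim
    labels[r < 0.80] = 2  # GM shell
    labels[r < 0.55] = 3  # WM core
    return labels


def _carve_atlas(tissue: np.ndarray) -> np.ndarray:
    """Assign small blocks of atlas-style ids inside the WM core."""
    atlas = np.zeros_like(tissue)
    core = np.argwhere(tissue == 3)
    if core.size == 0:
        return atlas
    # split the core voxels into contiguous index runs, one per atlas id
    chunks = np.array_split(np.arange(len(core)), len(_PHANTOM_ATLAS_IDS))
    for aid, chunk in zip(_PHANTOM_ATLAS_IDS, chunks):
        for i in chunk:
            atlas[tuple(core[i])] = aid
    return atlas


def _base_gradient(spec: PhantomSpec) -> np.ndarray | None:
    """Spatially constant base grad U for the affine kinds, else None."""
    a = spec.amplitude
    if spec.kind == "zero":
        return np.zeros((3, 3))
    if spec.kind == "uniaxial_stretch":
        g = np.zeros((3, 3))
        g[0, 0] = a
        return g
    if spec.kind == "simple_shear":
        g = np.zeros((3, 3))
        g[0, 1] = a
        return g
    if spec.kind == "dilation":
        return a * np.eye(3)
    return None  # rigid_rotation, pulsatile_composite handled separately


def _composite_field(coords: np.ndarray, amplitude: float,
                     extent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Smooth trigonometric displacement and its analytic gradient.

    u_x = A sin(ax) cos(by); u_y = A sin(ay) cos(bz); u_z = A sin(az) cos(bx)
    with one wavelength of a and b across the domain extent.
    """
    a = 2.0 * np.pi / extent  # per-axis wavenumbers (3,)
    b = a / 2.0
    x, y, z = coords[..., 0], coords[..., 1], coords[..., 2]
    A = amplitude
    u = np.stack(
        [
            A * np.sin(a[0] * x) * np.cos(b[1] * y),
            A * np.sin(a[1] * y) * np.cos(b[2] * z),
            A * np.sin(a[2] * z) * np.cos(b[0] * x),
        ],
        axis=-1,
    )
    g = np.zeros(coords.shape[:-1] + (3, 3))
    g[..., 0, 0] = A * a[0] * np.cos(a[0] * x) * np.cos(b[1] * y)
    g[..., 0, 1] = -A * b[1] * np.sin(a[0] * x) * np.sin(b[1] * y)
    g[..., 1, 1] = A * a[1] * np.cos(a[1] * y) * np.cos(b[2] * z)
    g[..., 1, 2] = -A * b[2] * np.sin(a[1] * y) * np.sin(b[2] * z)
    g[..., 2, 2] = A * a[2] * np.cos(a[2] * z) * np.cos(b[0] * x)
    g[..., 2, 0] = -A * b[0] * np.sin(a[2] * z) * np.sin(b[0] * x)
    return u, g


def make_phantom(
    spec: PhantomSpec,
    material: MaterialTable | None = None,
) -> tuple[DisplacementField, LabelVolume, GroundTruth]:
    """Generate a phantom displacement field, tissue labels, and ground truth.

    Raises if the requested amplitude would drive J <= 0 anywhere.
    """
    material = material or MaterialTable()
    geom = GridGeometry.axis_aligned(spec.shape, spec.spacing, frames=spec.n_t)
    coords = geom.world_coordinates()
    centre = coords.reshape(-1, 3).mean(axis=0)
    rel = coords - centre
    mod = _temporal_modulation(spec.n_t)

    nx, ny, nz = spec.shape
    u = np.zeros((nx, ny, nz, spec.n_t, 3))
    gradU = np.zeros((nx, ny, nz, spec.n_t, 3, 3))

    base = _base_gradient(spec)
    if base is not None:
        for t, m in enumerate(mod):
            u[:, :, :, t, :] = rel @ (m * base).T
            gradU[:, :, :, t, :, :] = m * base
    elif spec.kind == "rigid_rotation":
        theta0 = np.deg2rad(spec.amplitude)
        for t, m in enumerate(mod):
            th = m * theta0
            c, s = np.cos(th), np.sin(th)
            R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            u[:, :, :, t, :] = rel @ (np.eye(3) - R.T).T
            gradU[:, :, :, t, :, :] = np.eye(3) - R.T
    else:  # pulsatile_composite
        extent = np.asarray(spec.shape, float) * np.asarray(spec.spacing, float)
        u0, g0 = _composite_field(rel, spec.amplitude, extent)
        for t, m in enumerate(mod):
            u[:, :, :, t, :] = m * u0
            gradU[:, :, :, t, :, :] = m * g0
        if spec.noise_amplitude > 0:
            rng = np.random.default_rng(spec.seed)
            u += spec.noise_amplitude * rng.standard_normal(u.shape)

    A = np.eye(3) - gradU
    detA = np.linalg.det(A)
    if np.min(detA) <= 0.0:
        raise ValueError(
            f"amplitude {spec.amplitude} drives J <= 0 (min det(I - gradU) = {detA.min():.3g})"
        )
    F = np.linalg.inv(A)
    J = np.linalg.det(F)
    E = 0.5 * (np.swapaxes(F, -1, -2) @ F - np.eye(3))

    tissue = _tissue_shells(geom)
    labels = LabelVolume(tissue, geom.with_frames(1), dict(DEFAULT_TISSUE_LOOKUP))
    atlas_labels = _carve_atlas(tissue)
    atlas_lut: dict[int, LabelEntry] = {0: LabelEntry("background", TissueClass.BACKGROUND)}
    from .regions import atlas_lookup

    full = atlas_lookup()
    for aid in _PHANTOM_ATLAS_IDS:
        atlas_lut[aid] = full[aid]
    atlas = LabelVolume(atlas_labels, geom.with_frames(1), atlas_lut)

    G, K = _moduli_maps(labels, material)
    sigma = mooney_rivlin_cauchy_stress(F, G[..., None], K[..., None])

    field = DisplacementField(u, geom)
    return field, labels, GroundTruth(gradU, F, E, J, sigma, atlas)


def make_amplified_phantom(
    spec: PhantomSpec, amplification: float
) -> DisplacementField:
    """Phantom displacements multiplied by an amplification factor.

    Emulates amplified-MRI output prior to downscaling: brain motion
    exaggerated by up to ~25x.  Requires ``amplification >= 1``.
    """
    if amplification < 1:
        raise ValueError("amplification must be >= 1")
    field, _, _ = make_phantom(spec)
    return dataclasses.replace(field, data=field.data * amplification)
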