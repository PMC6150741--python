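"""Synthetic tumor-phantom generator for test-retest studies.

Stands in for paired T2-weighted MR acquisitions of a segmented tumor on two
consecutive days.  A phantom is a stationary correlated Gaussian random field
(white noise convolved with a Gaussian kernel of width ``correlation_length``,
affinely rescaled to a target mean/SD) inside an ellipsoidal mask whose
boundary is radially perturbed for realism.  The default geometry mirrors a
pelvic T2 axial acquisition: 96 x 96 x 10 voxels at 0.68 x 0.68 mm in-plane
and 7.8 mm through-plane pitch (6 mm section + 1.8 mm gap).

Test-retest model
-----------------
Day 1 and day 2 share the base field; each day ``d`` observes

    x_d(v) = base(v) * (1 + gamma_d + eta_d(b(v)))

with ``gamma_d ~ N(0, noise_cv)`` a per-study multiplicative gain and
``eta_d ~ N(0, noise_cv)`` drawn independently per in-plane block of side
~``correlation_length``.  The study-level gain makes ``noise_cv`` the true
within-subject CV of intensity-scale summary features; the block term
perturbs spatial texture coarsely enough to survive 32-bin quantization
(per-voxel noise would be absorbed by it).  ROI re-delineation is emulated by
per-slice morphological dilation/erosion of the day-2 mask (``mask_jitter``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .io import append_manifest_row, write_mask, write_study
from .volume import ImageVolume, RoiMask


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture of one synthetic tumor phantom.

    ``shape`` is voxels per axis ``(nx, ny, nz)`` and ``voxel_size`` is mm per
    axis ``(dx, dy, dz)`` — note this user-facing order is the reverse of the
    internal ``(z, y, x)`` array convention. ``tumor_axes`` are the mm
    semi-axes of the ellipsoidal mask; ``boundary_irregularity`` scales a
    smooth random radial perturbation of the tumor border.
    """

    shape: tuple[int, int, int] = (96, 96, 10)
    voxel_size: tuple[float, float, float] = (0.68, 0.68, 7.8)
    correlation_length: float = 5.0
    intensity_mean: float = 300.0
    intensity_sd: float = 60.0
    tumor_axes: tuple[float, float, float] = (20.0, 20.0, 20.0)
    boundary_irregularity: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.shape):
            raise GeometryError(f"shape must be positive, got {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError(f"voxel_size must be positive, got {self.voxel_size}")
        if any(a <= 0 for a in self.tumor_axes):
            raise GeometryError(f"tumor_axes must be positive, got {self.tumor_axes}")
        if self.correlation_length < 0 or self.intensity_sd < 0:
            raise GeometryError("correlation_length and intensity_sd must be >= 0")
        # tumor (with perturbation headroom) must fit inside the grid
        margin = 1.0 + 2.0 * max(self.boundary_irregularity, 0.0)
        for n, d, a in zip(self.shape, self.voxel_size, self.tumor_axes):
            if a * margin / d > (n - 1) / 2:
                raise GeometryError(
                    f"tumor semi-axis {a} mm does not fit in {n} voxels of {d} mm"
                )


@dataclass(frozen=True)
class RetestSpec:
    """Within-subject day-to-day perturbation.

    ``noise_cv`` is the true multiplicative within-subject coefficient of
    variation between the two studies; ``mask_jitter`` is the per-slice
    morphological perturbation radius (voxels) emulating re-delineation.
    """

    noise_cv: float = 0.10
    mask_jitter: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.mask_jitter < 0:
            raise ValueError(f"mask_jitter must be >= 0, got {self.mask_jitter}")


def _correlated_field(rng: np.random.Generator, shape_zyx, sigma_vox) -> np.ndarray:
    field = rng.standard_normal(shape_zyx)
    if any(s > 0 for s in sigma_vox):
        field = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="wrap")
    sd = field.std()
    if sd > 0:
        field = (field - field.mean()) / sd
    return field


def _ellipsoid_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.voxel_size
    ax, ay, az = spec.tumor_axes
    z, y, x = np.meshgrid(
        (np.arange(nz) - (nz - 1) / 2) * dz,
        (np.arange(ny) - (ny - 1) / 2) * dy,
        (np.arange(nx) - (nx - 1) / 2) * dx,
        indexing="ij",
    )
    rho = np.sqrt((x / ax) ** 2 + (y / ay) ** 2 + (z / az) ** 2)
    radius = np.ones_like(rho)
    if spec.boundary_irregularity > 0:
        sigma_inplane = max(2.0, 0.25 * ax / dx)
        pert = _correlated_field(rng, rho.shape, (1.0, sigma_inplane, sigma_inplane))
        radius = radius + spec.boundary_irregularity * pert
    mask = rho <= radius
    if not mask.any():  # pragma: no cover - guarded by validate()
        raise GeometryError("perturbed tumor mask is empty")
    # keep the largest connected component so the tumor stays a single body
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, RoiMask]:
    """Generate one tumor phantom: correlated-field intensities + ellipsoid mask.

    Deterministic given ``spec.seed``: the same spec always yields
    bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.voxel_size
    shape_zyx = (nz, ny, nx)
    sigma = (
        spec.correlation_length / dz,
        spec.correlation_length / dy,
        spec.correlation_length / dx,
    )
    field = _correlated_field(rng, shape_zyx, sigma)
    data = spec.intensity_mean + spec.intensity_sd * field
    mask = _ellipsoid_mask(spec, rng)
    voxel_size_zyx = (dz, dy, dx)
    return ImageVolume(data, voxel_size_zyx), RoiMask(mask)


def _block_noise(
    rng: np.random.Generator, shape_zyx, block_side: int, sd: float
) -> np.ndarray:
    """Per-block multiplicative deviations, one i.i.d. draw per in-plane block."""
    nz, ny, nx = shape_zyx
    nby = -(-ny // block_side)
    nbx = -(-nx // block_side)
    eta = rng.normal(0.0, sd, size=(nz, nby, nbx))
    eta = np.repeat(np.repeat(eta, block_side, axis=1), block_side, axis=2)
    return eta[:, :ny, :nx]


def _jitter_mask(mask: np.ndarray, jitter: int, rng: np.random.Generator) -> np.ndarray:
    """Random per-slice dilation/erosion of radius <= ``jitter`` voxels."""
    out = mask.copy()
    for k in range(mask.shape[0]):
        if not mask[k].any():
            continue
        r = int(rng.integers(-jitter, jitter + 1))
        if r == 0:
            continue
        if r > 0:
            out[k] = ndimage.binary_dilation(mask[k], iterations=r)
        else:
            eroded = ndimage.binary_erosion(mask[k], iterations=-r)
            if eroded.any():  # never let re-delineation delete a slice entirely
                out[k] = eroded
    return out


def generate_retest_pair(
    spec: PhantomSpec, retest: RetestSpec
) -> tuple[tuple[ImageVolume, RoiMask], tuple[ImageVolume, RoiMask]]:
    """Generate a day-1/day-2 study pair around a shared base phantom.

    Each day receives an independent multiplicative perturbation (study-level
    gain + block-level texture noise, both with SD ``noise_cv``); the day-2
    mask is additionally jittered by per-slice morphology. With
    ``noise_cv=0`` and ``mask_jitter=0`` the two studies are identical.
    """
    spec.validate()
    retest.validate()
    base_vol, base_mask = generate_phantom(spec)
    rng = np.random.default_rng(retest.seed)
    dz, dy, dx = base_vol.voxel_size
    block = max(1, int(round(spec.correlation_length / dx))) if spec.correlation_length > 0 else 1

    def perturbed() -> ImageVolume:
        gamma = rng.normal(0.0, retest.noise_cv)
        eta = _block_noise(rng, base_vol.shape, block, retest.noise_cv)
        return ImageVolume(base_vol.data * (1.0 + gamma + eta), base_vol.voxel_size)

    day1_vol = perturbed()
    day2_vol = perturbed()
    day1_mask = RoiMask(base_mask.data.copy())
    if retest.mask_jitter > 0:
        day2_mask = RoiMask(_jitter_mask(base_mask.data, int(retest.mask_jitter), rng))
    else:
        day2_mask = RoiMask(base_mask.data.copy())
    return (day1_vol, day1_mask), (day2_vol, day2_mask)


def subject_specs(
    base: PhantomSpec, n_subjects: int, seed: int, heterogeneity: float = 0.2
) -> list[PhantomSpec]:
    """Derive per-subject phantom specs with realistic between-subject spread.

    Tumor size, texture correlation length and mean signal each vary uniformly
    by ±``heterogeneity`` (±10% for mean signal) around the base spec.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_subjects):
        s = rng.uniform(1 - heterogeneity, 1 + heterogeneity)
        cl = rng.uniform(1 - heterogeneity, 1 + heterogeneity)
        mu = rng.uniform(0.9, 1.1)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        specs.append(
            dataclasses.replace(
                base,
                tumor_axes=tuple(a * s for a in base.tumor_axes),
                correlation_length=base.correlation_length * cl,
                intensity_mean=base.intensity_mean * mu,
                seed=sub_seed,
            )
        )
    return specs


def simulate_cohort(
    n_subjects: int,
    out_dir: str | Path,
    *,
    seed: int = 0,
    noise_cv: float = 0.10,
    mask_jitter: int = 0,
    n_readers: int = 1,
    base_spec: PhantomSpec | None = None,
) -> Path:
    """Simulate a paired cohort to disk; returns the manifest path.

    Writes one volume per subject-day plus one mask per subject-day-reader
    (readers beyond the first re-delineate via independent 1-voxel jitter),
    and a manifest CSV with one row per (subject, day, reader).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    if manifest.exists():
        manifest.unlink()
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    specs = subject_specs(base, n_subjects, seed=int(rng.integers(0, 2**31 - 1)))
    for i, spec in enumerate(specs, start=1):
        subject = f"sub{i:03d}"
        retest = RetestSpec(
            noise_cv=noise_cv,
            mask_jitter=mask_jitter,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        (v1, m1), (v2, m2) = generate_retest_pair(spec, retest)
        for day, vol, mask in ((1, v1, m1), (2, v2, m2)):
            stem = out_dir / f"{subject}_day{day}"
            vol_path, mask_path = write_study(vol, mask, stem)
            append_manifest_row(manifest, subject, day, vol_path, mask_path, reader_id=1)
            for reader in range(2, n_readers + 1):
                jrng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
                rmask = RoiMask(_jitter_mask(mask.data, 1, jrng))
                rpath = out_dir / f"{subject}_day{day}_reader{reader}_mask.nii.gz"
                write_mask(rmask, rpath, vol.voxel_size)
                append_manifest_row(
                    manifest, subject, day, vol_path, str(rpath), reader_id=reader
                )
    return manifest


def simulate_cohort_memory(
    n_subjects: int,
    *,
    seed: int = 0,
    noise_cv: float = 0.10,
    mask_jitter: int = 0,
    base_spec: PhantomSpec | None = None,
):
    """In-memory cohort generator: yields (subject_id, (v1, m1), (v2, m2))."""
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    specs = subject_specs(base, n_subjects, seed=int(rng.integers(0, 2**31 - 1)))
    for i, spec in enumerate(specs, start=1):
        retest = RetestSpec(
            noise_cv=noise_cv,
            mask_jitter=mask_jitter,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        day1, day2 = generate_retest_pair(spec, retest)
        yield f"sub{i:03d}", day1, day2
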