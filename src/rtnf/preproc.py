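"""Online volume-by-volume preprocessing.

Mirrors the real-time stage of an fMRI neurofeedback system: each incoming
volume is (1) rigid-body realigned to the training run's mean functional
image, (2) smoothed with an 8-mm FWHM Gaussian, and (3) restricted to a brain
mask before being fed to the classifier.  All three steps are stateless given
the reference ``(MeanImage, BrainMask)`` pair, so volumes can be processed in
any order with identical results.

Rigid-body convention
---------------------
A :class:`RigidTransform` holds 3 translations (mm) and 3 rotations (rad).
In world (mm) coordinates the mapping is ``y = R (x - c) + c + t`` where
``R = Rz(rz) @ Ry(ry) @ Rx(rx)`` (rotations applied about x, then y, then z)
and ``c`` is the rotation centre — the intensity centre of mass of the
reference volume.  Realignment reports the *correction* applied to the moving
volume: the transform that, applied to the moving image, best matches the
reference in a least-squares sense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import GridMismatchError, MaskError

__all__ = [
    "Volume",
    "RigidTransform",
    "apply_rigid",
    "realign",
    "smooth",
    "make_mask",
    "realign_series_two_pass",
    "OnlinePreprocessor",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume:
    """One 3D image: voxel array, grid-to-world affine (mm), acquisition index."""

    data: np.ndarray
    affine: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def voxel_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def default_affine(voxel_mm) -> np.ndarray:
    """RAS+ affine with the given voxel size and origin at the grid origin."""
    a = np.eye(4)
    a[0, 0], a[1, 1], a[2, 2] = voxel_mm
    return a


@dataclass(frozen=True)
class RigidTransform:
    """Six-parameter rigid-body transform: translations mm, rotations rad."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    @property
    def translation(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])

    @property
    def rotation(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz])

    def as_params(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @classmethod
    def from_params(cls, p) -> "RigidTransform":
        return cls(*[float(v) for v in p])

    def rotation_matrix(self) -> np.ndarray:
        # extrinsic x-y-z == Rz @ Ry @ Rx
        return Rotation.from_euler("xyz", [self.rx, self.ry, self.rz]).as_matrix()

    def matrix(self, center_mm) -> np.ndarray:
        """Homogeneous 4x4 world-coordinate matrix for y = R(x-c)+c+t."""
        c = np.asarray(center_mm, dtype=float)
        R = self.rotation_matrix()
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c + self.translation - R @ c
        return m

    def inverse(self) -> "RigidTransform":
        """Parameters of the inverse transform (same rotation centre)."""
        R = self.rotation_matrix()
        rx, ry, rz = Rotation.from_matrix(R.T).as_euler("xyz")
        t_inv = -R.T @ self.translation
        return RigidTransform(*t_inv, rx, ry, rz)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first), about a shared centre 0."""
        R = self.rotation_matrix() @ other.rotation_matrix()
        rx, ry, rz = Rotation.from_matrix(R).as_euler("xyz")
        t = self.rotation_matrix() @ other.translation + self.translation
        return RigidTransform(*t, rx, ry, rz)


def center_of_mass_mm(data: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Intensity centre of mass in world (mm) coordinates."""
    d = np.clip(np.asarray(data, dtype=float), 0, None)
    tot = d.sum()
    if tot <= 0:
        com_vox = (np.array(d.shape) - 1) / 2.0
    else:
        com_vox = np.array(ndimage.center_of_mass(d))
    return affine[:3, :3] @ com_vox + affine[:3, 3]


def apply_rigid(
    data: np.ndarray,
    transform: RigidTransform,
    affine: np.ndarray,
    center_mm=None,
    cval: float = 0.0,
    order: int = 1,
) -> np.ndarray:
    """Resample ``data`` so the image content is moved by ``transform``.

    Trilinear interpolation by default; voxels sampled outside the grid are
    filled with the background value ``cval``.
    """
    affine = np.asarray(affine, dtype=float)
    if center_mm is None:
        center_mm = affine[:3, :3] @ ((np.array(data.shape) - 1) / 2.0) + affine[:3, 3]
    t_inv = np.eye(4)
    R = transform.rotation_matrix()
    t_inv[:3, :3] = R.T
    c = np.asarray(center_mm, dtype=float)
    t_inv[:3, 3] = c - R.T @ (c + transform.translation)
    vox2vox = np.linalg.inv(affine) @ t_inv @ affine
    return ndimage.affine_transform(
        data, vox2vox[:3, :3], offset=vox2vox[:3, 3], order=order, mode="constant", cval=cval
    )


# ---------------------------------------------------------------------------
# realignment
# ---------------------------------------------------------------------------

def _downsample(data: np.ndarray) -> np.ndarray:
    return ndimage.zoom(data, 0.5, order=1, mode="nearest", grid_mode=True)


def realign(
    moving: np.ndarray,
    reference: np.ndarray,
    affine: np.ndarray,
    max_iter: int = 32,
    tol: float = 1e-6,
    presmooth_vox: float = 1.0,
) -> tuple[RigidTransform, np.ndarray, bool]:
    """Estimate the rigid correction aligning ``moving`` to ``reference``.

    Two-level multi-resolution least squares on the mean squared intensity
    difference, solved with a trust-region Gauss-Newton (finite-difference
    Jacobian).  The rotation centre is the reference's intensity centre of
    mass; rotation order is Z-Y-X (see module docstring).

    Returns
    -------
    (transform, resampled, converged)
        ``transform`` is the correction applied to the moving volume;
        ``resampled`` is the moving volume after applying it (trilinear).
        If the optimiser did not converge a warning is emitted and the
        best-so-far result is returned with ``converged=False``.
    """
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise GridMismatchError(f"grids differ: {moving.shape} vs {reference.shape}")
    if reference.std() == 0:
        raise ValueError("reference volume has zero variance")
    affine = np.asarray(affine, dtype=float)
    center = center_of_mass_mm(reference, affine)

    mov_s = ndimage.gaussian_filter(moving, presmooth_vox) if presmooth_vox else moving
    ref_s = ndimage.gaussian_filter(reference, presmooth_vox) if presmooth_vox else reference

    levels = []
    if min(moving.shape) >= 16:
        aff2 = affine.copy()
        aff2[:3, :3] *= 2.0
        levels.append((_downsample(mov_s), _downsample(ref_s), aff2))
    levels.append((mov_s, ref_s, affine))

    # translation warm start: move the intensity centre of mass onto the
    # reference's, which puts large displacements inside the capture range
    p = np.zeros(6)
    p[:3] = center - center_of_mass_mm(moving, affine)
    converged = True
    for mov_l, ref_l, aff_l in levels:
        scale = np.sqrt(mov_l.size)

        def residual(params, mov=mov_l, ref=ref_l, aff=aff_l, s=scale):
            # cubic interpolation in the cost: trilinear resampling loses
            # high-frequency power, which biases sub-voxel estimates toward 0
            res = apply_rigid(
                mov, RigidTransform.from_params(params), aff, center_mm=center, order=3
            )
            return (res - ref).ravel() / s

        sol = least_squares(
            residual,
            p,
            method="trf",
            diff_step=[5e-2, 5e-2, 5e-2, 2e-3, 2e-3, 2e-3],
            xtol=tol,
            ftol=tol,
            gtol=None,
            max_nfev=max_iter * 8,
        )
        p = sol.x
        if sol.status == 0:
            converged = False
    if not converged:
        warnings.warn("realignment did not converge; returning best-so-far estimate")
    transform = RigidTransform.from_params(p)
    resampled = apply_rigid(moving, transform, affine, center_mm=center)
    return transform, resampled, converged


def realign_series_two_pass(
    series: np.ndarray, affine: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[RigidTransform]]:
    """Training-run realignment relative to the run's own mean image.

    Pass 1 realigns every volume to volume 0 and forms a mean; pass 2
    realigns every volume to that mean.  Returns (mean of realigned volumes,
    realigned 4D series, per-volume transforms from pass 2).
    """
    n = series.shape[-1]
    pass1 = np.empty_like(series)
    pass1[..., 0] = series[..., 0]
    for t in range(1, n):
        _, pass1[..., t], _ = realign(series[..., t], series[..., 0], affine)
    mean1 = pass1.mean(axis=-1)
    out = np.empty_like(series)
    transforms: list[RigidTransform] = []
    for t in range(n):
        tr, out[..., t], _ = realign(series[..., t], mean1, affine)
        transforms.append(tr)
    return out.mean(axis=-1), out, transforms


def motion_params_table(transforms: list[RigidTransform]) -> np.ndarray:
    """(n, 6) array: tx ty tz (mm), rx ry rz (rad) — one row per volume."""
    return np.array([t.as_params() for t in transforms])


def write_motion_params(transforms: list[RigidTransform], path) -> None:
    np.savetxt(path, motion_params_table(transforms), fmt="%.8f")


# ---------------------------------------------------------------------------
# smoothing and masking
# ---------------------------------------------------------------------------

def smooth(data: np.ndarray, fwhm_mm: float, voxel_mm) -> np.ndarray:
    """Separable 3D Gaussian smoothing, sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    The boundary uses a renormalised truncated kernel (zero-padded
    convolution divided by the smoothed indicator of the grid), so a
    constant image is preserved exactly.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be > 0")
    voxel_mm = np.asarray(voxel_mm, dtype=float)
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    num = ndimage.gaussian_filter(np.asarray(data, dtype=float), sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(np.ones(data.shape), sigma_vox, mode="constant")
    return num / den


def make_mask(mean: np.ndarray, frac: float = 0.5) -> np.ndarray:
    """Brain mask: threshold at ``frac`` x robust maximum, keep largest blob.

    The robust maximum is the 99th percentile of the mean image; clusters are
    26-connected.  Raises :class:`MaskError` if the mask comes out empty.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must lie in (0, 1)")
    mean = np.asarray(mean, dtype=float)
    robust_max = np.percentile(mean, 99)
    if robust_max <= 0:
        raise MaskError("mean image has non-positive robust maximum")
    binary = mean >= frac * robust_max
    if not binary.any():
        raise MaskError("empty brain mask")
    labeled, n = ndimage.label(binary, structure=np.ones((3, 3, 3)))
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    return labeled == (int(np.argmax(sizes)) + 1)


@dataclass
class OnlinePreprocessor:
    """Stateless per-volume pipeline: realign to mean -> smooth -> (mask).

    Holds the reference mean image, its affine, the brain mask and the
    smoothing FWHM; :meth:`process` handles one incoming volume.
    """

    mean: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    fwhm_mm: float = 8.0
    do_realign: bool = True
    _voxel_mm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.mask.shape != self.mean.shape:
            raise GridMismatchError("mask grid differs from mean image grid")
        self._voxel_mm = np.sqrt((np.asarray(self.affine)[:3, :3] ** 2).sum(axis=0))

    def process(self, data: np.ndarray) -> tuple[RigidTransform, np.ndarray]:
        """Returns (motion estimate, realigned+smoothed volume)."""
        if data.shape != self.mean.shape:
            raise GridMismatchError("incoming volume grid differs from reference")
        if self.do_realign:
            transform, resampled, _ = realign(data, self.mean, self.affine)
        else:
            transform, resampled = RigidTransform(), np.asarray(data, dtype=float)
        return transform, smooth(resampled, self.fwhm_mm, self._voxel_mm)

    def process_series(
        self, series: np.ndarray
    ) -> tuple[list[RigidTransform], np.ndarray]:
        transforms = []
        out = np.empty_like(series, dtype=float)
        for t in range(series.shape[-1]):
            tr, out[..., t] = self.process(series[..., t])
            transforms.append(tr)
        return transforms, out
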