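"""Synthetic 4D BOLD phantom with known ground truth.

Generates block-design BOLD runs that emulate the study's acquisition
(64 x 64 x 37 grid at 3 mm isotropic, TR = 2 s, 255 volumes) so the whole
closed loop — preprocessing, decoding, feedback, GLM — is testable without
real data.  The voxel model is

    y_v(t) = baseline * (1 + sum_c a_c/100 * (boxcar_c (x) HRF)(t) * P_c(v))
             + drift(t) + AR(1) noise,            v inside the brain,
    y_v(t) = 0                                    outside,

where ``P_c`` is condition c's spatial pattern (per-voxel weights), ``a_c`` its
amplitude in percent of baseline, and the HRF is the canonical double-gamma.
The brain is an axis-aligned ellipsoid; optional rigid-body motion is
injected by trilinear resampling of each volume.

Left- and right-hand motor-imagery patterns deliberately overlap in a
midline cluster and differ only in their lateralised clusters, so they are
distinguishable by their multivoxel configuration rather than by overall
amplitude — the regime multivoxel pattern analysis targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import InvalidSpecError
from .paradigm import Condition, Paradigm, default_paradigm
from .preproc import RigidTransform, apply_rigid, default_affine

__all__ = [
    "PatternSpec",
    "PhantomSpec",
    "GroundTruth",
    "canonical_hrf",
    "simulate_run",
    "brain_ellipsoid",
    "default_patterns",
]


def canonical_hrf(tr_s: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at ``tr_s``.

    Response gamma peaks at 6 s, undershoot gamma at 16 s, undershoot ratio
    1/6, 32-s support; the sampled kernel's peak is normalised to 1.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be > 0")
    t = np.arange(0.0, duration_s + 1e-9, tr_s)
    # gamma pdf with shape k, scale 1 peaks at k - 1; shapes 6 and 16 put the
    # peaks at ~5 s and ~15 s, the standard convention for "peak 6 s" kernels
    h = stats.gamma.pdf(t, 6) - stats.gamma.pdf(t, 16) / 6.0
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF sampling")
    return h / peak


@dataclass(frozen=True)
class PatternSpec:
    """Spatial activation pattern: spherical clusters + amplitude (% baseline).

    ``clusters`` is a list of ``(center_voxel, radius_voxels)`` or
    ``(center_voxel, radius_voxels, weight)`` tuples; the pattern value is
    the maximum cluster weight at each voxel (1.0 where no weight is given),
    so the effective local amplitude is ``amplitude * weight``.  Patterns of
    different conditions may overlap.
    """

    amplitude: float
    clusters: tuple = ()

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise InvalidSpecError("pattern amplitude must be >= 0")

    def values(self, grid) -> np.ndarray:
        """Per-voxel pattern weights (0 outside every cluster)."""
        out = np.zeros(grid)
        idx = np.indices(grid)
        for cluster in self.clusters:
            center, radius = cluster[0], cluster[1]
            weight = cluster[2] if len(cluster) > 2 else 1.0
            c = np.asarray(center, dtype=float)
            d2 = sum((idx[k] - c[k]) ** 2 for k in range(3))
            out = np.maximum(out, np.where(d2 <= radius**2, weight, 0.0))
        if not (out > 0).any():
            raise InvalidSpecError("pattern voxel set is empty on this grid")
        return out

    def mask(self, grid) -> np.ndarray:
        return self.values(grid) > 0


def brain_ellipsoid(grid, semi_frac: float = 0.42) -> np.ndarray:
    """Axis-aligned ellipsoid 'brain' centred in the grid."""
    grid = tuple(grid)
    idx = np.indices(grid)
    center = (np.array(grid) - 1) / 2.0
    semi = semi_frac * np.array(grid)
    d2 = sum(((idx[k] - center[k]) / semi[k]) ** 2 for k in range(3))
    return d2 <= 1.0


def default_patterns(
    grid, amplitude: float = 1.0, lateral_weight: float = 0.35
) -> dict[Condition, PatternSpec]:
    """Overlapping left/right motor-imagery patterns scaled to the grid.

    Each condition activates a shared midline cluster (bilateral
    sensorimotor analogue, full amplitude) plus one lateralised
    contralateral cluster carrying ``lateral_weight`` times the amplitude.
    The two task patterns therefore overlap and differ only in their
    multivoxel configuration; shrinking ``lateral_weight`` makes the tasks
    harder to tell apart while leaving task-vs-rest contrast intact.
    """
    nx, ny, nz = grid
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    r = max(1.5, 0.06 * min(nx, ny))
    off = 0.22 * nx
    left = (cx - off, cy + 0.08 * ny, cz + 0.15 * nz)
    right = (cx + off, cy + 0.08 * ny, cz + 0.15 * nz)
    mid = (cx, cy - 0.05 * ny, cz + 0.2 * nz)
    w = lateral_weight
    return {
        # imagined left-hand movement -> right-hemisphere cluster, and vice versa
        Condition.LGO: PatternSpec(amplitude, ((right, r, w), (mid, 1.3 * r, 1.0))),
        Condition.RGO: PatternSpec(amplitude, ((left, r, w), (mid, 1.3 * r, 1.0))),
    }


@dataclass
class PhantomSpec:
    """Everything needed to generate one synthetic run.

    Defaults reproduce the study's acquisition geometry and timing; tests
    may use smaller grids.  ``noise_sd`` is the stationary AR(1) noise SD in
    signal units (baseline = 100 => 1.0 is 1% of baseline).  ``drift`` maps
    basis names to coefficient lists: ``{"poly": [c1, c2, ...]}`` adds
    ``sum_k c_k (t/T)^k`` and ``{"cosine": [d1, ...]}`` adds
    ``sum_k d_k cos(pi k t / T)`` (signal units, T = n_volumes - 1).
    """

    grid: tuple = (64, 64, 37)
    voxel_mm: tuple = (3.0, 3.0, 3.0)
    paradigm: Paradigm = field(default_factory=default_paradigm)
    baseline: float = 100.0
    patterns: dict = None
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift: dict = field(default_factory=lambda: {"poly": [1.0], "cosine": [0.5]})
    motion: list | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.grid):
            raise InvalidSpecError("grid dimensions must be positive")
        if self.baseline <= 0:
            raise InvalidSpecError("baseline must be > 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if not 0 <= self.ar1_rho < 1:
            raise InvalidSpecError("ar1_rho must lie in [0, 1)")
        if self.patterns is None:
            self.patterns = default_patterns(self.grid)
        task_conditions = {
            c for c in np.unique(self.paradigm.labels) if c is not Condition.REST
        }
        missing = task_conditions - set(self.patterns)
        if missing:
            raise InvalidSpecError(f"patterns missing for conditions: {missing}")
        if self.motion is not None and len(self.motion) != self.paradigm.n_volumes:
            raise InvalidSpecError("motion list length must equal n_volumes")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_mm)


@dataclass
class GroundTruth:
    """Sidecar truth for a simulated run (same seed => bit-identical run)."""

    pattern_values: dict      # condition -> per-voxel pattern weights
    brain_mask: np.ndarray
    regressors: dict          # condition -> boxcar (x) HRF, per volume
    noiseless: np.ndarray     # (..., n_volumes) signal before noise/motion
    drift: np.ndarray
    motion: list | None
    labels: np.ndarray
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": int(self.seed),
            "labels": [str(c) for c in self.labels],
            "drift": self.drift.tolist(),
            "regressors": {str(k): v.tolist() for k, v in self.regressors.items()},
            "pattern_voxel_counts": {
                str(k): int((v > 0).sum()) for k, v in self.pattern_values.items()
            },
            "brain_voxel_count": int(self.brain_mask.sum()),
            "motion": None
            if self.motion is None
            else [m.as_params().tolist() for m in self.motion],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _drift_timecourse(drift: dict | None, n: int) -> np.ndarray:
    out = np.zeros(n)
    if not drift:
        return out
    t = np.arange(n) / max(n - 1, 1)
    for k, c in enumerate(drift.get("poly", ()), start=1):
        out += c * t**k
    for k, c in enumerate(drift.get("cosine", ()), start=1):
        out += c * np.cos(np.pi * k * t)
    return out


def _ar1_noise(rng: np.random.Generator, shape, n: int, sd: float, rho: float) -> np.ndarray:
    """AR(1) innovations scaled so the stationary SD equals ``sd``."""
    w = rng.standard_normal(shape + (n,))
    if rho == 0:
        return sd * w
    e = np.empty_like(w)
    e[..., 0] = w[..., 0]
    innov = np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        e[..., t] = rho * e[..., t - 1] + innov * w[..., t]
    return sd * e


def simulate_run(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Generate one 4D run (nx, ny, nz, n_volumes) plus its ground truth."""
    grid = tuple(spec.grid)
    n = spec.paradigm.n_volumes
    brain = brain_ellipsoid(grid)
    hrf = canonical_hrf(spec.paradigm.tr_s)

    pattern_values: dict[Condition, np.ndarray] = {}
    regressors: dict[Condition, np.ndarray] = {}
    for cond, pat in spec.patterns.items():
        vals = pat.values(grid)
        if ((vals > 0) & ~brain).any():
            raise InvalidSpecError(f"pattern for {cond} extends outside the brain region")
        pattern_values[cond] = vals
        regressors[cond] = np.convolve(spec.paradigm.boxcar(cond), hrf)[:n]

    drift = _drift_timecourse(spec.drift, n)

    gain = np.ones(grid + (n,))
    for cond, pat in spec.patterns.items():
        vals = pattern_values[cond]
        in_pat = vals > 0
        gain[in_pat] += (pat.amplitude / 100.0) * np.outer(
            vals[in_pat], regressors[cond]
        )
    noiseless = np.zeros(grid + (n,))
    noiseless[brain] = spec.baseline * gain[brain] + drift[None, :]
    del gain

    data = noiseless.copy()
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        nb = int(brain.sum())
        data[brain] += _ar1_noise(rng, (nb,), n, spec.noise_sd, spec.ar1_rho)

    if spec.motion is not None:
        affine = spec.affine
        for t, m in enumerate(spec.motion):
            if not isinstance(m, RigidTransform):
                m = RigidTransform.from_params(m)
            data[..., t] = apply_rigid(data[..., t], m, affine, cval=0.0)

    truth = GroundTruth(
        pattern_values=pattern_values,
        brain_mask=brain,
        regressors=regressors,
        noiseless=noiseless,
        drift=drift,
        motion=spec.motion,
        labels=spec.paradigm.labels.copy(),
        seed=spec.seed,
    )
    return data, truth


def write_run_nifti(data: np.ndarray, spec: PhantomSpec, path: str | Path) -> None:
    """Write a simulated run as NIfTI-1 with an RAS+ affine."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), spec.affine)
    img.header.set_zooms(tuple(spec.voxel_mm) + (spec.paradigm.tr_s,))
    nib.save(img, str(path))
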