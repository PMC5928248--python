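"""Offline evaluation: voxelwise GLM, contrast t-maps, cluster inference,
and decoding performance metrics.

The activation model is the standard mass-univariate GLM: each task
condition enters as its block boxcar convolved with the canonical
double-gamma HRF, the six realignment parameters enter as motion nuisance
regressors, and an intercept (plus optional polynomial drift terms)
completes the design.  Per-voxel OLS yields effect sizes and t-statistics.

Cluster-level inference is a sign-flip permutation test on the maximum
supra-threshold cluster size (26-connectivity): residual time courses are
sign-flipped with one shared sign per time point — preserving the spatial
correlation structure each permutation — the model is refit, and the
observed cluster sizes are referred to the permutation null of the maximum
cluster size.  This replaces random-field-theory family-wise-error cluster
correction, which needs smoothness estimation machinery; the permutation
test is exact under exchangeability and is validated by simulation in the
test suite.

Decoding metrics follow the protocol's definitions: TPV (task predictive
value) = correctly classified task volumes / all task volumes; accuracy =
correctly classified volumes / all volumes of the contrast's two classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .decoder import CONTRASTS, DecisionTrace
from .errors import DesignError
from .paradigm import Condition, Paradigm, TASK_CONDITIONS
from .phantom import canonical_hrf

__all__ = [
    "drop_initial",
    "build_design",
    "DesignMatrix",
    "GLM",
    "GLMResults",
    "ContrastMap",
    "contrast_t",
    "cluster_inference",
    "tpv_and_accuracy",
    "paired_compare",
]


def drop_initial(series: np.ndarray, k: int, labels: np.ndarray | None = None):
    """Discard the first ``k`` volumes (initial signal stabilisation).

    Returns the trimmed series, or ``(series, labels)`` trimmed consistently
    when per-volume labels are supplied.  ``k`` must leave at least one
    volume.
    """
    n = series.shape[-1]
    if not 0 <= k < n:
        raise ValueError(f"k must lie in [0, {n}), got {k}")
    out = series[..., k:]
    if labels is None:
        return out
    if len(labels) != n:
        raise ValueError("labels length does not match series")
    return out, np.asarray(labels)[k:]


@dataclass
class DesignMatrix:
    """n_volumes x n_regressors design with named columns."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise DesignError("column count does not match names")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            # name the offending columns for the error message
            bad = []
            cols = self.matrix
            for j in range(cols.shape[1]):
                others = np.delete(cols, j, axis=1)
                if np.linalg.matrix_rank(others) == rank:
                    bad.append(self.names[j])
            raise DesignError(f"design matrix is rank deficient; collinear: {bad}")

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> int:
        return self.names.index(name)

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(self.n_regressors)
        for name, w in weights.items():
            c[self.column(name)] = w
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def build_design(
    labels: np.ndarray,
    tr_s: float,
    motion: np.ndarray | None = None,
    drift_order: int = 0,
) -> DesignMatrix:
    """Task boxcars convolved with the canonical HRF + nuisance columns.

    Parameters
    ----------
    labels : per-volume Condition array (post any initial-volume discard)
    tr_s : repetition time in seconds
    motion : optional (n, 6) realignment parameters; near-constant columns
        (SD < 1e-10) are dropped since they are collinear with the intercept
    drift_order : number of Legendre-like polynomial drift terms to add
    """
    labels = np.asarray(labels, dtype=object)
    n = len(labels)
    hrf = canonical_hrf(tr_s)
    cols, names = [], []
    for cond in TASK_CONDITIONS:
        box = (labels == cond).astype(float)
        if box.any():
            cols.append(np.convolve(box, hrf)[:n])
            names.append(cond.value)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n, 6):
            raise DesignError(f"motion must be (n, 6), got {motion.shape}")
        for j, nm in enumerate(["tx", "ty", "tz", "rx", "ry", "rz"]):
            col = motion[:, j]
            if col.std() > 1e-10:
                cols.append(col - col.mean())
                names.append(f"motion_{nm}")
    t = np.linspace(-1, 1, n)
    for k in range(1, drift_order + 1):
        cols.append(t**k)
        names.append(f"drift_{k}")
    cols.append(np.ones(n))
    names.append("intercept")
    return DesignMatrix(np.column_stack(cols), names)


@dataclass
class GLMResults:
    """Per-voxel OLS estimates and what is needed for inference."""

    beta: np.ndarray          # (n_regressors, n_voxels)
    sigma2: np.ndarray        # residual variance, (n_voxels,)
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray
    fitted: np.ndarray        # (n_volumes, n_voxels)
    residuals: np.ndarray     # (n_volumes, n_voxels)
    mask: np.ndarray | None = None

    def contrast(self, c) -> "ContrastMap":
        return contrast_t(self, c)

    def summary(self) -> pd.DataFrame:
        """Per-regressor summary of effect sizes across voxels."""
        b = self.beta
        return pd.DataFrame(
            {
                "regressor": self.design.names,
                "mean_beta": b.mean(axis=1),
                "sd_beta": b.std(axis=1),
                "max_abs_beta": np.abs(b).max(axis=1),
            }
        )


@dataclass
class GLM:
    """Mass-univariate linear model of a masked 4D series.

    ``Y`` is (n_volumes, n_voxels); use :meth:`from_series` to go from a
    4D array plus a boolean mask.  :meth:`fit` performs ordinary least
    squares per voxel and returns :class:`GLMResults`.
    """

    Y: np.ndarray
    design: DesignMatrix
    mask: np.ndarray | None = None

    @classmethod
    def from_series(cls, series: np.ndarray, mask: np.ndarray, design: DesignMatrix):
        if mask.shape != series.shape[:-1]:
            raise DesignError("mask grid does not match series grid")
        return cls(Y=series[mask].T.astype(float), design=design, mask=mask)

    def fit(self) -> GLMResults:
        X = self.design.matrix
        n, p = X.shape
        if self.Y.shape[0] != n:
            raise DesignError(
                f"series has {self.Y.shape[0]} volumes, design has {n} rows"
            )
        if not np.all(np.isfinite(self.Y)):
            raise DesignError("series contains non-finite values")
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ self.Y
        fitted = X @ beta
        resid = self.Y - fitted
        df = n - p
        if df <= 0:
            raise DesignError("no residual degrees of freedom")
        sigma2 = (resid**2).sum(axis=0) / df
        return GLMResults(
            beta=beta,
            sigma2=sigma2,
            df=df,
            design=self.design,
            xtx_inv=xtx_inv,
            fitted=fitted,
            residuals=resid,
            mask=self.mask,
        )


@dataclass
class ContrastMap:
    """Per-voxel effect and t-statistic for one contrast vector."""

    effect: np.ndarray
    t: np.ndarray
    df: int
    contrast: np.ndarray
    valid: np.ndarray              # False where residual variance was 0
    results: GLMResults = field(repr=False, default=None)

    def t_image(self) -> np.ndarray:
        """t-map as a 3D image (zeros outside the mask) if a mask is known."""
        if self.results is None or self.results.mask is None:
            raise ValueError("no mask associated with this contrast map")
        img = np.zeros(self.results.mask.shape)
        img[self.results.mask] = np.where(self.valid, self.t, 0.0)
        return img


def contrast_t(fit: GLMResults, c) -> ContrastMap:
    """t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c), per voxel.

    Voxels with zero residual variance (and nonzero contrast variance) have
    an undefined t and are masked out via ``valid``.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (fit.design.n_regressors,):
        raise ValueError(
            f"contrast length {c.shape} does not match {fit.design.n_regressors} regressors"
        )
    effect = c @ fit.beta
    var_c = float(c @ fit.xtx_inv @ c)
    se = np.sqrt(fit.sigma2 * var_c)
    valid = se > 0
    t = np.zeros_like(effect)
    if var_c == 0:
        return ContrastMap(effect, t, fit.df, c, np.ones_like(effect, bool), fit)
    t[valid] = effect[valid] / se[valid]
    return ContrastMap(effect, t, fit.df, c, valid, fit)


# ---------------------------------------------------------------------------
# cluster-level inference (sign-flip permutation substitute for RFT FWEc)
# ---------------------------------------------------------------------------

_CONN26 = np.ones((3, 3, 3))


def _cluster_sizes(tmap3d: np.ndarray, thr: float):
    """Supra-threshold 26-connected clusters of |t| (two-sided)."""
    labeled, nlab = ndimage.label(np.abs(tmap3d) > thr, structure=_CONN26)
    if nlab == 0:
        return labeled, np.array([], dtype=int)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, nlab + 1))
    return labeled, sizes.astype(int)


def cluster_inference(
    tmap: ContrastMap,
    cdt_p: float = 0.001,
    n_perm: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation max-cluster-size inference on a contrast t-map.

    Clusters are formed at the two-sided cluster-defining threshold
    ``cdt_p``; the null distribution of the maximum cluster size is built by
    sign-flipping the residuals of the *reduced* model (the design without
    the contrast's regressors) with one shared sign per time point across
    voxels — preserving the spatial correlation structure — adding them back
    to the reduced-model fit, and refitting the full model.  Corrected p for
    an observed cluster of size s is ``(1 + #{perm max >= s}) / (n_perm + 1)``;
    clusters with corrected p < ``alpha`` are flagged significant.
    """
    fit = tmap.results
    if fit is None or fit.mask is None:
        raise ValueError("cluster_inference needs a ContrastMap with a masked fit")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; corrected p-values will be coarse")
    thr = stats.t.ppf(1 - cdt_p / 2, fit.df)
    labeled, sizes = _cluster_sizes(tmap.t_image(), thr)

    columns = ["cluster", "size", "peak_t", "peak_x", "peak_y", "peak_z",
               "p_corrected", "significant"]
    if sizes.size == 0:
        return pd.DataFrame(columns=columns)

    rng = np.random.default_rng(seed)
    X = fit.design.matrix
    hat = fit.xtx_inv @ X.T
    c = tmap.contrast
    var_c = float(c @ fit.xtx_inv @ c)
    mask = fit.mask
    # reduced model: drop the regressors the contrast touches, so the tested
    # effect is not smuggled back into the permuted data
    Y = fit.fitted + fit.residuals
    keep = c == 0
    if keep.any():
        X0 = X[:, keep]
        beta0 = np.linalg.lstsq(X0, Y, rcond=None)[0]
        fitted0 = X0 @ beta0
    else:
        fitted0 = np.zeros_like(Y)
    resid0 = Y - fitted0
    null_max = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=Y.shape[0])
        Yp = fitted0 + signs[:, None] * resid0
        beta = hat @ Yp
        resid = Yp - X @ beta
        sigma2 = (resid**2).sum(axis=0) / fit.df
        se = np.sqrt(sigma2 * var_c)
        tval = np.divide(c @ beta, se, out=np.zeros_like(se), where=se > 0)
        timg = np.zeros(mask.shape)
        timg[mask] = tval
        _, perm_sizes = _cluster_sizes(timg, thr)
        null_max[i] = perm_sizes.max() if perm_sizes.size else 0

    timg_obs = tmap.t_image()
    rows = []
    for lab in range(1, sizes.size + 1):
        in_cluster = labeled == lab
        tvals = timg_obs[in_cluster]
        peak_flat = np.abs(tvals).argmax()
        peak_idx = tuple(np.argwhere(in_cluster)[peak_flat])
        s = int(sizes[lab - 1])
        p_corr = (1 + int((null_max >= s).sum())) / (n_perm + 1)
        rows.append(
            {
                "cluster": lab,
                "size": s,
                "peak_t": float(tvals[peak_flat]),
                "peak_x": int(peak_idx[0]),
                "peak_y": int(peak_idx[1]),
                "peak_z": int(peak_idx[2]),
                "p_corrected": p_corr,
                "significant": p_corr < alpha,
            }
        )
    return pd.DataFrame(rows, columns=columns).sort_values(
        "size", ascending=False, ignore_index=True
    )


# ---------------------------------------------------------------------------
# decoding performance metrics
# ---------------------------------------------------------------------------

def tpv_and_accuracy(trace: DecisionTrace, contrast: str | None = None) -> dict:
    """Task predictive value and accuracy for one decision trace.

    Only volumes whose true block condition belongs to the contrast's two
    classes are scored.  TPV = correct task volumes / all task volumes;
    accuracy = correct volumes / all scored volumes.
    """
    if len(trace) == 0:
        raise ValueError("empty decision trace")
    contrast = contrast or trace.contrast
    first, second = CONTRASTS[contrast]
    true = trace.true_condition
    scored = (true == first) | (true == second)
    if not scored.any():
        raise ValueError(f"trace contains no volumes of contrast {contrast}")
    correct = trace.correct() & scored
    is_task = scored & np.isin(true, TASK_CONDITIONS)
    n_task = int(is_task.sum())
    if n_task == 0:
        raise ValueError("TPV undefined: zero task volumes in the scored trace")
    return {
        "contrast": contrast,
        "tpv": float((correct & is_task).sum() / n_task),
        "accuracy": float(correct.sum() / scored.sum()),
        "n_task": n_task,
        "n_scored": int(scored.sum()),
        "n_correct": int(correct.sum()),
        "n_correct_task": int((correct & is_task).sum()),
    }


def paired_compare(metric_a, metric_b) -> tuple[float, float]:
    """Paired t-test on per-subject (or per-seed) metric values.

    Returns ``(t, two-sided p)`` with df = n - 1.  Identical inputs give
    (0, 1); zero-variance nonzero differences are degenerate and reported
    as p = 0 with a warning.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_compare needs two equal-length 1D arrays, n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero differences; p reported as 0")
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * stats.t.sf(abs(t), df=n - 1))
    return t, p
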