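"""Linear-SVM decoding of streamed volumes with incremental drift correction.

Three binary contrasts are trained on the pre-feedback run (run 0): Rest vs
LGO, Rest vs RGO, and LGO vs RGO, all linear soft-margin SVMs with
regularisation c = 1.  During feedback runs each preprocessed volume is
classified in real time; the raw decision value is passed through an
incremental detrender before thresholding, to correct slow classifier drift.

Detrending reconstruction
-------------------------
The drift corrector is an online recursive least-squares fit of a line
(intercept + slope) to all raw decision values seen so far, maintained with
O(1) running sums per volume; the detrended value is the raw value minus the
fitted baseline at the current volume.  During a warm-up window (first W
volumes, default W = 10) the baseline is the running mean, since a 2-point
line fit is degenerate.  This is a reconstruction of the incremental
detrending idea — the exact recursion of the original real-time system is
not public — chosen because it nulls any affine drift exactly and runs in
constant time per volume.

Sign convention: ``decision(x) = w . x_scaled + b`` with positive values
voting for the second-named class of the contrast; exact zeros resolve to
the first-named class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import GridMismatchError, InvalidContrastError
from .paradigm import Condition, Paradigm, labels_with_delay

__all__ = [
    "CONTRASTS",
    "TrainingSet",
    "ClassifierModel",
    "DetrendConfig",
    "DetrendState",
    "detrend_update",
    "DecisionTrace",
    "build_training_set",
    "train_svm",
    "stream_classify",
]

# contrast name -> (first class, second class); positive decision = second
CONTRASTS: dict[str, tuple[Condition, Condition]] = {
    "REST_vs_LGO": (Condition.REST, Condition.LGO),
    "REST_vs_RGO": (Condition.REST, Condition.RGO),
    "LGO_vs_RGO": (Condition.LGO, Condition.RGO),
}

SD_FLOOR = 1e-12


@dataclass
class TrainingSet:
    """Feature matrix (volumes x in-mask voxels) for one binary contrast."""

    X: np.ndarray                 # standardized features
    y: np.ndarray                 # -1 = first class, +1 = second class
    contrast: str
    mask: np.ndarray
    mean_: np.ndarray
    sd_: np.ndarray

    @property
    def classes(self) -> tuple[Condition, Condition]:
        return CONTRASTS[self.contrast]


@dataclass
class ClassifierModel:
    """Linear decision function w.x_scaled + b for one binary contrast."""

    contrast: str
    weights: np.ndarray
    bias: float
    c: float
    mask: np.ndarray
    mean_: np.ndarray
    sd_: np.ndarray

    @property
    def classes(self) -> tuple[Condition, Condition]:
        return CONTRASTS[self.contrast]

    def features(self, volume: np.ndarray) -> np.ndarray:
        if volume.shape != self.mask.shape:
            raise GridMismatchError("volume grid differs from the model's mask grid")
        return (volume[self.mask] - self.mean_) / self.sd_

    def decision(self, volume: np.ndarray) -> float:
        return float(self.weights @ self.features(volume) + self.bias)

    def label_for(self, decision_value: float) -> Condition:
        first, second = self.classes
        return second if decision_value > 0 else first

    # -- persistence: weight image (NIfTI) + JSON sidecar ------------------

    def save(self, stem: str | Path, affine: np.ndarray) -> None:
        import nibabel as nib

        stem = Path(stem)
        wimg = np.zeros(self.mask.shape, dtype=np.float32)
        wimg[self.mask] = self.weights
        nib.save(nib.Nifti1Image(wimg, affine), str(stem) + "_weights.nii")
        meta = {
            "contrast": self.contrast,
            "bias": self.bias,
            "c": self.c,
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "sign_convention": "positive = second-named class",
        }
        Path(str(stem) + "_model.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, stem: str | Path) -> "ClassifierModel":
        import nibabel as nib

        stem = Path(stem)
        wimg = np.asarray(nib.load(str(stem) + "_weights.nii").dataobj, dtype=float)
        meta = json.loads(Path(str(stem) + "_model.json").read_text())
        mask = wimg != 0
        return cls(
            contrast=meta["contrast"],
            weights=wimg[mask],
            bias=float(meta["bias"]),
            c=float(meta["c"]),
            mask=mask,
            mean_=np.asarray(meta["mean"], dtype=float),
            sd_=np.asarray(meta["sd"], dtype=float),
        )


def build_training_set(
    series: np.ndarray,
    paradigm: Paradigm,
    contrast: str,
    mask: np.ndarray,
    label_shift: int = 0,
    standardize: bool = True,
) -> TrainingSet:
    """Rows = volumes whose (shifted) label is one of the contrast's classes.

    Features are the in-mask voxel intensities, z-scored per voxel by the
    training mean/SD (SD floored at 1e-12); ``standardize=False`` keeps raw
    intensities (mean 0, SD 1 recorded so downstream scaling is a no-op).
    """
    first, second = CONTRASTS[contrast]
    labels = labels_with_delay(paradigm, label_shift)
    sel = (labels == first) | (labels == second)
    if not (labels == first).any() or not (labels == second).any():
        raise InvalidContrastError(
            f"contrast {contrast}: one of its classes has zero volumes"
        )
    X = series[mask][:, sel].T.astype(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features in training data")
    y = np.where(labels[sel] == second, 1, -1)
    if standardize:
        mean_ = X.mean(axis=0)
        sd_ = np.maximum(X.std(axis=0), SD_FLOOR)
    else:
        mean_ = np.zeros(X.shape[1])
        sd_ = np.ones(X.shape[1])
    return TrainingSet(
        X=(X - mean_) / sd_, y=y, contrast=contrast, mask=mask, mean_=mean_, sd_=sd_
    )


def train_svm(ts: TrainingSet, c: float = 1.0) -> ClassifierModel:
    """Fit a linear soft-margin SVM (libsvm via scikit-learn), c = 1 default."""
    if c <= 0:
        raise ValueError("regularization parameter c must be > 0")
    svc = SVC(kernel="linear", C=c, tol=1e-8)
    svc.fit(ts.X, ts.y)
    # classes_ is sorted [-1, +1]; decision_function > 0 votes for +1,
    # i.e. the second-named class, matching the package sign convention
    return ClassifierModel(
        contrast=ts.contrast,
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        c=c,
        mask=ts.mask,
        mean_=ts.mean_,
        sd_=ts.sd_,
    )


# ---------------------------------------------------------------------------
# incremental detrending
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetrendConfig:
    enabled: bool = True
    warmup: int = 10


@dataclass(frozen=True)
class DetrendState:
    """O(1) running sums for the online linear baseline fit."""

    n: int = 0
    sum_t: float = 0.0
    sum_t2: float = 0.0
    sum_y: float = 0.0
    sum_ty: float = 0.0
    warmup: int = 10


def detrend_update(
    state: DetrendState, raw: float, t: int
) -> tuple[float, DetrendState]:
    """One detrending step: absorb (t, raw), return raw minus the baseline.

    The baseline is the least-squares line through all points seen so far
    (including the current one), evaluated at ``t``; while fewer than
    ``warmup`` points have been seen it is the running mean.  The very first
    value is therefore detrended to exactly 0.
    """
    new = DetrendState(
        n=state.n + 1,
        sum_t=state.sum_t + t,
        sum_t2=state.sum_t2 + t * t,
        sum_y=state.sum_y + raw,
        sum_ty=state.sum_ty + t * raw,
        warmup=state.warmup,
    )
    n = new.n
    mean_y = new.sum_y / n
    if n <= new.warmup:
        baseline = mean_y
    else:
        mean_t = new.sum_t / n
        stt = new.sum_t2 - n * mean_t * mean_t
        if stt <= 0:
            baseline = mean_y
        else:
            slope = (new.sum_ty - n * mean_t * mean_y) / stt
            baseline = mean_y + slope * (t - mean_t)
    return raw - baseline, new


@dataclass
class DecisionTrace:
    """Per-volume classifier outputs for one contrast over one run."""

    contrast: str
    volume: np.ndarray            # acquisition index
    raw: np.ndarray               # raw decision values
    detrended: np.ndarray
    predicted: np.ndarray         # Condition per volume
    true_condition: np.ndarray    # block condition per volume
    command: np.ndarray = None    # filled by the feedback stage

    def __post_init__(self) -> None:
        if self.command is None:
            self.command = np.array(["NONE"] * len(self.volume), dtype=object)

    def __len__(self) -> int:
        return len(self.volume)

    def correct(self) -> np.ndarray:
        return self.predicted == self.true_condition

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "volume": self.volume,
                "raw": self.raw,
                "detrended": self.detrended,
                "predicted": [str(c) for c in self.predicted],
                "true_condition": [str(c) for c in self.true_condition],
                "command": [str(c) for c in self.command],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, contrast: str) -> "DecisionTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(
            contrast=contrast,
            volume=df["volume"].to_numpy(),
            raw=df["raw"].to_numpy(float),
            detrended=df["detrended"].to_numpy(float),
            predicted=np.array([Condition(c) for c in df["predicted"]], dtype=object),
            true_condition=np.array(
                [Condition(c) for c in df["true_condition"]], dtype=object
            ),
            command=df["command"].to_numpy(object),
        )


def stream_classify(
    model: ClassifierModel,
    volumes: Iterable[np.ndarray] | np.ndarray,
    true_labels: np.ndarray,
    detrend: DetrendConfig = DetrendConfig(),
) -> DecisionTrace:
    """Classify an ordered stream of preprocessed volumes.

    Each volume is handled independently and in order, as it would arrive
    from the scanner: extract in-mask features, scale with the training
    statistics, compute the raw decision value, update the incremental
    detrender, and threshold the detrended value at 0.
    """
    if isinstance(volumes, np.ndarray) and volumes.ndim == 4:
        series = volumes
        volumes = (series[..., t] for t in range(series.shape[-1]))
    state = DetrendState(warmup=detrend.warmup)
    raws, detr, preds = [], [], []
    for t, vol in enumerate(volumes):
        raw = model.decision(vol)
        if detrend.enabled:
            value, state = detrend_update(state, raw, t)
        else:
            value = raw
        raws.append(raw)
        detr.append(value)
        preds.append(model.label_for(value))
    n = len(raws)
    if len(true_labels) != n:
        raise ValueError(f"true_labels has {len(true_labels)} entries for {n} volumes")
    return DecisionTrace(
        contrast=model.contrast,
        volume=np.arange(n),
        raw=np.asarray(raws),
        detrended=np.asarray(detr),
        predicted=np.array(preds, dtype=object),
        true_condition=np.asarray(true_labels, dtype=object).copy(),
    )
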