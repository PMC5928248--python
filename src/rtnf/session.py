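"""Session orchestration: the 4-run neurofeedback protocol end to end.

A session is one simulated participant visit: a pre-feedback run (run 0)
used to build the reference mean image, brain mask and the three SVM
models, followed by three test runs (runs 1-3) that are preprocessed and
classified volume-by-volume.  In a neurofeedback (NF) session the feedback
rule emits robot commands during runs 1-3; in a non-NF session the same
decoding happens but no commands are issued.

Outputs use a BIDS-flavoured layout (sub-*/ses-*/run-* naming) with a
manifest JSON capturing the full configuration, the seed and the package
versions, so a session can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decoder import (
    CONTRASTS,
    ClassifierModel,
    DetrendConfig,
    build_training_set,
    train_svm,
)
from .errors import InvalidConfigError
from .feedback import FeedbackConfig, SessionResult, run_session
from .glm import GLM, build_design, cluster_inference, drop_initial, tpv_and_accuracy
from .paradigm import Condition, make_paradigm
from .phantom import PhantomSpec, default_patterns, simulate_run
from .preproc import (
    OnlinePreprocessor,
    make_mask,
    motion_params_table,
    realign_series_two_pass,
    smooth,
)

__all__ = ["SessionConfig", "run_protocol", "ProtocolResult"]


@dataclass
class ParadigmConfig:
    n_rest: int = 9
    n_task: int = 8
    block_s: float = 30.0
    tr_s: float = 2.0
    task_order: list = field(default_factory=lambda: ["LGO", "RGO"] * 4)
    label_shift: int = 0


@dataclass
class PhantomConfig:
    grid: list = field(default_factory=lambda: [64, 64, 37])
    voxel_mm: list = field(default_factory=lambda: [3.0, 3.0, 3.0])
    baseline: float = 100.0
    amplitude: float = 1.0          # % of baseline, both task patterns
    lateral_weight: float = 0.35    # lateralised-cluster weight (pattern overlap)
    noise_sd: float = 1.0
    ar1_rho: float = 0.3
    drift_poly: list = field(default_factory=lambda: [1.0])
    drift_cosine: list = field(default_factory=lambda: [0.5])


@dataclass
class PreprocConfig:
    fwhm_mm: float = 8.0
    mask_frac: float = 0.5
    realign: bool = True


@dataclass
class DecoderConfig:
    c: float = 1.0
    standardize: bool = True
    detrend: bool = True
    detrend_warmup: int = 10


@dataclass
class GlmConfig:
    enabled: bool = False
    drop_initial: int = 5
    drift_order: int = 1
    cdt_p: float = 0.001
    n_perm: int = 200


@dataclass
class SessionConfig:
    """Full configuration of one simulated session."""

    session_type: str = "NF"          # "NF" or "non-NF"
    n_runs: int = 4                   # run 0 = training, runs 1..n_runs-1 = test
    seed: int = 0
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    feedback_angle_deg: float = 85.0
    glm: GlmConfig = field(default_factory=GlmConfig)

    def __post_init__(self) -> None:
        if self.session_type not in ("NF", "non-NF"):
            raise InvalidConfigError("session_type must be 'NF' or 'non-NF'")
        if self.n_runs < 2:
            raise InvalidConfigError("protocol needs a training run plus >= 1 test run")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        for key, sub in (
            ("paradigm", ParadigmConfig),
            ("phantom", PhantomConfig),
            ("preproc", PreprocConfig),
            ("decoder", DecoderConfig),
            ("glm", GlmConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SessionConfig":
        path = Path(path)
        if not path.exists():
            raise InvalidConfigError(f"config file not found: {path}")
        payload = yaml.safe_load(path.read_text())
        if "config" in payload and isinstance(payload["config"], dict):
            payload = payload["config"]   # manifest round-trip
        return cls.from_dict(payload)


def _run_seed(seed: int, run: int) -> int:
    return int((seed * 1_000_003 + 7919 * run + 1) % (2**31 - 1))


def _phantom_spec(cfg: SessionConfig, run: int) -> PhantomSpec:
    p = cfg.paradigm
    paradigm = make_paradigm(p.n_rest, p.n_task, p.block_s, p.tr_s, p.task_order)
    ph = cfg.phantom
    return PhantomSpec(
        grid=tuple(ph.grid),
        voxel_mm=tuple(ph.voxel_mm),
        paradigm=paradigm,
        baseline=ph.baseline,
        patterns=default_patterns(
            tuple(ph.grid), amplitude=ph.amplitude, lateral_weight=ph.lateral_weight
        ),
        noise_sd=ph.noise_sd,
        ar1_rho=ph.ar1_rho,
        drift={"poly": list(ph.drift_poly), "cosine": list(ph.drift_cosine)},
        seed=_run_seed(cfg.seed, run),
    )


@dataclass
class ProtocolResult:
    """Everything the 4-run protocol produces, in memory."""

    config: SessionConfig
    models: dict[str, ClassifierModel]
    mean_image: np.ndarray
    mask: np.ndarray
    run_results: dict[int, SessionResult]
    metrics: pd.DataFrame
    motion: dict[int, np.ndarray]
    cluster_tables: dict[int, pd.DataFrame] = field(default_factory=dict)

    def manifest(self) -> dict:
        import scipy
        import sklearn

        return {
            "config": self.config.to_dict(),
            "seed": self.config.seed,
            "versions": {
                "rtnf": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "sklearn": sklearn.__version__,
            },
        }

    def write(self, outdir: str | Path, subject: str = "sub-01") -> Path:
        outdir = Path(outdir)
        ses = "ses-NF" if self.config.session_type == "NF" else "ses-nonNF"
        base = outdir / subject / ses
        base.mkdir(parents=True, exist_ok=True)
        manifest_path = outdir / "manifest.json"
        if manifest_path.exists():
            raise FileExistsError(f"refusing to overwrite {manifest_path}")
        manifest_path.write_text(json.dumps(self.manifest(), indent=1))
        self.metrics.to_csv(base / "metrics.tsv", sep="\t", index=False)
        for run, result in self.run_results.items():
            result.write(base, prefix=f"{subject}_{ses}_run-{run}")
            np.savetxt(
                base / f"{subject}_{ses}_run-{run}_motion.txt",
                self.motion[run],
                fmt="%.8f",
            )
        for run, table in self.cluster_tables.items():
            table.to_csv(
                base / f"{subject}_{ses}_run-{run}_clusters.tsv", sep="\t", index=False
            )
        return base


def run_protocol(cfg: SessionConfig) -> ProtocolResult:
    """Simulate and analyse a full session (training run + test runs)."""
    p = cfg.paradigm
    paradigm = make_paradigm(p.n_rest, p.n_task, p.block_s, p.tr_s, p.task_order)
    affine = _phantom_spec(cfg, 0).affine
    voxel_mm = tuple(cfg.phantom.voxel_mm)

    # ---- run 0: training -------------------------------------------------
    train_series, _ = simulate_run(_phantom_spec(cfg, 0))
    if cfg.preproc.realign:
        mean_img, realigned, transforms0 = realign_series_two_pass(train_series, affine)
    else:
        realigned = train_series.astype(float)
        mean_img = realigned.mean(axis=-1)
        from .preproc import RigidTransform

        transforms0 = [RigidTransform()] * paradigm.n_volumes
    mask = make_mask(mean_img, cfg.preproc.mask_frac)
    smoothed = np.empty_like(realigned)
    for t in range(realigned.shape[-1]):
        smoothed[..., t] = smooth(realigned[..., t], cfg.preproc.fwhm_mm, voxel_mm)

    models: dict[str, ClassifierModel] = {}
    for contrast in CONTRASTS:
        ts = build_training_set(
            smoothed, paradigm, contrast, mask,
            label_shift=p.label_shift, standardize=cfg.decoder.standardize,
        )
        models[contrast] = train_svm(ts, c=cfg.decoder.c)

    motion: dict[int, np.ndarray] = {0: motion_params_table(transforms0)}

    # ---- runs 1..n-1: streaming test/feedback runs -----------------------
    pre = OnlinePreprocessor(
        mean=mean_img, affine=affine, mask=mask,
        fwhm_mm=cfg.preproc.fwhm_mm, do_realign=cfg.preproc.realign,
    )
    fb = FeedbackConfig(
        raise_angle_deg=cfg.feedback_angle_deg,
        feedback_enabled=cfg.session_type == "NF",
    )
    detrend = DetrendConfig(
        enabled=cfg.decoder.detrend, warmup=cfg.decoder.detrend_warmup
    )

    run_results: dict[int, SessionResult] = {}
    cluster_tables: dict[int, pd.DataFrame] = {}
    rows = []
    for run in range(1, cfg.n_runs):
        series, _ = simulate_run(_phantom_spec(cfg, run))
        transforms, processed = pre.process_series(series)
        motion[run] = motion_params_table(transforms)
        result = run_session(models, processed, paradigm, fb, detrend)
        run_results[run] = result
        for contrast, trace in result.traces.items():
            m = tpv_and_accuracy(trace)
            rows.append(
                {
                    "run": run,
                    "contrast": contrast,
                    "tpv": m["tpv"],
                    "accuracy": m["accuracy"],
                    "n_task": m["n_task"],
                    "n_scored": m["n_scored"],
                    "n_commands": result.n_raise(),
                }
            )
        if cfg.glm.enabled:
            cluster_tables[run] = _offline_glm(cfg, processed, paradigm, mask, motion[run])
    metrics = pd.DataFrame(rows)
    return ProtocolResult(
        config=cfg,
        models=models,
        mean_image=mean_img,
        mask=mask,
        run_results=run_results,
        metrics=metrics,
        motion=motion,
        cluster_tables=cluster_tables,
    )


def _offline_glm(cfg, processed, paradigm, mask, motion_table) -> pd.DataFrame:
    """Single-run offline activation mapping on the preprocessed series."""
    k = cfg.glm.drop_initial
    series, labels = drop_initial(processed, k, paradigm.labels)
    design = build_design(
        labels, paradigm.tr_s, motion=motion_table[k:], drift_order=cfg.glm.drift_order
    )
    fit = GLM.from_series(series, mask, design).fit()
    tables = []
    for cond in (Condition.LGO, Condition.RGO):
        if cond.value not in design.names:
            continue
        cmap = fit.contrast(design.contrast_vector({cond.value: 1.0}))
        tab = cluster_inference(
            cmap, cdt_p=cfg.glm.cdt_p, n_perm=cfg.glm.n_perm, seed=cfg.seed
        )
        tab.insert(0, "task", cond.value)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
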