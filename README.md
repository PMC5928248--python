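# rtnf — a closed-loop real-time fMRI neurofeedback simulator

`rtnf` simulates, end to end and on a desk, a real-time fMRI brain–machine
interface for motor-imagery training: a participant imagines left- or
right-hand gripping-and-opening (LGO / RGO) in a 30-s block design
(9 rest + 8 task blocks, TR = 2 s, 255 volumes per run); each volume is
realigned to a reference mean image, smoothed (8-mm FWHM), masked, and
classified by linear SVMs (c = 1) trained on a pre-feedback run; a correct
task classification raises the matching arm of a simulated humanoid robot
by 85° as visual feedback. Because no scanner is available at a desk, a
synthetic BOLD phantom with known ground truth — hemodynamically convolved
activation patterns, AR(1) noise, low-frequency drift, optional rigid-body
motion — stands in for the acquisition, which makes every stage of the loop
quantitatively testable.

It is intended for people building or studying real-time decoding
pipelines: you can measure how realignment error, smoothing, classifier
drift correction, or label timing affect decoding performance before ever
touching a scanner.

## The core computation

Per brain voxel v the phantom generates

    y_v(t) = B (1 + Σ_c a_c/100 · (boxcar_c ⊗ h)(t) · P_c(v)) + d(t) + ε_v(t)

(B baseline, h canonical double-gamma HRF, P_c spatial pattern of condition
c, d drift, ε AR(1) noise). The decoder computes, per streamed volume,

    s_t = w · x̃_t + b,      ŝ_t = s_t − baseline_t,

where x̃_t are the z-scored in-mask intensities, w, b come from a linear
soft-margin SVM, and baseline_t is an incrementally updated least-squares
line over all decision values seen so far (running mean during the first
10 volumes) — an O(1)/volume drift correction. Offline, a voxelwise GLM
with boxcar⊗HRF task regressors and 6 motion nuisance regressors yields
contrast t-maps with sign-flip permutation cluster inference, and decoding
is scored by TPV (correct task volumes / all task volumes) and accuracy.
See `docs/methods.md` for the full model and design choices.

## Worked example

Run a full neurofeedback session — train on run 0, stream runs 1–3 with
feedback — on a reduced 20×20×12 grid:

```python
from rtnf.session import SessionConfig, PhantomConfig, run_protocol

cfg = SessionConfig(seed=1, phantom=PhantomConfig(grid=[20, 20, 12]))
result = run_protocol(cfg)
print(result.metrics.groupby("contrast")[["tpv", "accuracy"]].mean().round(3))
```

prints

```
               tpv  accuracy
contrast
LGO_vs_RGO   0.800     0.800
REST_vs_LGO  0.733     0.786
REST_vs_RGO  0.767     0.737
```

i.e. averaged over the three feedback runs, the Rest-vs-LGO model correctly
classifies 73% of LGO-block volumes (TPV), the Rest-vs-RGO model 77% of
RGO-block volumes, and the LGO-vs-RGO model tells the two imagery tasks
apart on 80% of task volumes — the realistic operating regime for
real-time motor-imagery decoding, with task-vs-task discrimination the
hardest problem. `result.run_results[r]` holds the per-volume decision
traces and the robot command log of run r; the raise-command count always
equals the number of correctly classified task volumes.

The same protocol is available from the shell:

```bash
rtnf simulate --seed 1 --grid 32,32,20 --out run0.nii   # one phantom run
rtnf session --config config.yaml --out outdir/         # full 4-run protocol
```

(`rtnf train`, `stream`, `evaluate`, and `glm` expose the individual
stages; `session` writes BIDS-flavoured traces, command logs, motion
parameters, metrics and a manifest that reproduces the session exactly.)

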