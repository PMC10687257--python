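# neuroscreen

Multimodal screening of **stroke** and **Parkinson's disease (PD)** from
camera-derived digital biomarkers: 2-D landmark trajectories of the body
(13 points), face (68) and hands (2×21), plus MFCC voice features, recorded
while a subject performs 15 standardized examination protocols (eye
movement, facial expression, speech, hand posture, gait).

The package is aimed at researchers in movement-disorder screening who have
landmark/MFCC tables per `(protocol, camera)` pair — the RGB-to-landmark
extraction step is out of scope — and want a full train/evaluate pipeline
with an auditable loss ledger. Because real examination-room data of this
kind is rarely shareable, a first-class synthetic cohort generator with
planted, ground-truth disease effects is included, so every stage is
runnable and testable end to end.

## Model

**Frame-length staticizer.** Fixed-input networks need equal-length
sequences; subjects take different times per protocol. A sequence of `F`
frames is cut into `N` overlapping segments of `S` frames with 1-based
starts

```
I_i = ⌊(i−1)(F−S)/(N−1)⌋ + 1,   i = 1..N,
```

concatenated to exactly `F′ = N·S` frames (body 4500 = 150×30, face
1200 = 40×30, hand 1500 = 50×30). No frame is dropped — momentary tremor
survives — and `F = N·S` is the identity. Lengths outside `[S, N·S]` are
outliers and excluded.

**Frozen encoders.** Per body part, a graph-based spatiotemporal encoder
(semantics-guided skeleton-network family: joint+semantic embeddings,
message passing over the skeleton adjacency, strided temporal convolution,
mean+std pooling) emits a 128-dim feature per camera. Voice uses a
multi-context time-delay encoder (parallel temporal convolutions of
different context widths over the 25 MFCC channels, statistics pooling)
emitting 512 dims from a 2500×25 sample. Encoder weights are fixed during
main training; a pretraining harness (classification/regression on
synthetic proxy corpora) is provided.

**Subnetworks + aggregator.** Per protocol, encoder outputs are
concatenated (`N_s = 128·N_cameras·N_parts`, or 512 for voice) and mapped
`N_s → 64 → 8` by two (linear–batchnorm–ReLU–dropout) blocks; a linear head
on the 8-dim feature scores protocol normality (auxiliary supervision from
the clinician's normal/abnormal label). All protocol features are
concatenated (`8·N_p → 8`) and two disease-specific linear heads give
stroke and PD logits. The multitask loss is

```
L_total = L_f^s + L_f^p + Σ_v λ_v·L_v ,   λ_v = 0.1,
```

with label smoothing, uncertain-protocol masking, and dual-head routing:
healthy controls contribute to both disease losses, patients only to their
disease's head. Subjects with ≥1 abnormal protocol label are oversampled
(4× / 6× by recruiting site). Evaluation uses stratified 3-fold
cross-validation with a common held-out test set, per-epoch validation AUC
early stopping, and Mann–Whitney AUC (ties half-credited).

## Worked example

```bash
neuroscreen generate cohort200 --n-subjects 200 --seed 7
# n_subjects=200 n_HC=156 n_stroke=22 n_PD=22

neuroscreen validate cohort200
# n_sessions=200 n_violations=0

neuroscreen evaluate cohort200 results200 --seed 7
# auc_stroke=0.953 auc_pd=1.000
```

The generator plants archetypal effects — 4–6 Hz rest tremor, facial
hypomimia and slowing for PD; lateral motion asymmetry, slowed gait and
voice perturbation for stroke — each expressed per protocol with
probability 0.9 (so some patient protocols are genuinely normal, as in
clinic). `evaluate` runs the full 3-fold cross-validation and reports the
held-out test AUC per disease, averaged over folds: here the pipeline
recovers the planted stroke signal at AUC 0.953 and the PD signal at 1.000.
`results200/report.json` holds the per-fold breakdown and chosen epochs;
`roc_*.csv` hold the test ROC curves. Training on your own data uses the
same directory layout (JSON manifest per subject, CSV tables per
recording; see `neuroscreen/session_io.py`).

Other subcommands: `staticize` (one file, prints segment starts),
`pretrain` (proxy-task encoder pretraining), `train` (single split,
checkpoint + history), `ablate` (protocol-subset sweeps).

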