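# Methods

## Problem setting

Each subject performs 15 examination protocols in front of synchronized
cameras. Depending on the protocol, the recording yields 2-D landmark
trajectories (body: 13 joints after excluding the eye/ear detector points
that overlap the face landmarks; face: 68; hands: 42 = 2×21) and/or a
frames×25 MFCC table for spoken protocols. Labels per subject: one disease
label (HC / stroke / PD) and 15 protocol labels (normal / abnormal /
uncertain). The protocol→modality map lives in `neuroscreen/protocols.py`
and is the single source of truth queried by every module.

## Frame-length staticizer

Inputs of `F` frames are mapped to exactly `N·S` frames by concatenating
`N` overlapping `S`-frame segments with evenly spread integer starts
`I_i = ⌊(i−1)(F−S)/(N−1)⌋ + 1`. Properties relied on elsewhere:

- output length is always `N·S`; `F = N·S` is the bit-exact identity;
- for `S ≤ F ≤ N·S` every input frame appears in some segment (verified
  exhaustively for small `N, S`);
- starts are nondecreasing, strictly increasing when `F−S ≥ N−1`.

`N = 1` degenerates to the first `S` frames so the operator is total;
`F < S` is an error (the generator never produces such lengths). The
operator itself accepts `F > N·S`; treating lengths outside `[S, N·S]` as
excluded outliers is a *policy* applied by session validation, not a
property of the operator. Presets: body `(150, 30)`, face `(40, 30)`, hand
`(50, 30)`; the tiny preset scales these to `(15, 10)`, `(4, 10)`,
`(5, 10)` for CPU-minutes runs.

## Preprocessing

- **Normalization**: per sequence, centre on the mean and scale the RMS
  radius to 1; all-constant sequences are centred only (a float-residue
  threshold avoids dividing by numerical noise). Idempotent and invariant
  to input translation/scaling.
- **Dynamic representation**: positions ∥ frame-difference velocities
  (`v_1 = 0`), giving F×J×4.
- **Augmentation** (training only, landmarks only): one similarity
  transform per sequence — rotation (default ±15°), scale (70–150%),
  translation (±20% of extent) — applied identically to every frame. The
  rotation centre and extent are taken from the first frame so the
  transform is strictly frame-wise and commutes bit-exactly with the
  staticizer. Identity must be reachable in configured ranges.
- **MFCC sizing**: truncate to 2500 frames, or tile short recordings
  cyclically (period = recording length) and cut. The alternative reading
  of "periodic cutting" — splitting one long recording into several
  2500-frame samples — was considered and rejected as the default because
  the model consumes exactly one fixed-size sample per recording.

## Encoders

Encoder internals are configuration, not contract: the pipeline requires
only the output dimensions (128 landmark / 512 voice under the full
preset) and frozen weights during main training.

**Landmark encoder** (graph-based): per-joint linear embedding of the
4-channel dynamic representation, plus a learned per-joint (semantic)
embedding; residual message-passing rounds over the symmetrically
normalized skeleton adjacency (body: kinematic tree; face: standard
68-point region chains/cycles; hands: two independent 21-point trees);
mean over joints; then two pooled paths feed the output layer — mean+std
over frames of the joint-pooled embedding, and mean+std over time of a
strided temporal convolution. Std pooling is load-bearing: oscillatory
energy (tremor) largely cancels under pure temporal averaging. Velocities
are internally rescaled by `velocity_gain` (default 30, i.e. units/second
at 30 fps) because after RMS normalization frame differences are two
orders of magnitude smaller than positions and would otherwise be
invisible to a fixed random projection.

**Voice encoder** (multi-context temporal): parallel strided 1-D
convolutions with distinct context widths (3/7/15 full, 3/5 tiny) over the
25 MFCC channels, each mean+std pooled, plus a direct per-channel mean+std
skip path. The convolution branches see cepstral-mean-normalized input
(per-channel temporal centring — standard practice in speech processing);
the skip path keeps raw channel statistics so speaker/timbre information
survives for pretraining tasks.

Without pretrained checkpoints the encoders act as *frozen random feature
maps*; the shipped pretraining harness (Adam, batch 8, early stopping on a
validation metric, best-epoch weight restore) trains them on synthetic
proxy corpora (3-class motion classification; speaker identification;
regression). The original large-scale pretraining corpora are a
reproduction path outside this package. Frozen-ness is auditable: a
SHA-256 digest over all encoder parameters is unchanged by main training.

## Fusion, loss, training

Per protocol: features concatenate in fixed order (cameras as configured,
default center then left; parts body, face, hand) to `N_s` =
`128·N_c·N_j` (landmarks) or 512 (voice). Subnetworks are two
(linear–batchnorm–ReLU–dropout) blocks `N_s → 64 → 8` with a 2-logit
normality head (mirroring the disease heads' 2-logit convention; the loss
is binary cross-entropy over the softmax pair). The aggregator is one such
block `8·N_p → 8` plus two 2-logit disease heads. A protocol whose payload
is missing (occluded face, dropped modality) contributes an exactly-zero
8-vector — masking is bit-identical to zero-imputation — and its normality
loss is skipped; subnetwork batch statistics use present rows only.
Dropout defaults to 0.3 (unstated upstream; mid-range for small cohorts).

Loss: `L_total = L_f^s + L_f^p + λ_v Σ L_v` with `λ_v = 0.1`; each term is
the mean smoothed cross-entropy over the samples it applies to. Routing is
implemented as loss masking over always-computed heads (batch-friendly,
mathematically identical to conditional forwarding): HC → both disease
terms (target healthy), stroke → stroke term only, PD → PD term only.
Protocol terms require a normal/abnormal label (uncertain masked) and a
present payload; `λ_v = 0` removes them entirely so the normality heads
are gradient-free. Label smoothing ε = 0.1 (the canonical value).

Training: Adam (lr 1e-3, weight decay 1e-4), batch 8, 50 epochs. Each
epoch draws `len(train)` samples with replacement proportionally to
weights 4 (KUAH) / 6 (SUSH) for subjects with ≥1 abnormal protocol label,
1 otherwise; both sites train jointly in one loop. Early stopping keeps
the epoch with the highest *mean* of the two validation AUCs (the
single-task criterion generalized symmetrically). Optional `n_augment`
pre-encodes augmented variants per session and samples among them per
epoch; it defaults to 0 because encoders are frozen and re-encoding every
epoch would dominate runtime at desk scale.

## Evaluation

AUC = Mann–Whitney statistic with half-credit ties; ROC points from
per-score thresholds (both via scikit-learn, oracle-checked in tests
against exhaustive pair counting). Splits: a held-out test fraction
(default 0.235, generalizing the source design's 135-of-574 test set) then
stratified k-fold (k=3) on a composite (disease label, any-abnormal)
stratum; strata too thin for k+1 members fall back to the disease label,
and a disease class below k+1 subjects is a hard error. Cross-validation
trains per fold with early stopping on the held-out fold and scores the
common test set; reported AUC per disease is disease-vs-HC (the contrast
each head is trained on under dual-head routing), per fold and averaged.
Encoders are created once from the config seed and shared across folds so
frozen encoding happens once per session.

## Synthetic cohorts

The generator emulates the structure of examination-room data, not
biomechanics: baseline motion is a per-joint mixture of low-frequency
(0.2–1.2 Hz) random-phase sinusoids around a per-subject jittered pose
template, plus out-and-back drift for walking protocols, a protocol-
appropriate facial excursion (eye vs mouth region), and white measurement
noise (σ = 0.5 units at scene scale 100). Voice is smooth per-channel MFCC
trajectories + noise. Cameras see affine-perturbed views of one underlying
trajectory with identical frame counts. Recording lengths are lognormal
per protocol with the published per-protocol mean/std (scaled by
`length_scale`, clipped to the staticizer-admissible range); uncertain
labels are injected at the published per-protocol rates and drop the face
payload (mask occlusion) or, for non-face protocols, the whole payload.
Cohort composition defaults to the published mix: prevalence 125/574,
patients split 62 stroke (site KUAH) / 63 PD (site SUSH), HC split 205/449
toward KUAH.

Disease archetypes (expression probability 0.9 per affected protocol, so
patients have genuinely normal protocols): PD — 5 Hz tremor at 5× the
measurement-noise σ, hypomimia 0.6, slowdown 1.5×, mild voice effect;
stroke — left-side motion damping 0.6, slowdown 1.4×, strong voice
perturbation. Abnormal protocol labels are set exactly where an effect
expressed, so auxiliary-label ground truth is known.

What passing tests show: the pipeline recovers planted, modality-specific
signals through frozen random encoders and calibrates to chance on
label-shuffled data. What they do not show: performance on real kinematic
data, robustness to landmark-extraction noise models, or the clinical
validity of the archetypes.

## Problem sizes and numerical choices

The heavy tests use a 200-subject tiny-preset cohort (two cameras,
sequences ≤ 150 frames, 16/32-dim encoder features) and full 3-fold
cross-validation at 50 epochs — minutes on one CPU; these sizes are the
package's desk-scale defaults, chosen so the full suite is routinely
runnable. Stochastic assertions are seed-pinned; the recovery threshold
(test AUC ≥ 0.9 per disease) and the chance band ([0.35, 0.65]) reflect
the planted-effect strength and test-set size. Batch norm uses ε = 1e-5
and momentum 0.1 with running statistics at eval; single-row batches
degenerate to the β offset. The autodiff engine is float64 throughout;
gradients are verified against central finite differences.

## Known limitations

- Encoders default to random frozen weights; pretraining is optional and
  synthetic. Real deployments would pretrain on large motion/speech
  corpora.
- The generator's voice effect is more linearly separable from raw
  statistics than from the frozen random voice features; voice protocols
  contribute less than landmark protocols to synthetic recovery.
- No attention-based aggregation, learning-rate schedules, or severity
  prediction; binary normality heads only.
- The HDF5 container mentioned as an interchange optimization is not
  implemented; CSV/JSON is canonical.
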