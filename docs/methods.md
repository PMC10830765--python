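# Methods

This note records the modeling choices behind `morphgcn`: the pipeline and
its assumptions, what the synthetic cohort generator does and does not
emulate, the numerical conventions, and the open design points we had to
settle.

## Pipeline

The unit of analysis is one T1-weighted scan, represented by vertex-level
cortical thickness with region labels from a parcellation atlas
(Desikan-Killiany 68, Destrieux 148, Glasser 360 regions). Upstream
surface reconstruction, registration and smoothing are out of scope: the
package starts from thickness tables.

1. **Features.** Each region is summarized by four moments
   x = (μ, σ, γ, k): mean (mm), SD (mm), skewness and non-excess
   kurtosis (unitless). The N×4 matrix X is the scan's feature matrix;
   row order follows the atlas and is the node identity everywhere
   downstream.
2. **Normalization** (optional, fitted per sex on healthy controls only).
   *Proportional*: OLS of whole-brain mean thickness on age; each scan is
   rescaled to the reference age 20 by the scalar α = Cth₂₀/Cth applied to
   μ and σ (the unitless γ, k pass through). *Residual*: per region and
   per moment, OLS on age; the corrected feature is the residual
   (predicted − observed).
3. **Graphs.** All pairwise region dissimilarities under the Mahalanobis
   or Taxicab distance form the adjacency; the lowest τ-quantile of each
   scan's distances is pruned (τ ∈ {0, 0.6, 0.7, 0.8}), fixing density
   per subject. Retained weights are the raw distances.
4. **Classifier.** Symmetrically normalized adjacency with unit
   self-loops; three 64-channel graph-convolution layers with ReLU and
   per-channel biases; global mean pooling; dropout 0.3 on the pooled
   vector; one affine head. 8835 trainable parameters for 3 classes.
5. **Evaluation.** Six clinical tasks; stratified group 5-fold CV at the
   patient level; support-weighted precision/recall/F1 (macro and
   per-class alongside); a 72-cell grid over
   atlases × distances × thresholds × normalizations.

## Assumptions

- Each patient carries one clinical-form label for all their scans;
  stratification operates on patients, and all scans of a patient share a
  fold (longitudinal repeats must never straddle the train/test split).
- Features are assumed finite; zero-variance regions get γ = k = 0 by
  convention so that distances stay defined.
- The Mahalanobis covariance S is estimated per scan from its N region
  vectors. A two-sample covariance is not defined, and the per-scan
  estimate both standardizes the four heterogeneous-scale moments and
  decorrelates them — the property that motivates this distance.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| τ rejection quantile | {0, 0.6, 0.7, 0.8} | – | grid values studied |
| reference age | 20 | years | youngest cohort age; correction target |
| min vertices per region | 10 | – | 4th moments of tiny samples are noise |
| covariance ridge | 1e-6·tr(S)/4 if cond > 1e8 | mm² | degenerate scans stay usable |
| GCN hidden width / layers | 64 / 3 | – | fixed architecture |
| dropout | 0.3 | – | after pooling |
| optimizer | Adam, lr 0.001 | – | fixed |
| epochs / batch | 300 / 16 | – | small model, desk scale |
| early stopping | patience 60 on a 25% grouped holdout, keep final weights | – | see below |

Early stopping is *stop-only*: training halts when the holdout loss has
not improved for `patience` epochs, keeping the weights of the last
epoch. Restoring the historical best was evaluated and rejected: the
holdout is a handful of patients, its loss is noisy, and snapping back to
a far-past state frequently restored near-initialization models whose
argmax is a constant class.

## The synthetic cohort generator

The generator emulates exactly the statistical structure the pipeline
relies on; everything else about real MRI is deliberately absent.

A vertex in region r of a scan is

    t = baseline[r] + slope[sex]·age + sex_offset[sex]
        − atrophy[label, r, vertex] + patient_intercept + scan_shift + noise

truncated at 0.5 mm. Defaults: per-region baselines drawn once, uniform
2.0–3.0 mm; healthy thinning −0.004 (F) / −0.005 (M) mm/year; male offset
−0.02 mm; patient random intercept SD 0.05 mm (this is what makes grouped
CV genuinely different from record-wise CV); scan-to-scan shift SD
0.02 mm; vertex noise SD 0.40 mm from a centred skew-normal (shape 4) so
the third and fourth moments carry real structure. Longitudinal schedule:
six-monthly for the first six scans, yearly after. Cohort composition
mirrors the study sizes: 42/21/28 RR/PP/SP patients with 299/143/218
scans, 21 protocol controls, and a 314-subject wide-age (20–86 y)
healthy reference.

**Class atrophy.** The defaults encode two clinical facts. First, the MS
forms differ in atrophy *severity*: RR is mildest and the progressive
forms accumulate substantially more cortical thinning, so the per-class
effect is a severity multiple (RR 1.0, PP 2.0, SP 3.0) of a base effect
(default: one between-subject SD of a region-mean feature) applied to a
distinct 10% subset of regions per form. Second, atrophy is *focal*: the
thinning concentrates in a sub-region (default half of the affected
region's vertices, each thinned by twice the nominal effect), which
leaves the region mean at the configured deficit while also raising its
variance and skewing its distribution — signatures that a patient-wide
mean offset cannot mimic. The severity gradient matters structurally: if
every form thinned same-sized disjoint subsets by identical amounts, the
forms' graphs would be identically distributed up to a node relabeling,
and *no* permutation-invariant graph classifier (global mean pooling
makes this GCN one) could separate them even in principle.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: scanner and site effects, lesions and their
segmentation artefacts, spatially correlated atrophy topographies,
non-linear aging, registration/parcellation error, or realistic spatial
autocorrelation of thickness along the surface. Results on this
simulator demonstrate that the pipeline's machinery is correct and can
recover the signal class it assumes, not that comparable F1 is reachable
on clinical cohorts.

## Benchmarks

The signal-recovery benchmark uses 20 patients per form, 5 scans each
(300 scans), Desikan-Killiany resolution with 500 vertices per region
(regions of that atlas have thousands of vertices in practice; the config
default of 200 is a lighter general-purpose setting), base effect one
between-subject SD in 10% of regions, residual normalization, Mahalanobis
distance, τ = 0.8 — the best-performing configuration family in the
original study — and grouped 5-fold CV per binary form-vs-form task. The
healthy reference for fitting uses 121 synthetic controls. These sizes
are the package's reference conditions; they run in minutes on one CPU.

The null control repeats the estimator on cohorts with the class effect
set to zero (10 patients per form, 3 scans each, 5 independent seeds) and
compares its weighted F1 against the *chance level of its own
predictions*, estimated by label permutation. Chance for weighted F1
depends on the predictor's output marginal — a constant predictor on
balanced binary data sits at 1/3, a coin-flip at 1/2 — and a
cross-entropy-trained network with no signal legitimately drifts toward
near-constant predictions, so the permutation level is the correct
no-association reference, not a fixed 1/C.

## Numerical conventions

- Moments are population (divide-by-n) estimators; kurtosis is
  non-excess; a `sample_adjusted` flag provides the bias-corrected
  variants. m₂ below (16·ε·max(1,|μ|))² is treated as exactly zero.
- The threshold quantile is numpy's linear-interpolation sample quantile
  of the scan's own upper-triangular distances; ties retained
  inclusively (d ≥ q); zero distances are never edges.
- The residual is *predicted − observed*, as the printed convention;
  `flip_sign` gives the usual orientation. The sign is irrelevant under
  the symmetric distances but is pinned for reproducibility.
- Training runs in float32 (halves matmul cost; ample precision here);
  gradient correctness is verified in float64 against central
  differences at 1e-6.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seed and config reproduce
  byte-identical cohort tables and bit-identical trained weights on a
  fixed BLAS/single-thread setup.

## Open points we settled

- **Fitting population for normalization:** healthy controls only (both
  control groups pooled), per sex; patient scans are corrected, never
  fitted on, to avoid leaking disease effect into the reference.
- **Feature standardization before Taxicab:** none — the four moments
  enter the distance at their natural scales, matching the printed
  formula (the magnitude imbalance this creates is a documented
  weakness of that distance).
- **Head architecture:** a single affine head after pooling; it is the
  only head consistent with the 8835-parameter total. A two-layer head
  exists behind a flag for ablation and breaks that total.
- **Edge semantics:** pruning removes the *lowest* distances (the most
  similar region pairs), and retained weights stay raw distances fed to
  the propagation rule as-is; self-loops get weight 1 from Ã = A + I.
- **MS-vs-HC fixed split:** test patients are selected whole per class
  until the per-class test scan quotas (24/10/8 MS; 21 + 24 controls)
  are met; a partially used patient's remaining scans are dropped rather
  than placed in training, so patient-group integrity holds exactly.

## Known limitations

- The numpy GCN is CPU-bound and single-device; it is sized for N ≤ 360
  graphs and a few hundred scans, not for large imaging studies.
- The stratified-group assignment is greedy (largest patients first,
  fold with fewest same-class scans wins); it is deterministic and
  well-balanced in practice but not optimal.
- Region-level (pre-summarized) input cannot produce a vertex-weighted
  whole-brain mean; the proportional model then falls back to the
  unweighted mean of region means with a logged warning.
- FreeSurfer `aparc.stats` tables carry only mean/SD and therefore
  cannot feed the 4-moment pipeline without externally supplied higher
  moments; the reader parses them but refuses silent degradation.
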