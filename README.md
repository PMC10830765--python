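# morphgcn

Classification of multiple-sclerosis (MS) clinical forms from brain
*morphological connectivity*: graphs built from cortical-thickness
dissimilarities between gray-matter regions, classified with a small
graph convolutional network (GCN).

MS evolves along distinct clinical courses — relapsing-remitting (RR),
secondary-progressive (SP) and primary-progressive (PP) — whose early
identification from conventional T1-weighted MRI would support
personalized care. Gray-matter atrophy, measured as cortical thinning, is
a sensitive marker of the neurodegenerative component of the disease.
`morphgcn` implements the full desk-side part of such a pipeline for
researchers in neuroimaging and machine learning: it consumes vertex-level
cortical-thickness tables (e.g. FreeSurfer output resampled to a
parcellation atlas) or generates fully synthetic cohorts, and carries them
through feature extraction, age/sex normalization, graph construction and
GCN classification with patient-grouped cross-validation.

## The model

For each scan, the cortical surface is parcellated into *N* regions
(Desikan-Killiany *N* = 68, Destrieux *N* = 148, or Glasser *N* = 360) and
each region's thickness distribution is summarized by four moments,

&nbsp;&nbsp;&nbsp;&nbsp;**x**ᵢ = (μᵢ, σᵢ, γᵢ, kᵢ),

giving a feature matrix X ∈ ℝ^{N×4}. Regions become graph nodes; edge
weights are pairwise dissimilarities, either the Mahalanobis distance
d_M(xᵢ,xⱼ) = ((xᵢ−xⱼ)ᵀ S⁻¹ (xᵢ−xⱼ))^{1/2} (S the per-scan covariance of
the N region vectors) or the Taxicab distance d_T(xᵢ,xⱼ) = Σₖ |xᵢₖ−xⱼₖ|.
A rejection quantile τ ∈ {0, 0.6, 0.7, 0.8} prunes the lowest distances
per scan, fixing graph density across subjects.

Two normalization schemes remove healthy aging effects, fitted per sex on
healthy controls only: *proportional* (whole-brain thickness regressed on
age, features rescaled to age 20 by α = Cth₂₀/Cth) and *residual* (per
region and per moment, the residual of an age regression).

The classifier applies the propagation rule
H^(l+1) = σ(D̃^{-1/2} Ã D̃^{-1/2} H^(l) W^(l)), Ã = A + I, with ReLU σ:
three 64-channel GCN layers, global mean pooling, dropout 0.3, and an
affine head — 8835 trainable parameters for a 3-class task. Evaluation
uses stratified *group* 5-fold CV (all scans of a patient stay in one
fold) over six clinical tasks (RR/PP, RR/SP, PP/SP, RR/PP+SP, the 3-way
task, MS/HC) and a 72-cell experiment grid
(3 atlases × 2 distances × 4 thresholds × 3 normalizations).

Since no torch build is required, the GCN (forward, backward, Adam) is
implemented directly in numpy and is bit-deterministic given a seed.

## Worked example

```python
import numpy as np
from morphgcn import (SimulationConfig, simulate_cohort,
                      simulate_healthy_reference, Parcellation,
                      build_feature_matrix, fit_residual, apply_residual,
                      build_adjacency, threshold_graph, TrainingConfig)
from morphgcn.evaluation import TASKS, cross_validate_task

cfg = SimulationConfig(atlas_size=68, vertices_per_region=200,
                       n_patients_per_class={"RR": 12, "PP": 12, "SP": 12, "HC": 12},
                       scans_per_patient=3, n_ixi_subjects=60, seed=7)
scans = [s for s in simulate_cohort(cfg) if s.label != "HC"]
healthy = simulate_healthy_reference(cfg)

parc = Parcellation.from_name("desikan-killiany")
feats = [build_feature_matrix(s, parc) for s in scans]
model = fit_residual(healthy, parc,
                     features=[build_feature_matrix(s, parc) for s in healthy])
rfeats = [apply_residual(f, s, model) for f, s in zip(feats, scans)]
graphs = [threshold_graph(build_adjacency(f, "mahalanobis"), 0.8,
                          node_features=f) for f in rfeats]

task = TASKS["RR_vs_SP"]
idx = [i for i, s in enumerate(scans) if s.label in task.label_map]
rep = cross_validate_task(
    [graphs[i] for i in idx],
    np.array([task.label_map[scans[i].label] for i in idx]),
    np.array([scans[i].patient_id for i in idx]),
    task.n_classes, TrainingConfig(), k=5, seed=7)
print(f"RR vs SP: F1 = {rep['summary']['mean_f1_weighted']:.3f} "
      f"± {rep['summary']['sd_f1_weighted']:.3f}")
```

prints (exactly, given the seed):

```
RR vs SP: F1 = 0.957 ± 0.036
```

i.e. the network separates the mild (RR) from the severely atrophic (SP)
synthetic form with mean weighted F1 0.957 across the five
patient-grouped folds. A command-line interface mirrors the library
(`morphgcn simulate / featurize / fit-norm / apply-norm / graph / train /
predict / evaluate / grid`); `morphgcn grid --dry-run` enumerates the
72-configuration experiment grid.

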