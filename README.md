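# refusion

Reference-guided fusion of multimodal brain-imaging features: multi-set
canonical correlation analysis with a scalar reference signal (MCCA-R)
plus joint ICA, with MDL model-order selection, FDR-corrected component
statistics, differential DNA-methylation testing, and subset
replication.

## The problem

Imaging-epigenetics studies ask whether a molecular marker — for
example, blood DNA-methylation of *NR4A1* at a promoter CpG — tracks a
pattern of brain alterations that is expressed coherently across
several MRI modalities (functional connectivity, fractional anisotropy,
gray matter volume) and differs between patients (e.g. temporal lobe
epilepsy) and controls.  Unsupervised fusion can find cross-modality
components but has no reason to rank the marker-related one first;
`refusion` instead lets the marker *guide* the decomposition.

Each modality k is a subjects x features matrix X_k modeled as
`X_k = A_k S_k + E_k` (loadings x sparse spatial sources + noise).
After whitening, per-modality weights W_k maximize

    J = Σ_{i<j} Σ_c corr(D_i[:,c], D_j[:,c])²  +  λ Σ_k Σ_c corr(D_k[:,c], ref)² ,

where D_k = Y_k W_k are canonical variates and `ref` is the per-subject
reference (methylation β at the target CpG); λ = 0 is plain multi-set
CCA, λ = 0.5 the default (selectable by cross-validation).  The
canonical maps are then rotated toward independence by joint ICA
(natural-gradient infomax), subject loadings are re-estimated on the
final maps, signs are aligned to the control > patient convention, and
every (component, modality) pair is tested for a group difference and a
reference correlation with Benjamini–Hochberg FDR over the
components x modalities family.  A component selected in every modality
is the *joint* component of interest.

No subject-level data accompany the study this package operationalizes,
so a first-class synthetic-data module generates cohorts with planted
ground truth (shared target loading, reference correlation, group
shift, clinical correlations, Beta-distributed methylation matrices),
and every stage is validated by parameter recovery against that truth.
See `docs/methods.md` for the full model description and
`FORMATS.md` for file formats.

## Worked example

The `analysis/` drivers run the whole study on a synthetic cohort
(33 patients / 40 controls, three modalities, one planted joint
component whose loading correlates −0.4 with the reference):

```bash
python analysis/01_simulate_cohort.py --seed 1 --out results
python analysis/02_fusion_analysis.py --seed 1 --out results
python analysis/03_methylation_analysis.py --seed 1 --out results
python analysis/04_subset_replication.py --seed 1 --out results
```

The fusion step prints (abridged):

```
MDL order for FA: 5
MDL order for FC: 5
MDL order for GMV: 5
fused with M = 5 components, lambda = 0.5
converged: MCCA=True, ICA=True

 component modality      t         p        q   r_ref     p_ref    q_ref  r_partial  selected
         0       FA  3.682 0.0004629 0.006078 -0.3732  0.001147 0.008599    -0.4231      True
         0       FC  3.509 0.0008104 0.006078 -0.3552  0.002047  0.01023    -0.3999      True
         0      GMV  3.302  0.001552 0.007758  -0.442 9.039e-05 0.001356    -0.4893      True
         1       FA 0.5021    0.6171   0.7121  0.0372    0.7547   0.9466    0.03526     False
         ...

joint components selected in all modalities: [0]
  reference correlations: FA: r=-0.373, FC: r=-0.355, GMV: r=-0.442
  clinical correlations of the selected loading:
    FA ~ onset_age: r=0.684 (p=1.1e-05, n=33)
    FA ~ MMSE: r=0.394 (p=0.00057, n=73)
```

Reading: the MDL criterion recovers the planted five-component order;
exactly one joint component (component 0) survives FDR for *both* the
group contrast and the reference correlation in all three modalities;
its loadings correlate negatively with the reference (higher
methylation, lower loading — the planted direction) and positively with
age of onset and cognition, as configured in the generator.  The
replication driver then shows the selected map is stable (|r| > 0.97 to
the full-cohort map) under two-thirds subsampling and a
lateralization-style patient split.

The same pipeline is exposed as a CLI (`refusion simulate|fuse|
replicate|stats|export-nifti`) for delimited-text or NIfTI inputs.

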