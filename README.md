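# nethom

Network-homogeneity (NH) analysis of resting-state fMRI networks, built
as a reproducible end-to-end pipeline: synthetic two-group BOLD cohorts
with known ground truth, temporal preprocessing with motion quality
control, group spatial ICA network-mask derivation, per-voxel NH,
covariate-adjusted voxel-wise group inference with permutation
cluster-level FWE correction, clinical correlation, and single-region
SVM classification.

## The scientific problem

Studies of large-scale brain networks (here, the default-mode network,
DMN) often ask whether a clinical group shows altered *coherence* of a
network rather than altered connectivity between two specific seeds.
Network homogeneity answers this at the voxel level: for the N voxels of
a network mask with time series x_1 … x_N,

    NH(i) = (1 / (N − 1)) · Σ_{j≠i} corr(x_i, x_j),

the mean Pearson correlation of voxel i with every other voxel of the
network. A group difference in NH localises where a patient group's
coupling to the rest of the network is raised or lowered — for example
an anterior increase (medial prefrontal cortex) together with a
posterior decrease (posterior cingulate / precuneus), the "dissociation
pattern" reported in mood-disorder cohorts. Regional NH means are then
correlated with clinical variables (serum lipids, cognitive scores) and
fed to a leave-one-out RBF-SVM to assess single-region diagnostic value.

Because clinical rs-fMRI datasets of this kind are rarely deposited, the
package ships a first-class synthetic-cohort generator whose ground
truth (network geometry, planted signed NH effects, motion levels,
phenotype correlations) makes every downstream stage testable against
closed-form or simulation oracles.

## Worked example

`analysis/` holds numbered drivers that run the whole study on a
synthetic cohort at a realistic clinical-study scale (43 patients recruited, 3
excluded for excessive head movement, 37 controls; 100 volumes at
TR = 2 s):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_preprocess_qc.py      # "77/80 subjects retained; 3 excluded"
python analysis/03_derive_network_mask.py
python analysis/04_network_homogeneity.py
python analysis/05_group_inference.py
python analysis/06_clinical_correlations.py
python analysis/07_classification.py
```

On this cohort the drivers print (abridged):

```
derived mask: 392 voxels; Dice vs ground truth = 1.000

   cluster         direction  peak_x_mm  peak_y_mm  peak_z_mm  extent_voxels   peak_t    p_fwe
cluster_01 patients>controls        7.5       10.5       10.5            144 14.74810 0.003996
cluster_02 patients<controls        4.5      -13.5       -1.5            122 -9.38977 0.003996

    region  sensitivity  specificity  accuracy sens_counts spec_counts acc_counts
cluster_01         95.0      97.2973   96.1039       38/40       36/37      74/77
cluster_02         92.5      78.3784   85.7143       37/40       29/37      66/77
```

Reading: group ICA on control runs alone recovers the planted network
exactly; the voxel-wise GLM (age and mean framewise displacement as
covariates, 1000 label permutations, cluster-level FWE p < 0.05 with a
×2 sign correction) finds exactly one NH increase and one NH decrease
in patients, coinciding with the planted regions; and either region's
mean NH separates the groups well under leave-one-out SVM
cross-validation. The correlation driver additionally contrasts
measured-NH correlations with those against the generator's true
regional NH, making measurement attenuation visible (see
`docs/methods.md`).

The same pipeline is scriptable through a config file:

```bash
nethom run --config configs/demo.yaml        # or any single stage:
nethom simulate --config configs/demo.yaml
```

All tabular outputs are TSV; volumes are NIfTI-1; voxel indices are
0-based and converted to RAS+ millimetres through the volume affine.

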