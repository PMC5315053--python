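# hubspoke

A phantom-validated Python pipeline for the fMRI analyses used to dissociate
**amodal semantic coding** from **input-modality coding** in cortex — the
central prediction of the hub-and-spoke model of semantic memory, in which
modality-specific "spoke" regions and an amodal anterior-temporal "hub"
jointly represent concepts.

The package is for neuroimaging researchers who need this analysis chain as
reusable, tested library code: a block-design GLM with a double-gamma HRF,
cross-modal searchlight MVPA with leave-one-run-out cross-validation and
cluster-corrected group inference, seed-based resting-state connectivity
with CompCor nuisance regression, and meta-analytic spatial-map decoding.
Because the original human data are not available in raw form, the package
ships a first-class synthetic-data module: phantoms whose generative ground
truth *is* the hub-and-spoke hypothesis, so every stage can be verified
end to end against what was planted.

## The analyses

**Cross-decoding.** Per run, per condition beta maps from the GLM are
z-scored per voxel within each run and classified inside 6 mm-radius
searchlight spheres (123 voxels on the 2 mm grid) by a linear SVM (LIBSVM,
C = 1) with leave-one-run-out folds. Two schemes isolate the two codes:

- *semantic-feature*: train auditory- vs visual-feature words (e.g. "loud"
  vs "shiny") on spoken items, test on written items, and vice versa — only
  format-independent meaning information can support accuracy above the 50%
  chance level;
- *perceptual*: train spoken vs written on meaningless non-words, test on
  words — only meaning-free format information can.

Smoothed accuracy maps (6 mm FWHM) are tested against chance across
subjects with a one-sample t → z map, clusters formed at z ≥ 2.3 and
family-wise error controlled by a max-cluster-mass sign-flip permutation
null. Region × classifier accuracies enter a 2×2 repeated-measures ANOVA
whose interaction is the dissociation test.

**Connectivity.** Rest runs are cleaned by regressing out 5 CompCor
principal components (from WM/CSF voxel time series) plus 6 motion
parameters, then Gaussian band-filtered (σ = 100 s high-pass, 2.8 s
low-pass). Fisher-z seed-correlation maps from small spherical seeds are
contrasted pairwise at the group level with the same permutation machinery,
and thresholded maps are quantified by overlap with template networks.

**Decoding.** Any statistic map is ranked against a library of term maps by
Pearson spatial correlation; the top/bottom-15 terms characterize it.

## Worked example

Simulate four phantom subjects and run both searchlights over the two
planted regions (`examples/03_cross_modal_searchlight.py`):

```
semantic_feature : hub 0.674   modality region 0.480
perceptual       : hub 0.481   modality region 0.634
```

Each number is the mean sphere accuracy in a region; 0.5 is chance. The hub
decodes word meaning across presentation formats but not the format itself,
and the modality region shows the mirror image — the planted double
dissociation. At cohort level (`examples/04_group_dissociation.py`, 12
subjects, 400 permutations):

```
fraction of each planted region covered by significant clusters:
  semantic_feature  hub 1.00   modality 0.00
  perceptual        hub 0.04   modality 1.00

ANOVA (region x classifier), F(1, 11):
                    F       p  df1   df2
region         0.2275  0.6427  1.0  11.0
classifier     3.0098  0.1107  1.0  11.0
interaction  137.7817  0.0000  1.0  11.0
```

The significant clusters of each classifier are confined to "its" region,
and the region × classifier interaction (with both simple effects, p ≈
.0005) confirms the dissociation statistically. The connectivity analogue
(`examples/05_resting_connectivity.py`) recovers both planted resting
networks and shows CompCor cutting spurious off-network coupling:

```
mean off-network |z|: 0.275 without CompCor, 0.097 with CompCor
```

The other examples cover the phantom and design generator (01), percent
signal change (02), meta-analytic decoding (06) and the one-config
end-to-end pipeline with its output manifest (07).

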