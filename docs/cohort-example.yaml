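# Example cohort configuration for `fma run --config cohort.yaml --out results/`
# Re-enacts the two-arm remnant-kidney comparison on synthetic animals.
seed: 1
scale: coarse              # "full" = native 0.73/0.8141 µm voxels (slower)
n_glomeruli_per_animal: 6
measure_cortex: true
cortex_n_glomeruli: 2
groups:
  - name: sham
    preset: sham
    n_animals: 5
  - name: snx
    preset: snx
    n_animals: 5
segmentation:
  method: otsu
  min_voxels: 27
  connectivity: 26
variability:
  semi_axes_cv: 0.05
  density_cv: 0.05
  dropout_sd: 0.03
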