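# Full-pipeline configuration example.
#
# mode: "simulate" runs the folded-ribbon cohort simulator; "volumes"
# instead takes a subject list of labeled NIfTI files plus an atlas
# mapping (see atlas_example.json) and measures every atlas region.
mode: simulate
seed: 7
methods: [BC, MB]        # subset of the two FD estimators
out_dir: ribbonfd_out
log_level: INFO

cohort:
  seed: 7
  # (group, sex) cell sizes of the emulated study design
  n_per_cell:
    adolescent/female: 11
    adult/female: 7
    adolescent/male: 6
    adult/male: 7
  # per-group folded-ribbon parameter distributions as [mean, sd]
  effect:
    adolescent: {fold_frequency: [6.0, 0.5], thickness: [2.0, 0.1], size: [48.0, 0.0]}
    adult:      {fold_frequency: [5.0, 0.5], thickness: [2.0, 0.1], size: [48.0, 0.0]}

# volumes-mode alternative:
# mode: volumes
# atlas_path: examples/atlas_example.json
# subjects:
#   - {subject_id: s01, group: adolescent, sex: female, path: data/s01_labels.nii.gz}
#   - {subject_id: s02, group: adult,      sex: female, path: data/s02_labels.nii.gz}
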