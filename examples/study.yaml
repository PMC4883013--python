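# Demo study configuration: full synthetic loop at a reduced cohort size.
# Run with:  subfieldstats run --config examples/study.yaml --out demo_out
seed: 0
n_mz_pairs: 60
n_dz_pairs: 60
retest_n_subjects: 120
retest_target_icc: 0.9
version_correlation: 0.8
version_scale: 1.0
dice_offset: [2, 0, 0]
ci_level: 0.95
alpha: 0.05
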