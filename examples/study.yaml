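# Four-group synthetic study: three CSR-like groups and one columnar group.
# Run with:  stereocol run --config examples/study.yaml
groups:
  C:
    n_subjects: 4
    pattern: {kind: columnar, line_intensity: 5.0e-4, points_per_line: 20, column_sd: 3.0}
  MDD:
    n_subjects: 4
    pattern: {kind: columnar, line_intensity: 5.0e-4, points_per_line: 20, column_sd: 3.0}
  SU:
    n_subjects: 4
    pattern: {kind: csr, n_points: 400}
  SCH:
    n_subjects: 4
    pattern: {kind: hardcore, proposal_intensity: 1.0e-4, hardcore_r: 10.0}
window: [200.0, 200.0, 200.0]
radii: [5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0]
half_length: 50.0
n_sim: 999
n_perm: 999
level: 0.95
seed: 7
outdir: scratch/study-out
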