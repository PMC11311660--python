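# Bicalutamide in CDCl3 against the computed-conformer ensemble.
solvent: CDCl3
distance_table: builtin:qc
reference_pair: H12a-H12b
marker_pair: H12b-H14/18
classification:
  criterion: explicit
  open: [BCL-3, BCL-4, BCL-5, BCL-8, BCL-9, BCL-10]
  closed: [BCL-1, BCL-2, BCL-6, BCL-7]
sigma_reference: {value: 2.46e-1, stderr: 1.5e-2}
sigma_marker: {value: 2.35e-3, stderr: 7.0e-5}
uncertainty: {n_draws: 100000, seed: 0}
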