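# Bicalutamide in DMSO-d6 against the computed-conformer ensemble.
# The marker rate stores the exponent-corrected value (see
# data/cross_relaxation_rates.csv).
solvent: DMSO-d6
distance_table: builtin:qc
reference_pair: H15/17-H14/18
marker_pair: H12b-H14/18
classification:
  criterion: explicit
  open: [BCL-3, BCL-4, BCL-5, BCL-8, BCL-9, BCL-10]
  closed: [BCL-1, BCL-2, BCL-6, BCL-7]
sigma_reference: {value: 1.29e-2, stderr: 9.0e-4}
sigma_marker: {value: 3.12e-3, stderr: 1.3e-4}
uncertainty: {n_draws: 100000, seed: 0}
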