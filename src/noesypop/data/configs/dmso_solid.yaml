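# Bicalutamide in DMSO-d6 against the deposited solid-state/bioactive
# structures. The inversion is expected to be infeasible here: the ISPA
# distance falls outside the range the crystallographic families span.
solvent: DMSO-d6
distance_table: builtin:solid
reference_pair: H14/18-H15/17
marker_pair: H12b-H14/18
classification:
  criterion: marker_distance
  threshold: 3.85
sigma_reference: {value: 1.29e-2, stderr: 9.0e-4}
sigma_marker: {value: 3.12e-3, stderr: 1.3e-4}
uncertainty: {n_draws: 100000, seed: 0}
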