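# Bicalutamide in CDCl3 against the deposited solid-state/bioactive
# structures; families assigned by the marker-distance rule.
solvent: CDCl3
distance_table: builtin:solid
reference_pair: H12a-H12b
marker_pair: H12b-H14/18
classification:
  criterion: marker_distance
  threshold: 3.85
sigma_reference: {value: 2.46e-1, stderr: 1.5e-2}
sigma_marker: {value: 2.35e-3, stderr: 7.0e-5}
uncertainty: {n_draws: 100000, seed: 0}
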