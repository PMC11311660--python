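# Model-averaged inter-group distances (A) for the ten computed bicalutamide
# conformers (APFD/6-311++g(2d,2p) gas-phase geometries, slow-motion r^-6
# member averaging). H12a-H12b and H15/17-H14/18 are conformation-independent
# reference pairs; H12b-H14/18 is the conformation-determining marker.
conformer,H12a-H12b,H15/17-H14/18,H12b-H14/18
BCL-1,1.78,2.81,4.33
BCL-2,1.78,2.80,4.31
BCL-3,1.79,2.81,3.44
BCL-4,1.79,2.81,3.45
BCL-5,1.78,2.81,3.62
BCL-6,1.77,2.78,4.11
BCL-7,1.77,2.79,4.11
BCL-8,1.77,2.81,3.34
BCL-9,1.78,2.81,3.61
BCL-10,1.77,2.81,2.97
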