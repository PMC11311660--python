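# Relative gas-phase conformer energies (kJ/mol) for bicalutamide,
# APFD/6-311++g(2d,2p).
conformer,dE_gas
BCL-1,0.00
BCL-2,1.35
BCL-3,25.59
BCL-4,26.01
BCL-5,29.71
BCL-6,30.05
BCL-7,30.26
BCL-8,30.30
BCL-9,30.61
BCL-10,31.02
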