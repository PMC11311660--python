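# Inter-group distances (A) measured on deposited bicalutamide structures:
# polymorphs (JAYCES01 form I, JAYCES02 form II), single crystal (JAYCES),
# DMSO solvate (FAHFIG), co-crystals (KIHZOR, KIHZIL), and the androgen-
# receptor-bound bioactive form (PDB 1Z95).
structure,H12a-H12b,H14/18-H15/17,H12b-H14/18
JAYCES01,1.56,2.60,3.53
JAYCES02,1.56,2.59,4.25
FAHFIG,1.56,2.59,3.16
KIHZOR,1.56,2.61,4.33
KIHZIL,1.57,2.60,3.43
1Z95,1.85,2.76,4.03
JAYCES,1.58,2.62,3.49
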