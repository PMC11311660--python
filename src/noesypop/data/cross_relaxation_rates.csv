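# PANIC/IRA cross-relaxation rates (s^-1) for bicalutamide at 500.17 MHz,
# 25 C. The DMSO-d6 marker rate appears in the source report as 3.12e-2 s^-1,
# which is inconsistent with the accompanying ISPA distance of 3.55 A and the
# reported populations; both are reproduced by 3.12e-3 s^-1, so the corrected
# exponent is stored here (see the note column).
solvent,pair_id,role,sigma,stderr,note
CDCl3,H12a-H12b,reference,2.46e-1,1.5e-2,
CDCl3,H12b-H14/18,marker,2.35e-3,7e-5,
DMSO-d6,H15/17-H14/18,reference,1.29e-2,9e-4,
DMSO-d6,H12b-H14/18,marker,3.12e-3,1.3e-4,exponent corrected from reported 3.12e-2
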