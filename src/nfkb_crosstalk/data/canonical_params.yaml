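# Canonical NF-kB crosstalk model parameters, version 1.
# Calibrated against constraints C1-C6 (see calibrate.py and docs/methods.md).
# Units: per-minute rates; bimolecular rates per (a.u. * minute).
k_syn_A: 0.05
k_syn_C: 0.05
k_syn_RelB: 0.05
k_deg_A: 0.0005
k_deg_C: 0.0005
k_deg_RelB: 0.005
k_deg_Bnuc: 0.005
k0_Ia: 0.15
k0_Ie: 0.08
k0_p100: 0.0002
g_Ia: 0.05
g_Ie: 0.01
g_p100: 0.18
h: 4.0
K_tx: 6.0
kb_Ia_A: 0.1
kb_Ia_C: 0.01
kb_Ie_A: 0.03
kb_Ie_C: 0.3
kb_Id_A: 0.01
kb_Id_C: 0.3
ku_Ia_A: 0.001
ku_Ia_C: 0.001
ku_Ie_A: 0.001
ku_Ie_C: 0.001
ku_Id_A: 0.001
ku_Id_C: 0.0001
d0_Ia: 0.0001
d0_Ie: 0.0001
d0_Id: 0.001
d_ikk_Ia: 2.0
d_ikk_Ie: 2.0
k_proc: 0.0004
k_syn_NIK: 0.01
k_deg_NIK: 0.01
k_in_A: 0.01
k_out_A: 0.05
k_in_C: 0.01
k_out_C: 0.05
b: 0.0005
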