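# Canonical SM-cell parameter set (calibrated defaults).
# Units: time s, voltage mV, current pA, conductance nS, capacitance pF,
# concentration mM.
C_m: 50.0          # membrane capacitance (pF)
F: 96.485          # Faraday constant (C/mmol)
vol_cyto: 1.0      # cytosolic volume fraction
f_c: 0.01          # free (unbuffered) Ca2+ fraction
E_ca: 60.0         # Ca2+ reversal (mV)
E_k: -75.0         # K+ reversal (mV)
E_na: 55.0         # Na+ reversal (mV)
E_nscc: 0.0        # non-selective cation reversal (mV)
g_cal: 0.6         # L-type Ca2+ conductance (nS)
g_lva: 0.05        # low-voltage-activated Ca2+ conductance (nS)
g_na: 0.25         # Na+ conductance (nS)
g_kv: 1.2          # delayed-rectifier K+ conductance (nS)
g_ka: 0.25         # A-type K+ conductance (nS)
g_bk: 1.5          # Ca2+-activated K+ conductance (nS)
g_kbg: 0.4         # background K+ conductance (nS)
g_bgns: 0.156      # background non-selective leak conductance (nS)
g_nscc: 2.0        # muscarinic-modulated NSCC conductance (nS)
r_lig: 0.1         # muscarinic ligand activity, uniform across cells
K_nscc_ca: 0.001   # Ca2+ half-inhibition of NSCC (mM)
n_ca: 4.0          # NSCC Ca2+ Hill coefficient
K_fca: 0.0005      # Ca2+ half-inactivation of L-type (mM)
K_bk: 0.001        # Ca2+ half-activation of BK (mM)
v_ex: 0.08         # maximal Ca2+ extrusion rate (mM/s)
k_ex: 0.0003       # extrusion half-activation (mM)
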