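# Canonical ICC parameter set (calibrated defaults).
# Units: time s, voltage mV, current pA, conductance nS, capacitance pF,
# concentration mM.
C_m: 25.0          # membrane capacitance (pF)
F: 96.485          # Faraday constant (C/mmol)
vol_cyto: 0.7      # cytosolic volume fraction
vol_ss: 0.01       # submembrane-space volume fraction
vol_er: 0.00185    # endoplasmic-reticulum volume fraction
vol_mito: 0.05     # mitochondrial volume fraction
f_c: 0.01          # free (unbuffered) Ca2+ fraction
E_ca: 60.0         # Ca2+ reversal (mV)
E_k: -75.0         # K+ reversal (mV)
E_na: 55.0         # Na+ reversal (mV)
E_nscc: 0.0        # non-selective cation reversal (mV)
E_cl: -20.0        # Cl- reversal (mV)
g_ltype: 0.4       # L-type Ca2+ conductance (nS)
g_vddr: 0.25       # dihydropyridine-resistant Ca2+ conductance (nS)
g_lva: 0.05        # low-voltage-activated Ca2+ conductance (nS)
g_na: 0.3          # Na+ conductance (nS)
g_kv: 1.6          # delayed-rectifier K+ conductance (nS)
g_kr: 0.6          # rapid K+ conductance (nS)
g_ka: 0.3          # A-type K+ conductance (nS)
g_erg: 0.8         # ERG K+ conductance (nS)
g_bk: 2.0          # Ca2+-activated K+ conductance (nS)
g_cl: 0.3          # Ca2+/voltage-activated Cl- conductance (nS)
g_kbg: 0.4         # background K+ conductance (nS)
g_nscc: 5.0        # non-selective cation conductance (nS)
K_nscc: 0.0004     # Ca_SS half-activation of NSCC (mM)
n_nscc: 6.0        # NSCC Hill coefficient
K_fca: 0.0003      # Ca_i half-inactivation of L-type (mM)
K_bk: 0.001        # Ca_i half-activation of BK (mM)
k_inh: 0.005       # IP3R high-Ca2+ inhibition constant (mM)
d1: 0.00013        # IP3R IP3 binding constant (mM)
d2: 0.001049       # IP3R Ca2+ inactivation constant (mM)
d3: 0.0009434      # IP3R IP3 modulation constant (mM)
d5: 0.00008234     # IP3R Ca2+ activation constant (mM)
a2: 200.0          # IP3R inactivation rate (1/(mM s))
v_ip3r: 900.0      # maximal IP3R release rate (1/s)
v_erleak: 11.0     # ER leak rate (1/s)
v_serca: 0.486     # maximal SERCA uptake (mM/s)
k_serca: 0.0001    # SERCA half-activation (mM)
v_uni: 0.004       # mitochondrial uniporter maximum (mM/s)
k_uni: 0.0008      # uniporter half-activation (mM)
v_naca: 0.0004     # mitochondrial Na+/Ca2+ exchanger maximum (mM/s)
k_naca: 0.0005     # exchanger half-activation (mM)
k_leak: 0.0002     # submembrane-to-cytosol leak rate (1/s)
v_pmca: 0.08       # plasma-membrane Ca2+ pump maximum (mM/s)
k_pmca: 0.0003     # pump half-activation (mM)
P_MV: 0.0002       # maximal voltage-dependent IP3 synthesis (mM/s)
k_V: 35.0          # synthesis half-inactivation voltage (mV)
eta: 0.03          # linear IP3 degradation rate (1/s)
V_m4: 0.0004       # nonlinear IP3 degradation maximum (mM/s)
k_4: 0.0009        # nonlinear degradation half-activation (mM)
beta: 0.00001993   # innervation IP3 production rate, mid-gradient (mM/s)
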