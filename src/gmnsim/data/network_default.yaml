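# Canonical chain configuration: 42 oscillatory units over 6 cm
# (about 7 cells/cm) under a linearly decreasing innervation gradient.
n_units: 42
length_cm: 6.0
g_icc_icc: 0.7          # ICC-ICC gap-junction conductance (nS)
p_ip3: 8.0              # ICC-ICC IP3 permeability (1/s)
p_ca: 0.8               # ICC-ICC Ca2+ permeability (1/s)
g_coup: 0.5             # ICC->SM conductance (nS)
g_sm_sm: 0.2            # SM-SM gap-junction conductance (nS)
beta_rostral: 0.0000265 # innervation drive at cell 1 (mM/s)
beta_caudal: 0.00001336 # innervation drive at cell N (mM/s)
enable_electrical: true
enable_ca: true
enable_ip3: true
variability: 0.0        # fractional coupling variability in [0, 1]
seed: 0
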