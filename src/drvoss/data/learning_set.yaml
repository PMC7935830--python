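# Learning-set population parameter estimates for the darunavir
# one-compartment model (reduced model without AAG).
cl_pop: 12.6       # CL/F, L/h
v_pop: 137.0       # V/F, L
ka_pop: 0.545      # 1/h
theta_sex: -0.198       # proportional effect on CL (female)
theta_cyp3a5: -0.192    # proportional effect on CL (CYP3A5 non-expresser)
theta_slco3a1: 0.991    # proportional effect on V (SLCO3A1 T-carrier)
omega_cl: 0.238    # log-scale IIV SD
omega_v: 0.353
omega_ka: 0.575
sigma_exp: 0.306   # exponential residual SD
sigma_add: 0.611   # additive residual SD, mg/L
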