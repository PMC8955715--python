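# Default population PK model for adult intravenous vancomycin.
# theta_cl_slope was least-squares calibrated against the 36 printed day-2
# AUC cells of the renal-function dosing nomogram with v_pop fixed at 60.7 L
# (see vancotdm.dosing.calibrate_cl_slope; max relative residual 1.3%).
# Between-subject and residual variability are package defaults, not
# published estimates.
theta_cl_slope: 0.0496095
theta_cl_intercept: 0.0
v_pop: 60.7
omega2_cl: 0.1225   # (omega_CL = 0.35)
omega2_v: 0.0625    # (omega_V = 0.25)
sigma_prop: 0.10
sigma_add: 0.5      # mg/L
clcr_cap: 130.0     # mL/min
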