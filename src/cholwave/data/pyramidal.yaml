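# Cortical pyramidal cell with an ACh-regulated slow potassium (M-type) current.
# All voltages in mV, conductances in mS/cm^2, times in ms, capacitance in uF/cm^2.
# gKs_max is the cholinergic control parameter (high ACh -> low gKs_max) and is
# usually overridden per experiment; I_tune is recalibrated per gKs_max.
cm: 1.0
gNa_max: 24.0
gKdr_max: 3.0
gKs_max: 0.0
gl: 0.02
ENa: 55.0
EK: -90.0
El: -60.0
I_tune: 0.0

# Gate x has steady state x_inf(V) = 1/(1 + exp((alpha_x - V)/beta_x)) and,
# unless tau is fixed, time constant tau_x(V) = 0.37 + D_x/(1 + exp((gamma_x + V)/eps_x)).
alpha_m: -30.0
beta_m: 9.5

alpha_h: -53.0
beta_h: -7.0
gamma_h: 40.5
eps_h: 6.0
D_h: 2.78

alpha_n: -30.0
beta_n: 10.0
gamma_n: 27.0
eps_n: 15.0
D_n: 1.85

alpha_s: -39.0
beta_s: 5.0
tau_s: 75.0

# Double-exponential conductance synapse, kernel normalized to unit peak.
syn_tau_F: 0.3
syn_tau_D: 1.0
syn_tau_S: 3.0
E_syn_exc: 0.0
E_syn_inh: -75.0
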