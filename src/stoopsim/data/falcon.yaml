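# Peregrine falcon (Falco peregrinus) flight morphology.
# Field names mirror the model's symbol table; SI units throughout.
species: peregrine_falcon
f: 5.1                 # max wingbeat frequency (Hz)
l_w: 0.284             # wing length (m)
b_max: 0.873           # max wing span (m)
m_b: 528.0e-3          # body mass (kg)
m_w: 32.0e-3           # single-wing mass (kg)
I_b: 448.0e-6          # body roll inertia (kg m^2)
I_wing: 296.6e-6       # single-wing inertia about the shoulder (kg m^2)
J: 2501.3e-6           # wing mass-moment sum, sum_i m_i r_i (kg m)
S_w_max: 89.7e-3       # wing area at full span (m^2)
AR_max: 8.49           # aspect ratio at full span
theta_over_pi: 0.4     # angular flapping amplitude, units of pi rad
S_b: 4.275e-3          # frontal body area (m^2)
c_d_body: 0.14         # body drag coefficient
c_d_fric_ref: 14.0e-3  # reference wing friction drag coefficient
v_thresh: 16.5         # airspeed where muscle torque constrains thrust (m/s)
c_l_max: 1.6           # max steady lift coefficient
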