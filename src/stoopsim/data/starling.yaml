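# Common starling (Sturnus vulgaris) flight morphology.
species: common_starling
f: 10.5
l_w: 0.185
b_max: 0.39
m_b: 70.0e-3
m_w: 3.7e-3
I_b: 15.65e-6
I_wing: 14.55e-6
J: 152.8e-6
S_w_max: 24.14e-3
AR_max: 6.40
theta_over_pi: 0.47
S_b: 2.1e-3
c_d_body: 0.24
c_d_fric_ref: 9.35e-3
v_thresh: 11.62
c_l_max: 1.6
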