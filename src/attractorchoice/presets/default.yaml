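# Default competitive attractor network: 1600 pyramidal cells (two selective
# pools of 240), 400 interneurons, conductance-based exponential
# integrate-and-fire neurons, Euler integration at 0.5 ms.
n_pyramidal: 1600
n_selective: 240
n_interneurons: 400
architecture: attractor
dt: 0.5
synaptic_update: add
# synaptic contacts per realized connection (dense-equivalent calibration)
contacts_ee: 12.5
contacts_ei: 6.8
contacts_ie: 7.0
contacts_ii: 20.0
w_plus: 1.48
ampa_rec_scale: 2.0
nonselective_policy: passive
connectivity:
  p_pyr_recurrent: 0.08
  p_int_recurrent: 0.1
  p_pyr_to_int: 0.1
  p_int_to_pyr: 0.2
  delay: 0.5
neurons:
  pyramidal:
    {C: 0.5, g_L: 25.0, E_L: -70.0, Delta_T: 3.0, V_T: -55.0, V_s: -20.0, V_r: -53.0, tau_r: 2.0}
  interneuron:
    {C: 0.2, g_L: 20.0, E_L: -70.0, Delta_T: 3.0, V_T: -55.0, V_s: -20.0, V_r: -53.0, tau_r: 1.0}
synapses:
  - {kind: AMPA_ext, target: pyramidal, G: 1.6, tau: 2.0}
  - {kind: AMPA_ext, target: interneuron, G: 1.6, tau: 2.0}
  - {kind: AMPA_background, target: pyramidal, G: 2.1, tau: 2.0}
  - {kind: AMPA_background, target: interneuron, G: 1.53, tau: 2.0}
  - {kind: AMPA_recurrent, target: pyramidal, G: 0.05, tau: 2.0}
  - {kind: AMPA_recurrent, target: interneuron, G: 0.04, tau: 2.0}
  - {kind: NMDA, target: pyramidal, G: 0.145, tau_1: 2.0, tau_2: 100.0, Mg: 1.0}
  - {kind: NMDA, target: interneuron, G: 0.13, tau_1: 2.0, tau_2: 100.0, Mg: 1.0}
  - {kind: GABA_A, target: pyramidal, G: 1.3, tau: 5.0}
  - {kind: GABA_A, target: interneuron, G: 1.0, tau: 5.0}
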