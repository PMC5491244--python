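# THOR-like default beam model, pre-calibrated so the advantage depth
# (tumor curve crossing the normal-tissue maximum, T/N 3.5) is 8.5 cm.
# Amplitudes are Gy/min at 1.2 MW; lengths in cm; boron reference 25 ppm.
beam:
  thermal_amplitude_gy_min: 0.06
  fast_amplitude_gy_min: 0.08
  photon_amplitude_gy_min: 0.14
  b10_amplitude_gy_min: 0.36
  neutron_decay_cm: 4.021067229003073
  neutron_buildup_cm: 1.0
  fast_decay_cm: 1.6
  photon_decay_cm: 5.0
  photon_buildup_cm: 0.9
  neutron_lateral_half_width_cm: 4.5
  collimator_diameter_cm: 14.0
  penumbra_cm: 0.5
  reference_power_mw: 1.2
  reference_flux_n_cm2_s: 1280000000.0
  reference_boron_ppm: 25.0
radiobiology:
  drsf_thermal: 0.64
  drsf_fast: 1.39
  drsf_photon: 0.96
  drsf_b10: 0.65
  rbe_thermal: 3.2
  rbe_fast: 3.2
  rbe_photon: 0.5
  cbe_tumor: 3.8
  cbe_brain: 1.3
  tn_ratio: 3.5
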