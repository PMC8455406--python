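# Average-response tri-layered wall model of the porcine upper thoracic
# aorta: layer-specific HGO parameters fitted to the average uniaxial
# mechanical response, modelled layer prestretches, and mean geometry.
geometry:
  unloaded_internal_radius_mm: 8.66
layers:
  intima:
    thickness_mm: 0.33
    params: {mu_kpa: 23.5, c1_kpa: 124.7, c2: 11.0, alpha_deg: 39.5, rho: 0.24}
    prestretch: {circ: 1.01, ax: 0.99}
  media:
    thickness_mm: 1.35
    params: {mu_kpa: 22.3, c1_kpa: 134.8, c2: 9.5, alpha_deg: 33.4, rho: 0.24}
    prestretch: {circ: 1.02, ax: 0.99}
  adventitia:
    thickness_mm: 0.61
    params: {mu_kpa: 21.2, c1_kpa: 25.7, c2: 67.3, alpha_deg: 42.9, rho: 0.18}
    prestretch: {circ: 0.95, ax: 1.04}
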