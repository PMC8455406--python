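# Per-animal layer-specific HGO parameters of the ten porcine upper
# thoracic aortas (mu kPa, c1 kPa, c2 -, alpha deg, rho -), fitted to each
# animal's uniaxial circumferential and axial responses.  Group results
# are means of the per-animal models.
samples:
  I:
    intima:     {mu_kpa: 31.1, c1_kpa: 119.2, c2: 17.5, alpha_deg: 40.8, rho: 0.24}
    media:      {mu_kpa: 19.8, c1_kpa: 200.4, c2: 7.7,  alpha_deg: 40.3, rho: 0.21}
    adventitia: {mu_kpa: 26.0, c1_kpa: 156.4, c2: 26.2, alpha_deg: 45.7, rho: 0.21}
  II:
    intima:     {mu_kpa: 22.3, c1_kpa: 158.1, c2: 4.7,  alpha_deg: 40.2, rho: 0.21}
    media:      {mu_kpa: 21.8, c1_kpa: 103.4, c2: 6.5,  alpha_deg: 27.0, rho: 0.26}
    adventitia: {mu_kpa: 15.6, c1_kpa: 95.3,  c2: 28.2, alpha_deg: 39.5, rho: 0.23}
  III:
    intima:     {mu_kpa: 22.8, c1_kpa: 121.0, c2: 4.3,  alpha_deg: 33.0, rho: 0.23}
    media:      {mu_kpa: 21.5, c1_kpa: 129.0, c2: 6.1,  alpha_deg: 20.4, rho: 0.26}
    adventitia: {mu_kpa: 17.3, c1_kpa: 51.5,  c2: 48.3, alpha_deg: 46.1, rho: 0.22}
  IV:
    intima:     {mu_kpa: 26.9, c1_kpa: 78.9,  c2: 15.4, alpha_deg: 44.7, rho: 0.27}
    media:      {mu_kpa: 19.0, c1_kpa: 163.6, c2: 3.6,  alpha_deg: 33.0, rho: 0.23}
    adventitia: {mu_kpa: 27.3, c1_kpa: 84.4,  c2: 28.6, alpha_deg: 47.5, rho: 0.23}
  V:
    intima:     {mu_kpa: 20.9, c1_kpa: 125.3, c2: 11.0, alpha_deg: 30.4, rho: 0.23}
    media:      {mu_kpa: 36.0, c1_kpa: 108.0, c2: 18.2, alpha_deg: 30.1, rho: 0.22}
    adventitia: {mu_kpa: 9.6,  c1_kpa: 25.1,  c2: 103.7, alpha_deg: 40.4, rho: 0.20}
  VI:
    intima:     {mu_kpa: 34.2, c1_kpa: 81.9,  c2: 19.4, alpha_deg: 43.3, rho: 0.26}
    media:      {mu_kpa: 14.5, c1_kpa: 199.9, c2: 2.0,  alpha_deg: 39.4, rho: 0.20}
    adventitia: {mu_kpa: 24.0, c1_kpa: 45.8,  c2: 41.3, alpha_deg: 51.1, rho: 0.24}
  VII:
    intima:     {mu_kpa: 25.5, c1_kpa: 86.3,  c2: 6.7,  alpha_deg: 37.1, rho: 0.26}
    media:      {mu_kpa: 14.6, c1_kpa: 120.0, c2: 5.0,  alpha_deg: 37.5, rho: 0.22}
    adventitia: {mu_kpa: 10.6, c1_kpa: 92.1,  c2: 17.5, alpha_deg: 39.2, rho: 0.23}
  VIII:
    intima:     {mu_kpa: 18.9, c1_kpa: 55.8,  c2: 8.7,  alpha_deg: 45.7, rho: 0.28}
    media:      {mu_kpa: 11.5, c1_kpa: 135.6, c2: 1.3,  alpha_deg: 36.0, rho: 0.23}
    adventitia: {mu_kpa: 18.3, c1_kpa: 24.8,  c2: 53.1, alpha_deg: 44.9, rho: 0.26}
  IX:
    intima:     {mu_kpa: 22.2, c1_kpa: 157.0, c2: 10.2, alpha_deg: 42.7, rho: 0.22}
    media:      {mu_kpa: 20.1, c1_kpa: 176.6, c2: 2.8,  alpha_deg: 37.4, rho: 0.21}
    adventitia: {mu_kpa: 18.1, c1_kpa: 80.3,  c2: 21.0, alpha_deg: 45.4, rho: 0.27}
  X:
    intima:     {mu_kpa: 12.2, c1_kpa: 189.1, c2: 4.8,  alpha_deg: 41.7, rho: 0.20}
    media:      {mu_kpa: 24.7, c1_kpa: 126.2, c2: 5.3,  alpha_deg: 34.8, rho: 0.26}
    adventitia: {mu_kpa: 18.4, c1_kpa: 82.6,  c2: 30.9, alpha_deg: 45.4, rho: 0.24}
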