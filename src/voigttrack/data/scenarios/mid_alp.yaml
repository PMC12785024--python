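# Intermediate loading: 10 uM ALP, 305 mM PNPP.  Same band set and common
# starting positions, but much smaller net shifts and slower apparent
# kinetics (k = ln(20)/12 min^-1).  B1 is seeded so its net shift is the
# reported +0.80 cm^-1.
name: mid_alp
metadata:
  alp_uM: 10.0
  pnpp_mM: 305.0
  condition: mid
grid: {lo: 400.0, hi: 4000.0, spacing: 0.5}
times: {t0: 0.0, t_end: 33.0, step: 1.5}
rate_k: 0.2496443561294992
noise_sd: 2.0e-4
drift: {slope_max: 1.0e-6, intercept_max: 1.0e-4}
bands:
  - {band_id: B1, center_start: 1509.742, center_end: 1510.542, area_start: 0.30, area_end: 0.30}
  - {band_id: B2, center_start: 1493.9, center_end: 1494.2, area_start: 0.30, area_end: 0.30}
  - {band_id: B3, center_start: 1344.8, center_end: 1343.1, area_start: 0.28, area_end: 0.22}
  - {band_id: B4, center_start: 1294.5, center_end: 1290.7, area_start: 0.25, area_end: 0.19}
  - {band_id: PI1077, center_start: 1077.0, center_end: 1077.0, area_start: 0.02, area_end: 0.27}
  - {band_id: R1606, center_start: 1606.0, center_end: 1606.0, area_start: 0.30, area_end: 0.15}
  - {band_id: R1617, center_start: 1617.0, center_end: 1617.0, area_start: 0.05, area_end: 0.20}
  - {band_id: D1583, center_start: 1583.0, center_end: 1583.0, area_start: 0.03, area_end: 0.08}
  - {band_id: D1595, center_start: 1595.0, center_end: 1595.0, area_start: 0.08, area_end: 0.12}
  - {band_id: CTRL1460, center_start: 1460.0, center_end: 1460.0, area_start: 0.22, area_end: 0.22}
  - {band_id: ALP1045, center_start: 1045.0, center_end: 1045.0, area_start: 0.18, area_end: 0.18}
  - {band_id: ALP925, center_start: 925.0, center_end: 925.0, area_start: 0.15, area_end: 0.15}
  - {band_id: PI847, center_start: 847.0, center_end: 847.0, area_start: 0.05, area_end: 0.14, sigma: 10.0, gamma: 12.0}
envelopes:
  - {center: 3380.0, area: 8.0, sigma: 110.0, gamma: 0.0}
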