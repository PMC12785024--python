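# Default tracking configuration: analysis windows, the reference-table
# band behind each tracked component, the drift-control band and the
# product readout.  The product readout is the comparatively isolated
# 1077 cm^-1 phosphate band; the ~990 cm^-1 region is avoided because it
# overlaps the protein ~925 cm^-1 band and the broad ~847 cm^-1 phosphate
# tail.
windows:
  - name: nitro_pair
    lo: 1478.0
    hi: 1545.0
    bands:
      - {band_id: B2, ref_label: pnpp_1496}
      - {band_id: B1, ref_label: pnpp_1508}
  - name: fingerprint_hi
    lo: 1322.0
    hi: 1368.0
    bands:
      - {band_id: B3, ref_label: pnpp_1345}
  - name: fingerprint_lo
    lo: 1268.0
    hi: 1320.0
    bands:
      - {band_id: B4, ref_label: pnpp_1294}
  - name: phosphate
    lo: 1030.0
    hi: 1115.0
    bands:
      - {band_id: ALP1045, ref_label: alp_1045}
      - {band_id: PI1077, ref_label: pi_1077}
  - name: control
    lo: 1436.0
    hi: 1482.0
    bands:
      - {band_id: CTRL1460, ref_label: alp_1459}
control_band: CTRL1460
control_tol_cm1: 1.0
product_band: PI1077
summary_bands: [B1, B2, B3, B4]
redistribution:
  lo: 1598.0
  hi: 1628.0
  centers: [1606.0, 1617.0]
  center_tol_cm1: 2.0
detection:
  smooth_window: 7
  smooth_order: 2
  merge_tol_cm1: 4.0
  min_prominence_sigma: 5.0
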