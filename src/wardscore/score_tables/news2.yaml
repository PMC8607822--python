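# National Early Warning Score 2 (Royal College of Physicians, 2017).
# Identical bands to NEWS except: consciousness is ACVPU (new confusion also
# scores 3 - already covered by the "anything but alert" band), and SpO2
# Scale 2 applies to confirmed hypercapnic respiratory failure.  Scale 2 is
# disabled by default and used only when the hypercapnic_failure flag is 1.
name: NEWS2
threshold: 5
max_total: 20
components:
  - name: respiratory_rate
    criteria:
      - variable: resp_rate
        bands:
          - {upper: 8, points: 3}
          - {upper: 11, points: 1}
          - {upper: 20, points: 0}
          - {upper: 24, points: 2}
          - {points: 3}
  - name: oxygen_saturation
    criteria:
      - variable: spo2                   # Scale 1
        bands:
          - {upper: 91, points: 3}
          - {upper: 93, points: 2}
          - {upper: 95, points: 1}
          - {points: 0}
  - name: supplemental_oxygen
    criteria:
      - variable: supplemental_o2
        bands:
          - {upper: 0, points: 0}
          - {points: 2}
  - name: temperature
    criteria:
      - variable: temperature
        bands:
          - {upper: 35.0, points: 3}
          - {upper: 36.0, points: 1}
          - {upper: 38.0, points: 0}
          - {upper: 39.0, points: 1}
          - {points: 2}
  - name: systolic_bp
    criteria:
      - variable: sbp
        bands:
          - {upper: 90, points: 3}
          - {upper: 100, points: 2}
          - {upper: 110, points: 1}
          - {upper: 219, points: 0}
          - {points: 3}
  - name: heart_rate
    criteria:
      - variable: heart_rate
        bands:
          - {upper: 40, points: 3}
          - {upper: 50, points: 1}
          - {upper: 90, points: 0}
          - {upper: 110, points: 1}
          - {upper: 130, points: 2}
          - {points: 3}
  - name: consciousness
    rule: first_present                  # ACVPU preferred when charted
    criteria:
      - variable: avpu                   # A:0, C/V/P/U: 3
        bands:
          - {upper: 0, points: 0}
          - {points: 3}
      - variable: gcs
        bands:
          - {upper: 14, points: 3}
          - {points: 0}
special:
  spo2_scale2:
    trigger_variable: hypercapnic_failure
    # on air (or when supplemental O2 absent/0)
    air_bands:
      - {upper: 83, points: 3}
      - {upper: 85, points: 2}
      - {upper: 87, points: 1}
      - {upper: 92, points: 0}
      - {points: 0}
    # on supplemental oxygen: high saturations score
    oxygen_bands:
      - {upper: 83, points: 3}
      - {upper: 85, points: 2}
      - {upper: 87, points: 1}
      - {upper: 92, points: 0}
      - {upper: 94, points: 1}
      - {upper: 96, points: 2}
      - {points: 3}
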