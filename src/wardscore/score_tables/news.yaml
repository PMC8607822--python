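# National Early Warning Score (Royal College of Physicians, 2012).
# Missing mentation is assumed alert; GCS fallback: 15->alert, otherwise not
# alert (scores 3).
name: NEWS
threshold: 5
max_total: 20
components:
  - name: respiratory_rate
    criteria:
      - variable: resp_rate              # <=8:3 9-11:1 12-20:0 21-24:2 >=25:3
        bands:
          - {upper: 8, points: 3}
          - {upper: 11, points: 1}
          - {upper: 20, points: 0}
          - {upper: 24, points: 2}
          - {points: 3}
  - name: oxygen_saturation
    criteria:
      - variable: spo2                   # <=91:3 92-93:2 94-95:1 >=96:0
        bands:
          - {upper: 91, points: 3}
          - {upper: 93, points: 2}
          - {upper: 95, points: 1}
          - {points: 0}
  - name: supplemental_oxygen
    criteria:
      - variable: supplemental_o2        # any oxygen: 2
        bands:
          - {upper: 0, points: 0}
          - {points: 2}
  - name: temperature
    criteria:
      - variable: temperature            # <=35.0:3 35.1-36.0:1 36.1-38.0:0 38.1-39.0:1 >=39.1:2
        bands:
          - {upper: 35.0, points: 3}
          - {upper: 36.0, points: 1}
          - {upper: 38.0, points: 0}
          - {upper: 39.0, points: 1}
          - {points: 2}
  - name: systolic_bp
    criteria:
      - variable: sbp                    # <=90:3 91-100:2 101-110:1 111-219:0 >=220:3
        bands:
          - {upper: 90, points: 3}
          - {upper: 100, points: 2}
          - {upper: 110, points: 1}
          - {upper: 219, points: 0}
          - {points: 3}
  - name: heart_rate
    criteria:
      - variable: heart_rate             # <=40:3 41-50:1 51-90:0 91-110:1 111-130:2 >=131:3
        bands:
          - {upper: 40, points: 3}
          - {upper: 50, points: 1}
          - {upper: 90, points: 0}
          - {upper: 110, points: 1}
          - {upper: 130, points: 2}
          - {points: 3}
  - name: consciousness
    rule: first_present                  # AVPU preferred when charted
    criteria:
      - variable: avpu                   # anything but Alert: 3
        bands:
          - {upper: 0, points: 0}
          - {points: 3}
      - variable: gcs
        bands:
          - {upper: 14, points: 3}
          - {points: 0}
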