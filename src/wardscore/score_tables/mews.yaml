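# Modified Early Warning Score (Subbe 2001).
# Consciousness uses ACVPU codes (A=0, C=1, V=2, P=3, U=4); new confusion is
# graded at the voice level.  GCS fallback mapping: 15->alert, 13-14->voice,
# 9-12->pain, <=8->unresponsive.
name: MEWS
threshold: 4
max_total: 14
components:
  - name: systolic_bp
    criteria:
      - variable: sbp                    # <=70:3 71-80:2 81-100:1 101-199:0 >=200:2
        bands:
          - {upper: 70, points: 3}
          - {upper: 80, points: 2}
          - {upper: 100, points: 1}
          - {upper: 199, points: 0}
          - {points: 2}
  - name: heart_rate
    criteria:
      - variable: heart_rate             # <41:2 41-50:1 51-100:0 101-110:1 111-129:2 >=130:3
        bands:
          - {upper: 40, points: 2}
          - {upper: 50, points: 1}
          - {upper: 100, points: 0}
          - {upper: 110, points: 1}
          - {upper: 129, points: 2}
          - {points: 3}
  - name: respiratory_rate
    criteria:
      - variable: resp_rate              # <9:2 9-14:0 15-20:1 21-29:2 >=30:3
        bands:
          - {upper: 8, points: 2}
          - {upper: 14, points: 0}
          - {upper: 20, points: 1}
          - {upper: 29, points: 2}
          - {points: 3}
  - name: temperature
    criteria:
      - variable: temperature            # <35:2 35-38.4:0 >=38.5:2
        bands:
          - {upper: 35.0, points: 2, exclusive: true}
          - {upper: 38.4, points: 0}
          - {points: 2}
  - name: consciousness
    rule: first_present                  # AVPU preferred when charted
    criteria:
      - variable: avpu                   # A:0 C/V:1 P:2 U:3
        bands:
          - {upper: 0, points: 0}
          - {upper: 2, points: 1}
          - {upper: 3, points: 2}
          - {points: 3}
      - variable: gcs
        bands:
          - {upper: 8, points: 3}
          - {upper: 12, points: 2}
          - {upper: 14, points: 1}
          - {points: 0}
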