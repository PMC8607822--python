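# quick Sequential Organ Failure Assessment (Sepsis-3 consensus, 2016).
# One point each for RR >= 22, SBP <= 100, altered mentation.
name: qSOFA
threshold: 2
max_total: 3
components:
  - name: respiratory_rate
    criteria:
      - variable: resp_rate              # >= 22 breaths/min
        bands:
          - {upper: 22, points: 0, exclusive: true}
          - {points: 1}
  - name: systolic_bp
    criteria:
      - variable: sbp                    # <= 100 mmHg
        bands:
          - {upper: 100, points: 1}
          - {points: 0}
  - name: mentation
    rule: first_present                  # AVPU preferred when charted
    criteria:
      - variable: avpu                   # anything but Alert (code 0)
        bands:
          - {upper: 0, points: 0}
          - {points: 1}
      - variable: gcs                    # GCS < 15
        bands:
          - {upper: 15, points: 1, exclusive: true}
          - {points: 0}
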