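# Systemic Inflammatory Response Syndrome criteria (Bone 1992).
# Each component is one criterion worth 1 point; the total is the number of
# criteria met.  All thresholds are strict inequalities.
# Bands: first entry whose "upper" bound admits the value wins; a band with
# "exclusive: true" admits value < upper, otherwise value <= upper; the final
# band (no upper) catches everything else.
name: SIRS
threshold: 2
max_total: 4
components:
  - name: temperature
    criteria:
      - variable: temperature            # >38 or <36 degC
        bands:
          - {upper: 36.0, points: 1, exclusive: true}
          - {upper: 38.0, points: 0}
          - {points: 1}
  - name: heart_rate
    criteria:
      - variable: heart_rate             # >90 bpm
        bands:
          - {upper: 90, points: 0}
          - {points: 1}
  - name: respiration
    criteria:
      - variable: resp_rate              # >20 breaths/min
        bands:
          - {upper: 20, points: 0}
          - {points: 1}
      - variable: paco2                  # or PaCO2 <32 mmHg
        bands:
          - {upper: 32, points: 1, exclusive: true}
          - {points: 0}
  - name: white_cells
    criteria:
      - variable: wbc                    # >12 or <4 x10^3/uL
        bands:
          - {upper: 4.0, points: 1, exclusive: true}
          - {upper: 12.0, points: 0}
          - {points: 1}
      - variable: band_pct               # or >10% band forms
        bands:
          - {upper: 10.0, points: 0}
          - {points: 1}
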