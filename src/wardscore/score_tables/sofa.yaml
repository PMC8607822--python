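# Sequential Organ Failure Assessment (Vincent 1996), ward adaptation.
# Banded components: coagulation, liver, CNS, renal.  Respiration and
# cardiovascular components are computed from the "special" parameters below:
# respiration from the most recent paired PaO2/FiO2 (3-4 points require
# respiratory support, else capped at 2); cardiovascular from MAP and any
# vasopressor administrations (with dose, ug/kg/min) in the lookback window.
# The renal urine-output bands are retained for completeness but unused by
# default (24-h urine output is rarely charted on the ward).
name: SOFA
threshold: 2
max_total: 24
components:
  - name: coagulation
    criteria:
      - variable: platelets              # x10^3/uL: <20:4 <50:3 <100:2 <150:1
        bands:
          - {upper: 20, points: 4, exclusive: true}
          - {upper: 50, points: 3, exclusive: true}
          - {upper: 100, points: 2, exclusive: true}
          - {upper: 150, points: 1, exclusive: true}
          - {points: 0}
  - name: liver
    criteria:
      - variable: bilirubin              # mg/dL: 1.2-1.9:1 2.0-5.9:2 6.0-11.9:3 >=12:4
        bands:
          - {upper: 1.2, points: 0, exclusive: true}
          - {upper: 2.0, points: 1, exclusive: true}
          - {upper: 6.0, points: 2, exclusive: true}
          - {upper: 12.0, points: 3, exclusive: true}
          - {points: 4}
  - name: cns
    criteria:
      - variable: gcs                    # 15:0 13-14:1 10-12:2 6-9:3 <6:4
        bands:
          - {upper: 5, points: 4}
          - {upper: 9, points: 3}
          - {upper: 12, points: 2}
          - {upper: 14, points: 1}
          - {points: 0}
  - name: renal
    criteria:
      - variable: creatinine             # mg/dL: 1.2-1.9:1 2.0-3.4:2 3.5-4.9:3 >=5:4
        bands:
          - {upper: 1.2, points: 0, exclusive: true}
          - {upper: 2.0, points: 1, exclusive: true}
          - {upper: 3.5, points: 2, exclusive: true}
          - {upper: 5.0, points: 3, exclusive: true}
          - {points: 4}
special:
  respiration:
    # PaO2/FiO2 (mmHg): <100:4 <200:3 <300:2 <400:1
    pf_bands:
      - {upper: 100, points: 4, exclusive: true}
      - {upper: 200, points: 3, exclusive: true}
      - {upper: 300, points: 2, exclusive: true}
      - {upper: 400, points: 1, exclusive: true}
      - {points: 0}
    support_required_above: 2            # 3-4 need respiratory_support = 1
  cardiovascular:
    map_bands:                           # MAP <70 mmHg: 1 point
      - {upper: 70, points: 1, exclusive: true}
      - {points: 0}
    vasopressor_bands:
      dopamine:                          # ug/kg/min
        - {upper: 5.0, points: 2}
        - {upper: 15.0, points: 3}
        - {points: 4}
      dobutamine:                        # any dose
        - {points: 2}
      epinephrine:
        - {upper: 0.1, points: 3}
        - {points: 4}
      norepinephrine:
        - {upper: 0.1, points: 3}
        - {points: 4}
  renal_urine_output:                    # retained, unused by default
    bands:
      - {upper: 200, points: 4, exclusive: true}
      - {upper: 500, points: 3, exclusive: true}
      - {points: 0}
worst:
  map:
    - {upper: 70, points: 1, exclusive: true}
    - {points: 0}
  respiratory_support:
    - {upper: 0, points: 0}
    - {points: 1}
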