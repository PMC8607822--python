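# Acute Physiology and Chronic Health Evaluation II (Knaus 1985), ward
# adaptation.  Acute physiology points for 11 banded variables plus the GCS
# deficit (15 - GCS, encoded as bands), plus age points (encounter attribute,
# in "special") and chronic-health points (constant 0 by default: chronic
# organ insufficiency is not ascertainable from the data model).
# Oxygenation: if FiO2 >= 0.5 and PaO2/PaCO2/FiO2 are all present, the
# alveolar-arterial gradient bands apply; if FiO2 < 0.5, the PaO2 bands;
# otherwise the component scores 0.  Creatinine points are not doubled for
# acute renal failure (not ascertainable).
name: APACHE_II
threshold: 15
max_total: 71
components:
  - name: temperature
    criteria:
      - variable: temperature            # core degC
        bands:
          - {upper: 29.9, points: 4}
          - {upper: 31.9, points: 3}
          - {upper: 33.9, points: 2}
          - {upper: 35.9, points: 1}
          - {upper: 38.4, points: 0}
          - {upper: 38.9, points: 1}
          - {upper: 40.9, points: 3}
          - {points: 4}
  - name: mean_arterial_pressure
    criteria:
      - variable: map                    # mmHg
        bands:
          - {upper: 49, points: 4}
          - {upper: 69, points: 2}
          - {upper: 109, points: 0}
          - {upper: 129, points: 2}
          - {upper: 159, points: 3}
          - {points: 4}
  - name: heart_rate
    criteria:
      - variable: heart_rate
        bands:
          - {upper: 39, points: 4}
          - {upper: 54, points: 3}
          - {upper: 69, points: 2}
          - {upper: 109, points: 0}
          - {upper: 139, points: 2}
          - {upper: 179, points: 3}
          - {points: 4}
  - name: respiratory_rate
    criteria:
      - variable: resp_rate
        bands:
          - {upper: 5, points: 4}
          - {upper: 9, points: 2}
          - {upper: 11, points: 1}
          - {upper: 24, points: 0}
          - {upper: 34, points: 1}
          - {upper: 49, points: 3}
          - {points: 4}
  - name: arterial_ph
    criteria:
      - variable: arterial_ph
        bands:
          - {upper: 7.15, points: 4, exclusive: true}
          - {upper: 7.25, points: 3, exclusive: true}
          - {upper: 7.33, points: 2, exclusive: true}
          - {upper: 7.50, points: 0, exclusive: true}
          - {upper: 7.60, points: 1, exclusive: true}
          - {upper: 7.70, points: 3, exclusive: true}
          - {points: 4}
  - name: sodium
    criteria:
      - variable: sodium                 # mmol/L
        bands:
          - {upper: 110, points: 4}
          - {upper: 119, points: 3}
          - {upper: 129, points: 2}
          - {upper: 149, points: 0}
          - {upper: 154, points: 1}
          - {upper: 159, points: 2}
          - {upper: 179, points: 3}
          - {points: 4}
  - name: potassium
    criteria:
      - variable: potassium              # mmol/L
        bands:
          - {upper: 2.5, points: 4, exclusive: true}
          - {upper: 3.0, points: 2, exclusive: true}
          - {upper: 3.5, points: 1, exclusive: true}
          - {upper: 5.5, points: 0, exclusive: true}
          - {upper: 6.0, points: 1, exclusive: true}
          - {upper: 7.0, points: 3, exclusive: true}
          - {points: 4}
  - name: creatinine
    criteria:
      - variable: creatinine             # mg/dL (no ARF doubling)
        bands:
          - {upper: 0.6, points: 2, exclusive: true}
          - {upper: 1.5, points: 0, exclusive: true}
          - {upper: 2.0, points: 2, exclusive: true}
          - {upper: 3.5, points: 3, exclusive: true}
          - {points: 4}
  - name: hematocrit
    criteria:
      - variable: hematocrit             # %
        bands:
          - {upper: 20, points: 4, exclusive: true}
          - {upper: 30, points: 2, exclusive: true}
          - {upper: 46, points: 0, exclusive: true}
          - {upper: 50, points: 1, exclusive: true}
          - {upper: 60, points: 2, exclusive: true}
          - {points: 4}
  - name: white_cells
    criteria:
      - variable: wbc                    # x10^3/uL
        bands:
          - {upper: 1.0, points: 4, exclusive: true}
          - {upper: 3.0, points: 2, exclusive: true}
          - {upper: 15.0, points: 0, exclusive: true}
          - {upper: 20.0, points: 1, exclusive: true}
          - {upper: 40.0, points: 2, exclusive: true}
          - {points: 4}
  - name: glasgow_coma
    criteria:
      - variable: gcs                    # points = 15 - GCS
        bands:
          - {upper: 3, points: 12}
          - {upper: 4, points: 11}
          - {upper: 5, points: 10}
          - {upper: 6, points: 9}
          - {upper: 7, points: 8}
          - {upper: 8, points: 7}
          - {upper: 9, points: 6}
          - {upper: 10, points: 5}
          - {upper: 11, points: 4}
          - {upper: 12, points: 3}
          - {upper: 13, points: 2}
          - {upper: 14, points: 1}
          - {points: 0}
special:
  age_bands:                             # encounter age, years
    - {upper: 44, points: 0}
    - {upper: 54, points: 2}
    - {upper: 64, points: 3}
    - {upper: 74, points: 5}
    - {points: 6}
  chronic_health_points: 0
  oxygenation:
    fio2_threshold: 0.5
    pao2_bands:                          # FiO2 < 0.5: PaO2 mmHg
      - {upper: 55, points: 4, exclusive: true}
      - {upper: 60, points: 3}
      - {upper: 70, points: 1}
      - {points: 0}
    aa_gradient_bands:                   # FiO2 >= 0.5: A-a gradient mmHg
      - {upper: 200, points: 0, exclusive: true}
      - {upper: 349, points: 2}
      - {upper: 499, points: 3}
      - {points: 4}
worst:
  pao2:
    - {upper: 55, points: 4, exclusive: true}
    - {upper: 60, points: 3}
    - {upper: 70, points: 1}
    - {points: 0}
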