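# Default feature schema for impacted mandibular third-molar (M3M) extraction records.
#
# Fourteen primary difficulty indicators, each with its ordered secondary levels and the
# baseline cohort proportion of each level (fractions; some rows do not sum exactly to 1
# because the source proportions were rounded — consumers renormalize within indicator).
indicators:
  - name: Crown condition of second molar
    abbreviation: SMC
    levels:
      - name: Prothesis
        proportion: 0.003
      - name: Distal tooth defect or filling
        proportion: 0.096
      - name: Other situations
        proportion: 0.900
  - name: Second molar looseness
    abbreviation: Stability
    levels:
      - name: Loose
        proportion: 0.050
      - name: Not loose
        proportion: 0.949
  - name: Relationship of M3M and IAN
    abbreviation: IAN
    levels:
      - name: Uncontacted
        proportion: 0.673
      - name: Overlap
        proportion: 0.101
      - name: Intrude
        proportion: 0.222
  - name: Impacted type (winter classification)
    abbreviation: Angle
    levels:
      - name: Distal
        proportion: 0.082
      - name: Vertical and mesial (located above the contour point of second molar)
        proportion: 0.266
      - name: Mesial (located below the contour point of second molar)
        proportion: 0.263
      - name: Horizontal
        proportion: 0.343
      - name: Inverted
        proportion: 0.004
      - name: Buccal
        proportion: 0.012
      - name: Lingual
        proportion: 0.024
  - name: Depth (Pell & Gregory classification)
    abbreviation: Depth
    levels:
      - name: High
        proportion: 0.493
      - name: Medium
        proportion: 0.445
      - name: Low
        proportion: 0.058
  - name: Crown condition of M3M
    abbreviation: Crown
    levels:
      - name: Tooth defect (non-mesial defect more than 1/2)
        proportion: 0.079
      - name: Unbroken or small decay
        proportion: 0.917
  - name: Root number
    abbreviation: Roots
    levels:
      - name: Two
        proportion: 0.525
      - name: Three or more
        proportion: 0.021
      - name: One or fusion
        proportion: 0.450
  - name: Root morphology
    abbreviation: Morphology
    levels:
      - name: Complete development
        proportion: 0.038
      - name: Incomplete development
        proportion: 0.072
      - name: Bending in opposite direction or to mesial
        proportion: 0.014
      - name: Bending in two or more different direction
        proportion: 0.021
      - name: Enlargement in apical site
        proportion: 0.849
  - name: Root width (a cervical width, b maximum root width)
    abbreviation: Width
    levels:
      - name: a>b or a~b
        proportion: 0.840
      - name: a<b
        proportion: 0.157
  - name: Crown resistance
    abbreviation: Resistance
    levels:
      - name: Complete eruption
        proportion: 0.089
      - name: Soft tissue coverage
        proportion: 0.491
      - name: Partial bone coverage
        proportion: 0.404
      - name: Complete bone coverage
        proportion: 0.012
  - name: Age
    abbreviation: Age
    levels:
      - name: 0-25
        proportion: 0.302
      - name: 25-35
        proportion: 0.547
      - name: ">35"
        proportion: 0.147
  - name: Mouth opening
    abbreviation: Opening
    levels:
      - name: Normal
        proportion: 0.985
      - name: Limited mouth opening
        proportion: 0.012
  - name: BMI
    abbreviation: BMI
    levels:
      - name: "<18.5"
        proportion: 0.114
      - name: 18.5-25
        proportion: 0.696
      - name: 25-30
        proportion: 0.150
      - name: 30-35
        proportion: 0.033
      - name: ">35"
        proportion: 0.004
  - name: Gender
    abbreviation: Gender
    levels:
      - name: Male
        proportion: 0.405
      - name: Female
        proportion: 0.594
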