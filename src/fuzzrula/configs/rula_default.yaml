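# Default fuzzy-RULA model definition.
#
# Membership breakpoints are reconstructions: they encode the published RULA
# angle categories (arm ~ -20/20/45/90 deg, trunk ~ 20/60 deg) as trapezoids
# with plateaus on each category and linear crossovers of +-5 deg width.
# Edge terms are shouldered (plateau runs to the universe edge) so every
# in-range input fires at least one rule.  The trunk set adds a
# deep-extension band (score 3 past ~20 deg backward lean) for reclined
# sitting, which plain RULA does not grade.  Rule consequents are generated
# from the crisp RULA worksheet tables, not listed here.
group_a:
  flexion:
    universe: [-180.0, 180.0]
    terms:
      - {label: extended,         params: [-180, -180, -25, -15], category: 2}
      - {label: neutral,          params: [-25, -15, 15, 25],     category: 1}
      - {label: mild_flexion,     params: [15, 25, 40, 50],       category: 2}
      - {label: moderate_flexion, params: [40, 50, 85, 95],       category: 3}
      - {label: severe_flexion,   params: [85, 95, 180, 180],     category: 4}
  abduction:
    universe: [-180.0, 180.0]
    terms:
      - {label: adducted, params: [-180, -180, -15, -10], modifier: 0}
      - {label: neutral,  params: [-15, -10, 10, 15],     modifier: 0}
      - {label: abducted, params: [10, 15, 180, 180],     modifier: 1}
  output:
    universe: [3.0, 7.0]
    half_width: 0.5
group_b:
  trunk_flexion:
    universe: [-180.0, 180.0]
    terms:
      - {label: deep_extension,   params: [-180, -180, -25, -15], category: 3}
      - {label: extension,        params: [-25, -15, -10, -5],    category: 2}
      - {label: upright,          params: [-10, -5, 5, 10],       category: 1}
      - {label: slight_flexion,   params: [5, 10, 15, 25],        category: 2}
      - {label: moderate_flexion, params: [15, 25, 55, 65],       category: 3}
      - {label: deep_flexion,     params: [55, 65, 180, 180],     category: 4}
  trunk_twist:
    # a +-5 deg plateau around 0 counts as centred; beyond it the trunk is
    # twisting left or right
    universe: [-180.0, 180.0]
    terms:
      - {label: twisted_left,  params: [-180, -180, -10, -5], modifier: 1}
      - {label: centered,      params: [-10, -5, 5, 10],      modifier: 0}
      - {label: twisted_right, params: [5, 10, 180, 180],     modifier: 1}
  output:
    universe: [1.0, 6.0]
    half_width: 0.5
final:
  # inputs are the static-adjusted group scores (+1 each)
  input_a: {universe: [4.0, 8.0]}
  input_b: {universe: [2.0, 7.0]}
  output:
    universe: [3.0, 7.0]
    # symmetric shapes: the centroid of a clipped symmetric MF does not move,
    # which keeps the defuzzified surface monotone across rule crossfades
    terms:
      - {label: medium, shape: trapezoid, params: [2.5, 3, 4, 4.5]}
      - {label: high,   shape: trapezoid, params: [4, 5, 6, 7]}
      - {label: severe, shape: triangle,  params: [6, 7, 8]}
evaluator_defaults:
  lower_arm: 2      # forearm category (1-3)
  wrist: 2          # wrist category (1-4)
  wrist_twist: 1    # wrist-twist category (1-2)
  neck: 1           # neck category (1-6)
  legs: 1           # legs category (1-2); seated, well supported
  shoulder_raised: false
defuzz_resolution: 1001
category_cuts:
  medium_high: 4.5
  high_severe: 6.5
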