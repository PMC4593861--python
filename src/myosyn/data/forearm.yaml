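# Default 7-muscle elbow flexion/extension fixture.
#
# A documented stand-in parameter set, not experimental data.  Muscle
# geometry (fiber/tendon lengths) follows standard published upper-limb
# models; strengths and moment arms are scaled down so that the shipped
# controller gains produce comparable, well-conditioned tracking for both
# the per-step optimizer and the synergy PID on the default task.
# Moment arms (negative derivative of the length polynomial) are positive
# (flexor) for the first four muscles and negative (extensor) for the
# triceps heads, with no muscle changing function anywhere in the range.
# The constant gravity torque represents a static extension load held
# against during tracking.
model:
  name: forearm
  inertia: 0.06          # kg m^2, forearm + hand about the elbow
  damping: 0.1           # N m s / rad
  gravity: -1.0          # N m, static extension load
  theta_range: [0.0, 2.6]
  rep_pos: biceps_long
  rep_neg: triceps_long
muscles:
  - name: brachioradialis
    f0max: 26.2
    pennation: 0.0
    length_poly: [0.3332675, -0.020, -0.00075]
    l_opt: 0.173
    l_slack: 0.133
    v_max: 10.0
  - name: brachialis
    f0max: 98.7
    pennation: 0.0
    length_poly: [0.156445, -0.012, -0.0005]
    l_opt: 0.086
    l_slack: 0.054
    v_max: 10.0
  - name: biceps_long
    f0max: 62.4
    pennation: 0.0
    length_poly: [0.408514, -0.015, -0.0006]
    l_opt: 0.116
    l_slack: 0.272
    v_max: 10.0
  - name: biceps_short
    f0max: 43.5
    pennation: 0.0
    length_poly: [0.340055, -0.013, 0.0005]
    l_opt: 0.132
    l_slack: 0.192
    v_max: 10.0
  - name: triceps_long
    f0max: 79.9
    pennation: 0.0
    length_poly: [0.262076, 0.012, -0.0004]
    l_opt: 0.134
    l_slack: 0.143
    v_max: 10.0
  - name: triceps_lateral
    f0max: 62.5
    pennation: 0.0
    length_poly: [0.198493, 0.010, 0.0003]
    l_opt: 0.114
    l_slack: 0.098
    v_max: 10.0
  - name: triceps_medial
    f0max: 62.0
    pennation: 0.0
    length_poly: [0.1924225, 0.010, -0.00025]
    l_opt: 0.114
    l_slack: 0.091
    v_max: 10.0
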