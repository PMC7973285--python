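# Default dosimetric bounds for plan-quality weighting.
#
# These are EXTERNAL REFERENCE VALUES transcribed from the published
# EMBRACE II protocol planning aims and limits for dose prescription
# (total EQD2 over EBRT + brachytherapy, alpha/beta = 10 Gy for targets,
# 3 Gy for organs at risk). They are not institutional values; override any
# of them with a site-specific YAML of the same shape.
#
# Shape: {metric: {planning_aim: {op: ">="|"<=", value: Gy},
#                  dose_constraint: {op: ..., value: Gy}}}   # optional
D90 HR-CTV:
  planning_aim: {op: ">=", value: 90.0}
  dose_constraint: {op: ">=", value: 85.0}
D98 HR-CTV:
  planning_aim: {op: ">=", value: 75.0}
D98 GTV:
  planning_aim: {op: ">=", value: 95.0}
D98 IR-CTV:
  planning_aim: {op: ">=", value: 60.0}
Point A EQD2:
  planning_aim: {op: ">=", value: 65.0}
Bladder D2cc:
  planning_aim: {op: "<=", value: 80.0}
  dose_constraint: {op: "<=", value: 90.0}
Rectum D2cc:
  planning_aim: {op: "<=", value: 65.0}
  dose_constraint: {op: "<=", value: 75.0}
Sigmoid D2cc:
  planning_aim: {op: "<=", value: 70.0}
  dose_constraint: {op: "<=", value: 75.0}
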