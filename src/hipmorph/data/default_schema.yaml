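# Default 80-point hip annotation schema (0-based landmark indices).
#
# Point roles name single landmarks; segment roles are half-open [start, stop)
# ranges of contiguous landmarks.  Edit or replace this file to adapt the
# pipeline to a different annotation protocol: any schema providing these
# roles works.
n_points: 80
points:
  TEARDROP_CAUDAL: 0
  SOURCIL_MEDIAL: 4
  SOURCIL_LATERAL: 8
  ACETAB_LATERAL_EDGE: 11
  FEMORAL_HEAD_APEX: 26
segments:
  HEAD_CONTOUR: [12, 42]
  HEADNECK_SUPERIOR_CONTOUR: [42, 52]
  NECK_LATERAL: [52, 60]
  NECK_MEDIAL: [60, 68]
  SHAFT_LATERAL: [68, 74]
  SHAFT_MEDIAL: [74, 80]
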