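# Canonical reconstruction of the two-landmark "Arctic" arena.
# Built from the stated constraints, not from measured coordinates:
#   arena radius 2.5 m; two 1 m landmarks at a right angle, centres >= 1.5 m
#   apart; 8 near targets (2 ends + 2 sides per landmark); end-mirror pairs
#   1.2 m apart. Side-target offsets are set to the same 0.6 m (a choice; the
#   side-pair separation is not pinned by any published figure).
# Users with measured coordinates may substitute their own file.
name: arctic
arena_radius: 2.5
chance_p1: 0.5
has_side_targets: true
landmarks:
  - id: 0
    label: black
    center: [-0.9, 0.0]
    orientation: 1.5707963267948966   # major axis along +y
    semi_major: 0.5
    semi_minor: 0.25
  - id: 1
    label: red
    center: [0.9, 0.0]
    orientation: 0.0                  # major axis along +x
    semi_major: 0.5
    semi_minor: 0.25
targets:
  - {id: 0, position: [-0.9,  0.6], landmark_id: 0, relation: end,  mirror_id: 1}
  - {id: 1, position: [-0.9, -0.6], landmark_id: 0, relation: end,  mirror_id: 0}
  - {id: 2, position: [-1.5,  0.0], landmark_id: 0, relation: side, mirror_id: 3}
  - {id: 3, position: [-0.3,  0.0], landmark_id: 0, relation: side, mirror_id: 2}
  - {id: 4, position: [ 0.3,  0.0], landmark_id: 1, relation: end,  mirror_id: 5}
  - {id: 5, position: [ 1.5,  0.0], landmark_id: 1, relation: end,  mirror_id: 4}
  - {id: 6, position: [ 0.9,  0.6], landmark_id: 1, relation: side, mirror_id: 7}
  - {id: 7, position: [ 0.9, -0.6], landmark_id: 1, relation: side, mirror_id: 6}
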