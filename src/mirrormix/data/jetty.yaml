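# Canonical reconstruction of the three-landmark "Jetty" arena.
# Constraints used: three 0.8 m landmarks at mutually oblique orientations,
# centres >= 1.5 m apart, 6 end targets (no side targets), arena radius 2.5 m.
# End targets sit 0.5 m from each landmark centre (0.1 m past the tip, the
# same convention as the Arctic reconstruction), so mirror pairs are 1.0 m
# apart. Centres lie on a 1.1 m ring at 90/210/330 degrees (pairwise 1.91 m).
name: jetty
arena_radius: 2.5
chance_p1: 0.3333333333333333
has_side_targets: false
landmarks:
  - id: 0
    label: red
    center: [0.0, 1.1]
    orientation: 0.2
    semi_major: 0.4
    semi_minor: 0.2
  - id: 1
    label: yellow
    center: [-0.9526279441628827, -0.55]
    orientation: 1.25
    semi_major: 0.4
    semi_minor: 0.2
  - id: 2
    label: green
    center: [0.9526279441628827, -0.55]
    orientation: 2.4
    semi_major: 0.4
    semi_minor: 0.2
targets:
  - {id: 0, position: [ 0.4900332889206208,  1.1993346653975308], landmark_id: 0, relation: end, mirror_id: 1}
  - {id: 1, position: [-0.4900332889206208,  1.0006653346024694], landmark_id: 0, relation: end, mirror_id: 0}
  - {id: 2, position: [-0.7949667629652482, -0.0755076903222069], landmark_id: 1, relation: end, mirror_id: 3}
  - {id: 3, position: [-1.1102891253605170, -1.0244923096777931], landmark_id: 1, relation: end, mirror_id: 2}
  - {id: 4, position: [ 0.5839310863922598, -0.2122684097244246], landmark_id: 2, relation: end, mirror_id: 5}
  - {id: 5, position: [ 1.3213248019335053, -0.8877315902755756], landmark_id: 2, relation: end, mirror_id: 4}
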