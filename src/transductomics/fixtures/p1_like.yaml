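# Weak generalized transducer: many low-processivity initiation sites whose
# overlapping staircases blur into mild (<= ~10-fold) coverage unevenness.
name: p1_like
contigs:
  - id: p1_host
    genome_length: 1200000
    circular: true
    wgs:
      mean_depth: 200.0
      ori_gradient: 1.3
      noise: true
    n_particles: 120000
    pac_sites:
      - {id: s01, position: 20000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.4}
      - {id: s02, position: 70000, headful: 44000, continuation_prob: 0.5, initiation_rate: 0.7}
      - {id: s03, position: 115000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.1}
      - {id: s04, position: 170000, headful: 44000, continuation_prob: 0.5, initiation_rate: 0.9}
      - {id: s05, position: 215000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.3}
      - {id: s06, position: 260000, headful: 44000, continuation_prob: 0.5, initiation_rate: 0.8}
      - {id: s07, position: 320000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.0}
      - {id: s08, position: 365000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.2}
      - {id: s09, position: 410000, headful: 44000, continuation_prob: 0.5, initiation_rate: 0.7}
      - {id: s10, position: 470000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.1}
      - {id: s11, position: 520000, headful: 44000, continuation_prob: 0.5, initiation_rate: 0.9}
      - {id: s12, position: 565000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.0}
      - {id: s13, position: 615000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.3}
      - {id: s14, position: 665000, headful: 44000, continuation_prob: 0.5, initiation_rate: 0.8}
      - {id: s15, position: 715000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.1}
      - {id: s16, position: 770000, headful: 44000, continuation_prob: 0.5, initiation_rate: 0.9}
      - {id: s17, position: 820000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.2}
      - {id: s18, position: 870000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.0}
      - {id: s19, position: 920000, headful: 44000, continuation_prob: 0.5, initiation_rate: 0.7}
      - {id: s20, position: 975000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.1}
      - {id: s21, position: 1025000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.3}
      - {id: s22, position: 1070000, headful: 44000, continuation_prob: 0.5, initiation_rate: 0.9}
      - {id: s23, position: 1120000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.0}
      - {id: s24, position: 1165000, headful: 44000, continuation_prob: 0.5, initiation_rate: 1.2}
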