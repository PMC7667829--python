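# Generalized transducer with processive headful packaging: six pac-like
# initiation sites on the host chromosome, headful ~44 kbp (one phage
# genome), per-headful continuation probability 0.7 so that the decaying
# staircase extends over several hundred kbp.
name: p22_like
contigs:
  - id: p22_host
    genome_length: 1800000
    circular: true
    wgs:
      mean_depth: 200.0
      ori_gradient: 1.3
      noise: true
    n_particles: 120000
    pac_sites:
      - {id: pacA, position: 150000, headful: 44000, continuation_prob: 0.7, direction: right, initiation_rate: 1.0}
      - {id: pacB, position: 460000, headful: 44000, continuation_prob: 0.7, direction: right, initiation_rate: 1.0}
      - {id: pacC, position: 745000, headful: 44000, continuation_prob: 0.7, direction: right, initiation_rate: 1.0}
      - {id: pacD, position: 1050000, headful: 44000, continuation_prob: 0.7, direction: right, initiation_rate: 1.0}
      - {id: pacE, position: 1330000, headful: 44000, continuation_prob: 0.7, direction: right, initiation_rate: 1.0}
      - {id: pacF, position: 1620000, headful: 44000, continuation_prob: 0.7, direction: right, initiation_rate: 1.0}
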