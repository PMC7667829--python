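# Gene-transfer-agent-like element: fixed 13 kbp fragments packaged
# quasi-randomly across the chromosome with a smooth 30-fold start-rate
# bias and reduced packaging over the element's own gene cluster.
name: pbsx_like
contigs:
  - id: pbsx_host
    genome_length: 1000000
    circular: true
    wgs:
      mean_depth: 200.0
      ori_gradient: 1.5
      noise: true
    n_particles: 150000
    gta:
      fragment_size: 13000
      bias_fold: 30
      bias_length_scale: 120000
      bias_bin: 1000
      self_exclusion:
        start: 480000
        end: 510000
        factor: 0.3
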