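# Multi-element host: two lateral-transducing prophages (in-situ headful
# initiation at one prophage edge; plateau:first-flank-headful frequency
# ratios ~1:500 and ~1:240) plus a phage-hijacking chromosomal island whose
# particle output exceeds the helper prophages by almost an order of
# magnitude.
name: faecalis_like
contigs:
  - id: faecalis_chrom
    genome_length: 2000000
    circular: true
    wgs:
      mean_depth: 200.0
      ori_gradient: 1.3
      noise: true
    n_particles: 2000000
    prophages:
      - id: phi1
        start: 200000
        end: 240000
        induction_rate: 1.0
        capsid_capacity: 40000
        lateral_rate: 5.0e-3      # 1 / (500 * (1 - q))
        lateral_direction: right
        continuation_prob: 0.6
      - id: island
        start: 900000
        end: 912000
        induction_rate: 8.0
      - id: pp5
        start: 1400000
        end: 1437000
        induction_rate: 0.6
        capsid_capacity: 37000
        lateral_rate: 6.25e-3     # 0.6 / (240 * (1 - q))
        lateral_direction: right
        continuation_prob: 0.6
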