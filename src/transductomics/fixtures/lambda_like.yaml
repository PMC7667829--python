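# Temperate prophage with rare imprecise excision (specialized transduction).
# The prophage occupies ~48.5 kbp; specialized particles keep part of the
# phage genome and carry up to ~25 kbp of adjacent host DNA on either side.
# The per-side specialized fraction of 1e-4 reproduces a prophage:flank
# coverage ratio of ~1:10,000.
name: lambda_like
contigs:
  - id: lambda_contig
    genome_length: 300000
    circular: false
    wgs:
      mean_depth: 200.0
      ori_gradient: 1.0
      noise: true
    n_particles: 3000000
    prophages:
      - id: lambda
        start: 125000
        end: 173500
        induction_rate: 1.0
        specialized_rate: 2.0e-4   # 1e-4 per side
        capsid_capacity: 48500
        max_flank: 25000
        side_bias: 0.5
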