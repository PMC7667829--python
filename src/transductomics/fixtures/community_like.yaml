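# Synthetic community fixture: per-mode contig counts; the individual
# contig layouts (lengths, element positions, rates) are drawn at run time
# from the fixture seed within the ranges coded in the generator.
name: community_like
counts:
  standard: 20
  contamination: 6
  induction: 8
  specialized: 8
  lateral: 6
  generalized: 6
  gta_like: 6
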