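# transductomics

Detection and characterization of transduced DNA from paired
whole-community / virus-like-particle (VLP) sequencing coverage.

## The problem

Phages and phage-like particles move host DNA between microbial cells
(transduction) far more often than classical transduction assays can
measure. When a microbiome sample is split into a whole-community
metagenome and an ultra-purified VLP fraction, and both read sets are
mapped onto the same long contigs, the VLP fraction leaves
characteristic coverage footprints over any contig whose DNA is carried
in particles:

| signature | VLP coverage footprint |
| --- | --- |
| prophage / island induction | sharply bounded high plateau over the element |
| specialized transduction | plateau plus short (~tens of kbp) declining flanks, orders of magnitude below the plateau |
| lateral transduction | plateau plus a one-sided decaying staircase spanning hundreds of kbp |
| generalized transduction | vertical rises at *pac*-like sites, declining staircases downstream, no plateau |
| GTA-like packaging | smooth genome-wide unevenness, fixed small fragments, no sharp edges |

This package turns the visual inspection of those footprints into an
automated, quantitative workflow: coverage loading and normalization,
change-point segmentation, per-contig mode classification,
transducing-particle frequency estimation
(N in "1:N" = plateau coverage / flank maximum), *pac*-site calling and
headful-size estimation, plus a normalized-coverage **rank screen** that
separates genuine VLP-borne DNA from residual cellular contamination:
each contig's share of sample coverage, `cov_i / Σ_j cov_j`, is ranked
in both samples; carriage keeps or improves the rank in the VLP sample,
contamination worsens it.

A mechanistic packaging simulator (the same process model the detector
assumes: geometric headful continuation `P(k-th headful) = q^(k-1)(1-q)`,
uniform imprecise-excision flank extents, biased fixed-size GTA
fragments) provides ground-truthed synthetic inputs for every stage.

## Worked example

Simulate a λ-style specialized-transduction fixture and scan it:

```bash
transductomics simulate --fixture lambda_like --seed 5 --out sim/
transductomics scan --wgs sim/wgs.bedgraph --vlp sim/vlp.bedgraph \
    --contigs sim/contigs.fai --out scan/ --seed 5
cat scan/calls.bed
```

```
lambda_contig	125000	173500	specialized	9400	.
```

One specialized call: the induced prophage plateau spans
125,000–173,500 bp and the flanking transduced host DNA peaks ~9,400-fold
below it, i.e. roughly one particle in ten thousand carries host DNA
(frequency "1:9400" in the score column; the fixture's configured truth
is 1:10,000). `scan/report.tsv` carries the
per-contig features behind the call (flank extents ≈ 25 kbp per side,
contig baseline, whole-community evenness CV, qc flags), and
`scan/rank.tsv` the contamination rank table.

The same works for the other model systems (`p22_like`, `p1_like`,
`pbsx_like`, `faecalis_like`) and for a mixed synthetic community with
seeded contamination (`community_like`). Real data enter through the
same door: coordinate-sorted SAM/BAM, per-base depth TSV, or bedGraph
tracks of the two read sets against one contig set (contigs < 40 kbp
are discarded by default — the patterns need room).

Library use mirrors the CLI:

```python
from transductomics import call_patterns, make_fixture

pairs, truths = make_fixture("community_like", seed=1)
calls = [call_patterns(p) for p in pairs]
```

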