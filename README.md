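# hicplaid

Integrative Hi-C structure analysis: A/B compartment calling, TAD boundary
detection, compartment-switch classification coupled to gene expression, and
known-motif enrichment around TAD boundaries — together with a synthetic
contact-map generator that plants ground truth so every stage is verifiable
without any external data.

## What's inside

| Module | Purpose |
| --- | --- |
| `hicplaid.synthdata` | Synthetic genomes with planted compartments, TAD tilings, bin biases; contact maps with distance decay + plaid + TAD enrichment + Poisson noise; matched expression tables and peak sets |
| `hicplaid.hic_core` | Bin tables (restriction-fragment or fixed-width), pairs → matrix, replicate merging, chromosome removal, coverage filtering, ICE balancing, rebinning |
| `hicplaid.compartments` | Observed/expected, pairwise-complete correlation PC1 per chromosome, peak-density sign orientation, A/B segmentation |
| `hicplaid.tads` | Per-distance z-scoring, multi-window diamond separation scores, local-minimum boundary candidates, one-sided rank-sum significance with Bonferroni correction, TAD assembly |
| `hicplaid.switch_analysis` | Four-way switch classification, TSS-based gene assignment, expression-by-group contrasts, normalized per-chromosome scores, reciprocal-overlap TAD conservation, boundary-proximity expression |
| `hicplaid.boundary_motifs` | Boundary flank extraction, log-odds PWM scanning on both strands, Altschul–Erickson dinucleotide shuffle background, binomial enrichment |

Conventions: all coordinates 0-based half-open; intervals written as BED;
matrices stored as symmetric sparse with an upper-triangle COO TSV + bin BED
on disk; expression analysed as log10(TPM + 1); every stochastic operation
takes an integer seed and is bit-reproducible.

## CLI

`hicplaid` exposes the pipeline stages:

```bash
hicplaid simulate --outdir demo --seed 1            # synthetic dataset + truth
hicplaid bins genome.fa --site GATC --out bins.bed  # restriction bins
hicplaid matrix pairs.tsv --bins bins.bed --out raw
hicplaid rebin raw --resolution 100000 --out raw100k
hicplaid filter raw100k --remove-chrom chrY --out filt
hicplaid ice filt --out iced
hicplaid compartments iced --peaks peaks.bed --out comp
hicplaid tads iced --windows 3,5,7,10 --pcut 0.01 --out tad
hicplaid switch comp1.labels.bed comp2.labels.bed --out switch.bed
hicplaid genes genes.bed comp.labels.bed --out gene_labels.tsv
hicplaid scores comp.labels.bed --chrom-sizes sizes.tsv --out scores.tsv
hicplaid tadcmp tad1.tads.bed tad2.tads.bed --frac 0.7 --out cmp
hicplaid boundary-expr genes.bed expression.tsv tad.boundaries.bed --dist 40000
hicplaid motifs tad.boundaries.bed genome.fa --pwm jaspar.txt --flank 20000 --out enrich.tsv
```

Matrix commands take/emit a prefix: `<prefix>.bins.bed`, `<prefix>.coo.tsv`
(upper triangle), `<prefix>.bins.tsv` (mask, bias).

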