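# equiprio

Multi-criteria prioritization of SNP-chip markers for candidate genes in
equine meat-quality traits.

## The problem

Horsemeat quality traits (tenderness, color, intramuscular fat, muscle
fiber composition) have essentially no mapped QTLs, so breeders cannot
select on them directly. What does exist is (a) a commercial genotyping
chip with ~70k markers, (b) a literature-derived list of candidate genes
from muscle transcriptomics/proteomics, and (c) rich functional genomics
resources in *other* species. `equiprio` implements the in-silico
prioritization strategy that connects these: annotate every chip marker
in or near a candidate gene — plus every whole-genome-sequencing SNP in
strong linkage disequilibrium (LD) with one — against a battery of
functional and regulatory criteria, keep SNPs that satisfy at least one
criterion, and then keep only genes whose orthologs fall inside QTLs for
meat-quality traits in livestock species that do have mapping data.

## The procedure

For each gene *g* with span *G*, markers are collected from
*G* ± 5,000 bp. The candidate set is expanded with WGS SNPs *s* such that
R²(*s*, *m*) > 0.95 for some chip marker *m* (strict inequality); a chip
marker is prioritized if it passes itself **or** any of its LD partners
passes. A variant passes when at least one of these holds:

* **severe consequence** — missense, stop gained/lost, or splice
  polypyrimidine tract variant (intronic positions 3–17 from the
  acceptor), from a built-in consequence classifier over GFF3 gene models;
* **constrained element** — position inside a multi-species constrained
  element (BED);
* **conservation** — GERP rejected-substitution score ≥ 2 at the base
  (bedGraph; uncovered bases are *missing*, never 0);
* **orthologous regulatory overlap** — the position lifts through a UCSC
  chain file into a regulatory feature (enhancer, promoter, open
  chromatin) of a proxy species' regulatory build (any number of
  (chain, build) pairs; typically human and mouse);
* **TFBS effect** — the rsID has a Gain of TFBS / Loss of TFBS / Score
  Change entry in a TF-binding effect table;
* **miRNA seed site** — for 3′ UTR SNPs, a 6-mer reverse complement of
  mature miRNA positions 2–7 is created or disrupted within ±5 bp of the
  SNP, scanned in gene orientation;
* **polyadenylation** — the SNP lies within ±50 bp of a polyA cluster;
* **CpG island** — recorded always, counted as a criterion only when
  enabled in the configuration.

Passing SNPs are then filtered by gene: a gene survives when one of its
orthologs intersects a meat-and-carcass QTL expanded by ±5,000 bp in the
matching species. Survivors are reported in a fixed-schema table — one
row per (gene, SNP), type `Marker` or `LD`, with LD anchor markers in
brackets — plus a per-stage funnel and a marker–marker LD side report.

All coordinates are 0-based half-open internally; 1-based formats (GFF3,
chip manifests, QTL tables) are converted at the I/O boundary.

## Worked example

The package ships a demonstration bundle whose inputs were engineered so
that the pipeline reproduces the packaged 31-SNP prioritized report
(`equiprio/data/prioritized_snps.tsv`), and a synthetic-data generator
with an independently computed ground-truth manifest.

```bash
python -c "from equiprio.demo import demo_bundle; demo_bundle().write('demo_bundle')"
equiprio run --bundle demo_bundle --out demo_out
```

prints the funnel:

```
chip_probes: 27
chip_snps: 27
after_ld_expansion: 40
annotated_pairs: 40
passing_snps: 31
passing_genes: 19
qtl_supported_genes: 19
final_snps: 31
final_genes: 19
final_markers: 27
```

27 chip markers (18 of which end up as `Marker` rows) are expanded with
13 LD partners to 40 candidate SNPs; 31 pass at least one criterion, all
19 genes carry QTL-supported orthologs, and the final report contains 31
SNPs in 19 genes traceable to 27 chip markers. `equiprio summarize
demo_out/prioritized.tsv` recomputes those counts from the written table,
and the first report rows look like:

```
gene_symbol  type    rs_id        marker_id        consequence      ... human_reg
ACYP2        LD      rs397216526  (BIEC2_307086)   intron variant   ... enhancer
ACYP2        LD      rs69086544   (BIEC2_307086)   intron variant   ... enhancer
AHNAK        Marker  rs69004899   12-26376598-G-A  missense variant ...
```

`equiprio synth --seed 6 --out bundle/` writes a fully synthetic bundle
plus `manifest.json` with the rows the pipeline must recover.

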