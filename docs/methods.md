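# Methods

## Scope

`equiprio` is a desk pipeline: it applies deterministic annotation and
filtering rules to already-computed resources (gene models, conservation
tracks, LD tables, chain files, regulatory builds, TFBS-effect tables,
miRNA catalogs, QTL and ortholog tables). It fits no statistical model
and estimates no parameters; correctness therefore means faithfully
implementing each rule, and the test strategy is oracle comparison
against independent brute-force re-computation rather than statistical
calibration.

## Coordinate conventions

Everything internal is 0-based half-open (`[start, end)`), the BED
convention. Conversions happen exactly once, at the I/O boundary:

* native: BED, bedGraph, UCSC chain;
* converted (1-based inclusive on disk): GFF3 gene models, regulatory
  GFF3, chip manifests, WGS SNP tables, QTL and ortholog tables. The chip
  manifest's base is not standardized across vendors; we declare it
  1-based and document that choice here.

Round-trip identity (read∘write = id, and 1-based position *p* ↔
`[p−1, p)`) is property-tested.

## Consequence classification

A deliberately small classifier replaces a full effect predictor. Per
transcript:

* outside the transcript span but within the gene flank →
  upstream/downstream resolved by strand; the upstream/downstream window
  equals the gene-expansion flank (5,000 bp) because no separate value is
  standard for this use;
* exonic → 5′/3′ UTR by annotation (or by position relative to the CDS
  when UTRs are unannotated); CDS positions translate the affected codon
  for both alleles with the standard genetic code, strand-aware, giving
  synonymous / missense / stop gained / stop lost. Non-coding transcripts
  are out of scope (their exonic positions fall back to a coarse intron
  call);
* intronic → intron variant, plus splice polypyrimidine tract variant
  when the base ranks 3–17 counted from the acceptor end of its intron
  (the two acceptor bases rank 1–2) — the standard VEP window, adopted
  because the term itself does not pin down the coordinates.

A gene's call is the union over its transcripts, which is how one SNP can
be "upstream gene variant, 5′ UTR variant, intron variant" at once.
Severity is missense / stop gained / stop lost / splice polypyrimidine
tract. The classifier is checked against an oracle that rebuilds the full
coding sequence, substitutes the allele, translates both proteins and
compares the affected residue, for 1,000 random variants on both strands,
and against a strand-reflection invariance test.

## Liftover

`lift_point` re-implements single-base liftOver over UCSC chains: choose
the highest-scoring chain covering the position (ties to the lowest chain
id), walk blocks, map inside aligned blocks by offset, report source-gap
positions as unmapped, and reflect minus-strand target coordinates
(`size − 1 − reading_position`). Fraction-match thresholds are
meaningless for width-1 queries and are deliberately absent. Equivalence
with explicit per-base chain expansion is tested over 100 random chains
(gaps, both strands) at every source position.

## Criteria details and tunables

| parameter | default | meaning |
|---|---|---|
| `flank_bp` | 5000 | gene-region expansion; also the QTL expansion and the upstream/downstream window |
| `r2_min` | 0.95 | strict LD cutoff: partners need R² **>** this value; a pair at exactly 0.95 is excluded |
| `gerp_min` | 2.0 | conservation cutoff (inclusive: a score of exactly 2.0 counts) |
| `polya_flank_bp` | 50 | extension around polyadenylation clusters |
| `mirna_window_bp` | 5 | half-window around a 3′ UTR SNP for the seed scan |
| `seed_len` | 6 | miRNA seed length (reverse complement of mature positions 2–7) |
| `cpg_is_criterion` | off | CpG overlap is always recorded; it only counts toward prioritization when enabled |
| `severe_is_criterion` | on | a severe consequence alone suffices to pass |
| `polya_symmetric` | on | ±50 bp on both sides; off = one-sided 5′ extension by gene strand |

Choices worth spelling out:

* **Missing GERP is missing.** Uncovered bases get no score, never 0, and
  can never satisfy the conservation criterion; the report prints an
  empty cell.
* **PolyA extension is symmetric by default.** "Upstream or downstream"
  of a cleavage cluster is ambiguous; the symmetric ±50 bp window is the
  superset and is the default, with strand-directed one-sided extension
  available as a switch.
* **TFBS lookup is by rsID only.** The upstream effect tables are
  promoter-resolved; re-deriving promoters and position-weight-matrix
  scores is out of scope.
* **CpG is recorded but off as a criterion.** CpG-island overlap is an
  annotation of interest but its status as a sufficient criterion is
  doubtful (no reported SNP is justified by CpG alone), so the default is
  conservative and a switch exists.
* **Severe-alone passes.** A missense SNP with no other evidence is kept
  by default (switchable), matching how missense-only rows appear in the
  shipped report.
* **miRNA scanning is gated** on a 3′ UTR call for the gene under
  consideration and runs on the sense strand of that gene only. Only
  6-mer placements overlapping the SNP are compared — placements that
  don't touch the changed base cannot change, which the exhaustive-seed
  property test confirms.
* **LD semantics.** Pairs resolve against chip marker ids, chip rsIDs and
  WGS rsIDs; marker–marker pairs above the cutoff go to a side report
  (they add no new variant); unknown ids produce a warning and are
  skipped; a WGS SNP linked to several markers records all anchors; on
  rsID collisions direct-marker provenance wins.
* **QTL filter.** A gene survives if *any* ortholog intersects *any*
  allowed-class QTL expanded by the flank, in the matching species.
  The trait-class allow-list defaults to `Meat and Carcass` (the QTL
  database's class covering meat-quality traits) and is configurable.
* **Determinism.** Output rows sort by (gene symbol, rsID); the table is
  byte-identical under input permutation, which is asserted in tests.

## Synthetic data

`equiprio.synth.generate(SynthConfig(seed))` builds a toy genome
(3 chromosomes × 60 kb by default) with 12 spaced-out genes (flank-
expanded spans disjoint, so every SNP maps to exactly one gene), 24 chip
markers (plus one duplicate probe), and 30 WGS SNPs, 70% of them linked
above the LD cutoff. Planted positives (defaults: 2 severe, 2 miRNA,
3 constrained, 3 conservation, 2+2 regulatory, 2 TFBS, 2 polyA, 2 CpG)
receive exactly the inputs their criterion needs: an engineered missense
codon, a seed site built from the actual reference window, a width-1
conservation entry above the cutoff, a regulatory feature placed at the
lifted position, and so on. Background conservation scores stay below the
cutoff and spacing rules keep area effects (constrained elements, CpG
windows, polyA extensions, regulatory features) from touching neighboring
SNPs.

The expected outcome is computed by straight-line reference code
(`equiprio._reference`) — full-mRNA translation, per-base chain
expansion, all-pairs scans, exhaustive seed placement — that shares no
logic with the pipeline modules, so the recovery test (pipeline output
equals expected rows exactly, 20 seeds) is a genuine dual-route check.
The generator's chains use target-side gaps and minus-strand targets but
no source-side gaps, so every planted SNP is liftable; the source-gap
branch is exercised by the random-chain property tests instead.

What the generator does **not** emulate: realistic LD structure (no
coalescent model; R² values are drawn directly), realistic conservation
score distributions, sequence-derived CpG islands, overlapping genes, or
real genome sequence. Passing recovery tests therefore demonstrates
correctness of the decision logic on well-formed inputs, not robustness
to the messiness of real annotation resources.

The demonstration bundle (`equiprio.demo.demo_bundle`) is the same idea
pointed at the packaged report: one invented gene per reported symbol,
with transcript structures chosen so each rsID reproduces its printed
consequence string (including the three-transcript case that yields
"upstream gene variant, 5′ UTR variant, intron variant"), score-track
entries equal to the printed GERP values, and engineered TFBS/regulatory/
miRNA inputs. It is a smoke fixture: the coordinates are synthetic and
make no claim about the real genomic context of those SNPs.

## Numerical and degenerate-input choices

* R² comparison is strict (`>`), conservation is inclusive (`≥`);
  both follow the stated cutoffs ("R² > 0.95", "2 or higher").
* Empty inputs are legal everywhere: empty tracks give all-false records;
  an empty pass set gives an empty table with all-zero summary.
* Indels and multi-allelic sites are rejected at parse time; the
  pipeline is SNV-only.
* Chain parsing validates block sums against header spans on every read;
  score-track parsing rejects overlapping intervals.
* The packaged report fixture carries an embedded SHA-256 checksum and a
  pinned row count; the reader refuses altered copies.

## Problem sizes

Default test and acceptance runs use the generator's default scale
(~180 kb genome, 54 SNPs per bundle, 20 seeds) and property suites of
100 chains / 1,000 windows / 1,000 coding variants. These sizes give
exhaustive or near-exhaustive coverage of each rule's branch structure;
scaling them up adds redundant cases rather than new behavior.

## Known limitations

* The consequence vocabulary is the ten terms the report needs; regulatory
  -region terms, splice donor/acceptor terms and protein-impact scores are
  out of scope.
* Whole-interval liftover (split mappings, net/axt) is not implemented —
  only width-1 queries need to be supported.
* TFBS effects are taken on faith from the input table; no motif
  rescoring.
* The QTL filter treats QTL intervals as given; no confidence weighting
  by QTL size or study count.
* bigWig/bigBed binaries are not parsed; the text conversions (bedGraph,
  BED) are canonical inputs.
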