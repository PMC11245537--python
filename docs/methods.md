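# Methods

This note records the models, conventions and design choices behind the
package, and what the synthetic study conditions do and do not establish
about real data.

## Clonotype model and input conventions

A clonotype is one recombined receptor chain. Its identity key
concatenates the CDR3 nucleotide sequence (falling back to the amino-acid
CDR3 for amino-acid-only data — the fallback matters because nucleotide
variants of one amino-acid CDR3 are distinct clones), the V gene, the J
gene and the isotype. Gene calls are collapsed to gene level on ingestion
(`IGHV1-2*02` → `IGHV1-2`); alleles are never discriminated downstream,
because single-cell contig assembly imputes part of the V region and
allele calls there are unreliable. The AIRR `junction_aa` field is taken
as the CDR3 verbatim, with its conserved C/W anchors — no anchor trimming
— matching the common clonotype-caller export convention. All coordinates
(CDR3 spans, peptide match spans) are 0-based half-open intervals.

Productivity filtering removes clonotypes annotated non-productive, those
with an internal stop in the variable region, and those whose CDR3
nucleotide length is not divisible by three (out of frame). Single-cell
droplets are kept only when they contain exactly one heavy and one light
chain; clonal counts are distinct UMIs for bulk data and distinct cell
barcodes for single-cell data. Light chains carry isotype `none`; the
"IgK" label appearing in serum proteomics sample metadata is a
purification-fraction label, not a clonotype isotype.

## Repertoire features

* **V-gene usage** is unweighted: each clonotype contributes one count
  regardless of clonal size, so bulk (UMI-based) and single-cell
  (barcode-based) count definitions, which are not comparable, cannot
  distort the profile. Pairwise Pearson correlation is computed over the
  union of the pair's genes with absent genes imputed 0 (an
  intersection-only option exists; union is the default because
  intersection support inflates correlations for shallow samples).
  Zero-variance pairs yield NaN, never a silent 0.
* **CDR3 overlap** is the Jaccard index on unique CDR3 amino-acid sets,
  with no V/J conditioning. Both-empty input is undefined (NaN).
* **Evenness** uses Hill diversity D_α(f) = (Σ fᵢ^α)^(1/(1−α)) on the
  clonal frequency distribution, α on a default grid 0 to 10 in steps of
  0.1 (the analysis range is standard; the step is our choice). α = 1 is
  the Shannon limit exp(−Σ fᵢ ln fᵢ), the standard continuity treatment
  for Hill numbers; zero frequencies are dropped before evaluation so
  α = 0 counts observed clones. E_α = D_α/n lies in (0, 1], equals 1
  exactly for uniform clone sizes, and is non-increasing in α.
* **Light-chain coherence (LCC)**: within a donor, eligible pairs are
  unordered cell pairs with equal heavy V gene, CDRH3 amino-acid identity
  of 100 %, and *different* computed clonotypes (clonally related cells
  would trivially share the light chain); coherence is the percentage of
  eligible pairs with equal light V gene. Across donors the
  different-clonotype requirement is dropped, since cross-donor cells are
  unrelated by construction. No eligible pairs → the value is undefined
  and reported as NA, not 0.

## Replicate merging

Merging operates on cell tables, not raw reads: barcodes are prefixed per
replicate so pooled droplets never collide, clonotypes are rebuilt and
sizes recounted from pooled barcodes. Consequences: the merged unique-CDRH3
set is exactly the union of the members' sets, and merging is
order-insensitive for a fixed member set. Read-level effects of merging
(consensus building across replicates before clonotype calling) are
deliberately not modelled. Random merge orderings are drawn once per seed
and recorded; the number of orderings per depth is configurable
(default 10).

## Peptide-to-clonotype mapping

References are the variable-region amino-acid sequences of all bulk and
single-cell clonotypes, deduplicated per source at (sequence, clonotype
key); the same sequence present in both sources is kept once per source so
that "both"-source attribution is possible. Substring search uses one
concatenated text with sentinel separators and `str.find`, mapping global
offsets back to entries by bisection — exact matching at 10⁵-entry scale
answers queries in well under a second without an external index.

The filter ladder follows spectral-search practice: contaminant-matching
peptides are removed first; peptides matching only decoy sequences never
become antibody-specific; the CDR3-overlap stage requires ≥ 3 contiguous
residues of intersection between the match span and the reference CDR3
span (both are intervals, so the intersection is contiguous by
construction); uniqueness requires all BCR hits to share one clonotype
identity. Identity for uniqueness is evaluated at the **amino-acid** level
(chain, V gene, J gene, CDR3 aa): peptide evidence cannot distinguish
synonymous nucleotide variants, and nucleotide-level identity would count
such variants as spurious multi-mapping. Hits on both bulk and single-cell
references do not make a peptide multi-mapped — they set source "both".
Isoleucine/leucine equivalence (indistinguishable by mass) is available as
a flag but off by default, since search engines report a concrete residue
choice. Peptides are matched anywhere within the variable region;
constant regions are absent from references by construction. Heavy and
light chains live in one index, with uniqueness evaluated within the
matched chain.

Clonal rank is competition ranking by descending clonal size (ties share
the minimum rank, rank 1 = most expanded). Paired-chain recovery collects
all cells carrying the identified clonotype (at amino-acid identity) and
reports the majority partner clonotype with an ambiguity fraction
(1 − majority share); ties are flagged and broken deterministically by
key. Reporting majority-with-ambiguity rather than discarding ambiguous
cases mirrors how the measured light-chain coherence is used as the
confidence argument for recovery. The class-switch table cross-tabulates
uniquely mapped peptides by reference-clonotype isotype against the serum
fraction of the supporting peptide. CDR3 edit distances are unit-cost
Levenshtein distances (computed with edlib).

## Synthetic data generator

The generator defines the study conditions; every generator is
deterministic given its seed (seeds are combined with stable CRC-based
salts, never Python's process-randomised `hash`).

* **Germline**: a synthetic stand-in for the germline reference — 40 heavy
  V genes (~85-aa framework scaffolds ending where the CDR3 begins), 6 J
  genes (~10-aa suffixes), with IMGT-style names; kappa/lambda analogues
  for light chains. A shared, non-uniform population base usage
  (Dirichlet(2) draw, fixed per germline) with per-donor
  Dirichlet(400·base) perturbation makes unrelated donors' V-gene usage
  correlate around r ≈ 0.7, as observed across human donors, while a
  donor's own usage is identical across sequencing methods.
* **Repertoires**: CDR3 lengths 8–25 with mode 15 (triangular pmf, the
  shape of human CDRH3 length distributions), conserved C…W anchors,
  clone sizes from a power-law rank-size law size(r) = max_size·r^(−s)
  (default s = 1, max 1000 — ~90 % singleton clones, a Zipf-like
  expansion profile). CDR3 nucleotide sequences are back-translated with
  a fixed (lexicographically first) codon per residue, keeping
  nucleotide-level keys deterministic; random synonymous codons are used
  where nucleotide *variants* of one amino-acid CDR3 are needed.
* **Paired-chain data**: a configurable fraction of cells (default 0.5)
  come in pairs sharing heavy V gene and CDRH3 amino-acid sequence with
  distinct CDR3 nucleotides — the eligible pairs for coherence
  evaluation. The first pair member carries the pair's canonical light V;
  the second matches it with probability ρ, otherwise draws from the
  donor's light-gene usage. Measured LCC therefore estimates
  ρ + (1−ρ)·q_c with q_c the small chance of re-drawing the canonical
  gene: ρ = 1 forces 100 %, ρ = 0 sits at the Σ q_v² collision baseline.
* **Serum digests**: serum clonotypes are sampled from the references
  with weight ∝ size^β; β = 0 (the default) makes sampling independent of
  clonal expansion, reflecting the observed weak coupling between BCR
  clonal abundance and serum antibody abundance, and is exposed as a free
  parameter because no quantitative abundance model is established. Each
  heavy clonotype receives a serum isotype from a configurable class-switch
  transition matrix (default biased towards IgG); light chains go to the
  kappa-purified fraction. Each sampled variable region is digested under
  all four protease configurations; contaminant- and decoy-derived
  peptides are appended at configurable rates with ground-truth labels.
* **Digestion**: site-based fully-specific rules — trypsin after K/R not
  before P; chymotrypsin high-specificity after F/W/Y not before P
  (excluding L/M, matching the common search-engine default;
  lower-specificity variants exist but only the enzyme name is usually
  reported); AspN before D; the sequential chymotrypsin+trypsin digest is
  modelled as the union of both site sets on the intact protein, which is
  equivalent for site-based rules. Missed cleavages enumerate windows of
  up to m+1 adjacent fragments (default m = 2), then peptides are
  filtered to 7–40 residues (spectral-search defaults). No semi-specific
  peptides.
* **Decoys**: variable-region-like sequences with shuffled CDR3 interiors,
  guaranteed string-disjoint from the true reference. Contaminants are
  random proteins named with the conventional `CON__` prefix and are
  synthetic stand-ins, not real contaminant databases.

**What the synthetic conditions do not establish.** CDR3s are uniform
random strings — no somatic hypermutation lineages, no convergent motifs,
no biased amino-acid composition — so cross-donor CDR3 sharing is near
zero by construction and peptide multi-mapping is rarer than in real
repertoires, where clonally related sequences make uniqueness genuinely
hard. Isotype-specific constant regions, spectrum-level effects
(intensities, retention times, identification error) and UMI/barcode
error are not modelled; peptide identification is treated as exact. Tests
passing under these conditions validate the computations and their
contracts, not the difficulty of real-data identification.

## Statistics

Group comparisons use Kruskal–Wallis globally and all pairwise two-sided
Wilcoxon rank-sum tests with Bonferroni adjustment (min(1, m·p));
significance threshold 0.05. The rank-sum p is exact when both groups
have ≤ 25 tie-free observations, otherwise a normal approximation with
tie correction — a standard default; the exact branch is verified against
full permutation enumeration in the tests. Pairwise feature values
(correlations, overlaps) are treated as independent observations; this
pseudo-replication is inherent to pairwise designs and is documented
rather than corrected.

## Problem sizes

The bundled analyses and checks run at desk scale, chosen to exercise
every code path with comfortable statistical resolution: 5 000-clonotype
bulk and 1 000-cell single-cell references with 50 serum clonotypes for
the end-to-end identification check; 10 000 clonotypes for usage
recovery; 1 000 cells (500 eligible pairs) for coherence recovery;
10 000-clonotype bulk with 8 replicates of 500 cells for the
depth-overlap curve. The deep-sequencing scale of real studies (10⁵–10⁶
reference sequences) is exercised only by the index performance check.

## Known limitations

* Exact substring matching only; no tolerance for sequencing or
  identification errors in either the reference or the peptides.
* Peptides from a given serum fraction are matched against both chains;
  fraction-restricted search (e.g. kappa fraction vs light chains only)
  is not implemented.
* Heatmap/violin rendering is out of scope; the package emits tidy tables
  and matrices for external plotting.
* Uniqueness of peptide mapping is evaluated across the pooled reference
  index; per-source uniqueness is not configurable per stage.
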