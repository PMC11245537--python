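# abseqmap

Integrated analysis of the human B-cell receptor (BCR) repertoire across
three measurement layers: deep bulk BCR sequencing (bulkBCR-seq),
paired-chain single-cell BCR sequencing (scBCR-seq), and bottom-up serum
antibody proteomics (Ab-seq), in which purified serum immunoglobulins are
protease-digested and the resulting peptides are matched against a
personalised BCR sequence reference.

The package is for immunologists and computational biologists who want to
(i) quantify and compare repertoire features between sequencing methods,
donors and B-cell subsets, (ii) study how sampling depth — in particular
merging single-cell technical replicates — changes repertoire coverage,
and (iii) map serum-antibody digest peptides back to clonotypes to recover
single- and paired-chain V(D)J sequences. A fully seeded synthetic
generator produces repertoires, paired-chain droplets, serum digests,
contaminants and decoys, so the whole pipeline runs and is tested without
any external data.

## What it computes

A *clonotype* is a receptor chain keyed by its CDR3 (nucleotide sequence
when available, else amino acid) plus V gene, J gene and isotype. On top
of clonotype tables (AIRR Rearrangement TSV) the package computes:

* **V-gene usage** — unweighted gene frequencies (each clonotype counts
  once, regardless of clonal size), compared pairwise by Pearson
  correlation over the union of genes.
* **CDR3 overlap** — Jaccard index on unique CDR3 amino-acid sets,
  `J(A,B) = |A ∩ B| / |A ∪ B|`.
* **Clonal expansion** — Hill-diversity evenness profiles,
  `D_α(f) = (Σᵢ fᵢ^α)^(1/(1−α))` over α ∈ [0, 10] (Shannon limit at
  α = 1), normalised by clonotype count: `E_α = D_α / n ∈ (0, 1]`.
* **Light-chain coherence (LCC)** — among cell pairs with the same heavy
  V gene and identical CDRH3 amino-acid sequence but distinct computed
  clonotypes, the percentage sharing the light V gene.
* **Replicate merging** — cumulative pooling of single-cell technical
  replicates (barcodes kept distinct), with the depth-vs-overlap curve
  against a deep bulk repertoire.
* **Peptide→clonotype mapping** — exact-substring matching of digest
  peptides against reference variable regions, pushed through a four-stage
  filter ladder: all (non-contaminant) → antibody-specific (hits a BCR
  reference; decoy-only hits never pass) → CDR3-overlapping (≥ 3
  contiguous residues over the reference CDR3) → uniquely mapped (all
  hits share one amino-acid clonotype identity). Uniquely mapped peptides
  identify a clonotype, annotate its clonal rank and class switching, and
  recover the full V(D)J sequence — plus, via single-cell barcodes, the
  paired partner chain.
* **Group statistics** — Kruskal–Wallis plus pairwise two-sided Wilcoxon
  rank-sum tests with Bonferroni correction.

## Worked example

```python
from abseqmap import (SimulationConfig, default_germline, simulate_repertoire,
                      simulate_paired_repertoire, simulate_abseq_run,
                      build_reference_index, match_peptides, classify_matches,
                      light_chain_coherence_within, evenness_profile)

heavy = default_germline("heavy")
kappa = default_germline("kappa")
cfg = SimulationConfig(n_clonotypes=2000, light_chain_coherence=0.9,
                       n_serum_clonotypes=40, seed=1)

bulk = simulate_repertoire(cfg, heavy, donor="D1", method="bulk")
sc = simulate_paired_repertoire(cfg, heavy, kappa, donor="D1", n_cells=800)

ev = evenness_profile(bulk, alpha_grid=[0.0, 1.0, 2.0, 10.0])
lcc = light_chain_coherence_within(sc)

peptides = simulate_abseq_run([bulk, sc], cfg)
index = build_reference_index([bulk], [sc])
matches, ladder = classify_matches(match_peptides(peptides, index), index)
```

This prints (via the obvious `print` calls):

```
bulk clonotypes: 2000
single-cell clonotypes: 1600 cells: 800
evenness E(0) = 1.0000
evenness E(1) = 0.1406
evenness E(2) = 0.0198
evenness E(10) = 0.0051
LCC: 187/200 pairs = 93.50%
filter ladder: FilterLadder(all=4256, antibody_specific=4256,
               cdr3_overlapping=1053, uniquely_mapped=1026, multi_mapped=27)
```

Reading: `E(0) = 1` by construction (richness normalised by itself) and
the steep drop to `E(1) ≈ 0.14` reflects the power-law clonal expansion of
the simulated bulk repertoire. The paired repertoire's light-chain
coherence (93.5 % over 200 eligible pairs) estimates the configured
coherence rate of 0.9. Of 4256 serum-digest peptides, all are
antibody-specific (no contaminants or decoys were simulated here), 1053
overlap a reference CDR3 by at least 3 residues, and 1026 of those map to
a single clonotype — these identify clonotypes and recover V(D)J
sequences.

A command-line interface mirrors the library
(`abseqmap simulate|features|overlap|evenness|lcc|merge|depth-curve|map-peptides|compare|run`);
`abseqmap run config.yaml --outdir out/` executes the whole pipeline and
writes tidy TSV/FASTA/JSON outputs plus a run manifest.

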