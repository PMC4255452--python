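# pia — phylogenetically-informed annotation

Assigning identities to transcripts from non-model organisms by sequence
similarity alone is unreliable: the closest BLAST hit is often a paralog
with a different function. `pia` annotates candidate genes *phylogenetically*
instead — each candidate is placed by maximum likelihood onto a
pre-calculated reference tree for its gene family, and its position
relative to functionally characterized **landmark** genes says whether it
behaves like an ortholog of the sought gene or like a distant relative.
Because the reference tree is fixed, annotating a query costs one
placement, not one tree inference.

The pipeline, per transcriptome and gene family:

1. **ORF extraction** — six-frame translation of each transcript; every
   stop-to-stop (or edge-truncated) stretch of ≥ 30 amino acids is a
   candidate.
2. **Homology screen** — Smith–Waterman local alignment of each candidate
   against the family's bait proteins (BLOSUM62, gap open −11 / extend −1);
   the Karlin–Altschul expectation `E = K·m·n·exp(−λS)` gates candidates at
   `E ≤ 1e-20` and the best three are retained per family.
3. **Profile alignment** — each retained candidate is added to the family's
   fixed reference alignment; reference columns are immutable, so the
   query lands on exactly the columns the reference tree was fit to.
4. **Placement** — the query is attached to every edge of the reference
   tree in turn; pendant branch length and attachment position are
   optimized under the WAG substitution model with Felsenstein pruning,
   using cached conditional likelihoods of the reference so no edge needs
   a full-tree recomputation. Placements are ranked by log-likelihood and
   weighted by LWR (the per-query softmax over edges).
5. **Annotation** — each placed query is classified against the landmark
   tiers (`LANDMARK1` = characterized genes with the sought function,
   `LANDMARK2` = characterized but functionally different relatives) by
   nearest patristic distance and pendant length; results aggregate into a
   family × sample presence matrix.

Outputs are standard formats: jplace v3 placement documents, Newick trees
with tagged tips, TSV annotation tables.

## Worked example

Simulate a 16-tip, 200-site reference package for a family called
`opsinoid` (`pia simulate --family opsinoid --n-tips 16 --n-sites 200
--seed 21 -o refpkg/`), build a transcriptome FASTA containing one
transcript that encodes a family member evolved from the tree (plus a
random junk transcript), and annotate it:

```sh
pia run -t transcripts.fasta -r refpkg/ -o out/
```

```
sample transcripts: 16 candidate ORFs (min 30 aa)
transcripts/opsinoid: 1 hits passed (E<=1e-20, top 3), 1 placed
outputs written to out
```

`out/annotations.tsv` then contains one record:

```
query_id                  family    best_edge best_lwr pendant_length nearest_LANDMARK1 dist_LANDMARK1 nearest_LANDMARK2 dist_LANDMARK2 flag
opsinoid_hit_UN0001_ORF2  opsinoid  4         0.328899 0.035966       t1                0.012214       t3                0.475461       candidate_ortholog_context
```

reading: of the 16 candidate ORFs only the planted one survived the
E-value gate; it placed best on edge 4 (likelihood weight 0.33, spread
over that edge's short-branch neighbourhood), with the LANDMARK1 tip
`t1` at patristic distance 0.012 substitutions/site, on a short pendant
branch — the configuration expected of an ortholog of the sought gene,
so the flag is `candidate_ortholog_context` and the presence matrix
(`out/presence_matrix.tsv`) gets a 1 in the (opsinoid, transcripts)
cell. The junk transcript produced no record at all. The flag is
advisory context, not an orthology proof: the jplace file reports every
edge's LWR so placements can be inspected on the tree.

Reference packages for real families are assembled from your own curated
data with `pia build-refpkg` (baits FASTA + reference alignment + Newick
topology from any tree program + landmark TSV); the package can
dereplicate sequences, drop long-branch tips and refresh branch lengths
under WAG before sealing the directory with checksums.

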