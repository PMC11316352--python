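# picocult

A culture-genomics toolkit for non-axenic picocyanobacterial culture
collections. It re-implements, as tested reusable components, the analysis
chain such studies run after assembly and binning:

- **`picocult.synthetic`** — synthetic genomes, cultures, shotgun reads,
  gene-taxonomy tables, KO panels and cas-locus tables with recorded ground
  truth, so every downstream stage is testable without external data.
- **`picocult.decontam`** — taxonomy-based contig decontamination
  (consensus-class + off-target-fraction rules), CheckM-style QC gate
  (≥ 80% completeness, ≤ 5% contamination), bin naming.
- **`picocult.ani`** — deterministic fragment-based average nucleotide
  identity (1 kb fragments, 16-mer seeding, ungapped extension) and
  single-linkage clustering at species (95%) and population (85%) cutoffs.
- **`picocult.recruitment`** — interval masking (e.g. rRNA genes), read
  subsampling, 15-mer seeded ungapped read mapping with identity ≥ 0.95 /
  read-coverage ≥ 0.9 / length ≥ 50 filters, coverage-per-Gb statistics and
  breadth-based presence calls (present iff breadth > 95%).
- **`picocult.cooccurrence`** — prevalence filtering (strictly > 5% of
  cultures), ecotype × taxon co-occurrence counts and heat-tree node tables.
- **`picocult.markers`** — marker-panel presence matrices, phycoerythrin
  (cpeA ∧ cpeB) pigmentation calls, ecotype contrasts, Jaccard + PCoA
  gene-content ordination.
- **`picocult.crispr`** — CRISPR-Cas operon completeness per subtype
  (editable YAML schema), per-group prevalence reports, Cas1 hit curation
  (p < 0.01, length > 80 aa, top-10 neighbors) and greedy 90%-identity
  protein clustering.

## CLI

```sh
picocult simulate --config sim.yaml --out simdir/        # synthetic collection
picocult decontam --genes bin_genes.tsv --stats checkm.tsv --out decisions.tsv
picocult ani --genomes genomes/ --out ani.tsv --clusters clusters.tsv
picocult recruit --genome g.fasta --mask rrna.bed --reads culture.fastq.gz --out profile.tsv
picocult cooccur --presence presence.tsv --taxonomy tax.tsv --ecotypes eco.tsv --out heat_tree.tsv
picocult markers --ko ko.tsv --ecotypes eco.tsv --out markers.tsv
picocult crispr --loci cas_loci.tsv --groups groups.tsv --out crispr_report.tsv
picocult cas1-curate --hits hits.tsv --similarities sim.tsv --seqs cas1.faa --out curated.faa
```

All coordinates are 0-based half-open (BED dialect); FASTA output is wrapped
at 80 columns, FASTQ is Phred+33, tables are TSV with one header line.

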