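# slimgo

Summarize and visualize the GO slim composition of gene sets.

From a nucleotide FASTA of coding sequences — plus either a reference
protein database for an external translated search (BLAST+ `blastx` or
DIAMOND) or a precomputed 12-column tabular hits file in BLAST
`-outfmt 6` layout — slimgo:

1. filters hits by E-value (default: remove E > 1e-5), alignment
   length, percent identity and bitscore (minimum thresholds, default 0),
2. keeps one best hit per query, ranked by lowest E-value (default),
   highest bitscore, longest alignment, or highest percent identity
   (ties break by higher bitscore, then input order),
3. transfers GO slim categories from a reference mapping file and writes
   four summary tables per gene set — raw counts and frequencies, at
   both gene-model and locus level (locus ids are gene-model ids with
   one trailing `.N` isoform suffix stripped, e.g. `AT1G01010.1` →
   `AT1G01010`),
4. outer-merges tables from multiple gene sets and renders pie charts,
   bar plots, raw and log10(x+1) heatmaps, and bubble graphs scaled to
   each category's share of its gene set's annotations,
5. calls over/under-represented categories between a focal and a
   reference gene set via a chi-square contingency test: focal-cell
   Pearson residuals > 2 → over, < −2 → under (strict; no
   multiple-testing correction is applied — adjusted/standardized
   residuals are available via `--adjusted`).

An external aligner is never required: any hits file matching
`-outfmt 6` can be fed in directly, and one search can be re-filtered
at many stringencies without re-running it.

## CLI

```sh
# end-to-end with a precomputed hits file
slimgo run --fasta queries.fasta --hits hits.tsv \
    --mapping-gene mapping_gene.tsv --mapping-locus mapping_locus.tsv \
    --label myset --outdir out/

# or let slimgo invoke blastx/diamond (database built beforehand with
# makeblastdb / diamond makedb)
slimgo run --fasta queries.fasta --database ref_db --search-program blast \
    --mapping-gene mapping_gene.tsv --outdir out/

# stage-by-stage (byte-identical to `run` on the same inputs)
slimgo parse-best-hits hits.tsv --evalue 1e-20 --rank-by bitscore --outdir out/
slimgo make-tables --best-hits out/best_hits.tsv \
    --mapping-gene mapping_gene.tsv --n-input 5000 --outdir out/

# merge several gene sets and draw everything ("both" = table + figures)
slimgo merge -m both set1_gene_raw.tsv set2_gene_raw.tsv set3_gene_raw.tsv \
    --outdir merged/

# enrichment of a focal set against a reference set (raw count tables)
slimgo enrich --focal paralogs_gene_raw.tsv \
    --reference transcriptome_gene_raw.tsv --threshold 2 --out enrich.tsv

# synthetic fixture with planted ground truth
slimgo simulate --seed 7 --n-queries 100 --out-dir fixture/
```

Mapping files are 2-column TSVs (`subject_key<TAB>slim_category`, the
"canonical" dialect) or multi-column TAIR-style TSVs
(`--mapping-dialect tair`, `!`-prefixed comment lines, configurable
key/term columns in the API). Categories can be dropped with repeated
`--exclude-category` flags. If `--mapping-locus` is omitted, it is
derived from the gene mapping by collapsing isoform suffixes.

To compare many gene sets, run the pipeline in a shell loop or job
array — one invocation per gene set — then `merge` / `enrich` the
resulting tables.

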