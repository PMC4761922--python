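# specnet

Analysis toolkit for label-free spectral-counting proteomics of a two-group
(control vs. injured) design, plus the downstream network and cross-omics
stages:

- **io_tables** — validated TSV/GMT/FASTA readers and writers for count
  tables, protein metadata, interaction edges, term annotations, transcript
  differential-expression tables and symbol alias maps.
- **synthetic_data** — seeded generators (negative-binomial counts with
  protein-size-dependent means, stochastic-block-model networks,
  module-concentrated annotations, overlap-controlled transcript tables)
  so every stage runs with no external downloads.
- **quant** — per-sample normalization to the mean spectral total, pooled
  (or Welch) unpaired two-tailed t-tests with a ≥2-unique-peptide inclusion
  filter, volcano coordinates, the spectra-per-kDa abundance index and a
  ddCt qPCR fold-change helper.
- **multivariate** — sample PCA (deterministic sign convention) and
  average-linkage hierarchical clustering of rows under 1 − Pearson r.
- **netclust** — score-thresholded interaction graphs (default 0.4), Markov
  clustering (default inflation 1.9), cluster ranking and per-component
  betweenness centrality.
- **enrichment** — log-space upper-tail hypergeometric over-representation
  per cluster, BH adjustment and the dominant-term ("k of n") call.
- **crossomics** — direction-concordant intersection of significant proteins
  and transcripts into a shared signature ordered by protein fold change.
- **pipeline / cli** — end-to-end orchestration with a versioned JSON run
  report; every intermediate written as TSV.

## CLI

```sh
# generate a fully synthetic dataset (plus ground truth and a ready config)
specnet simulate --seed 7 --outdir sim/

# run every stage end-to-end
specnet run --config sim/pipeline.yaml

# individual stages
specnet normalize --counts counts.tsv --groups groups.tsv --out normalized.tsv
specnet de --counts counts.tsv --groups groups.tsv --out differential.tsv
specnet abundance --counts counts.tsv --groups groups.tsv --meta meta.tsv --out abundance.tsv
specnet pca --counts counts.tsv --groups groups.tsv --out scores.tsv
specnet cluster --edges edges.tsv --nodes nodes.txt --out clusters.tsv
specnet enrich --clusters clusters.tsv --annotations ann.tsv --universe universe.txt --out enrichment.tsv
specnet crossomics --protein-de de.tsv --transcripts transcripts.tsv --out-prefix shared
```

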