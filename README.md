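# pbscreen

Analysis toolkit for piggyBac gain-of-function suppressor screens and
rescue transcriptomics:

- **screen calling** — collapse read-level integration records (BED6) to
  events and unique TTAA sites, validate sites against the genome, assign
  sites to genes within a distance window (default 20 kb), and call
  candidate suppressor genes with a binomial test against the TTAA-density
  null (Benjamini–Hochberg corrected, with a multi-experiment recurrence
  filter);
- **differential expression** — low-count filtering, median-of-ratios size
  factors, per-gene method-of-moments dispersion, and a two-group negative
  binomial Wald GLM (log link, IRLS at fixed dispersion);
- **rescue analysis** — classify disease DEGs as transcriptionally rescued
  by a suppressor (p ≥ 0.05 vs healthy AND |log2FC| > 0.5 vs disease),
  compare rescue fractions across suppressor conditions, and run
  binomial-underrepresentation / hypergeometric over-representation tests;
- **motif analysis** — extract strand-oriented promoter windows, scan both
  strands with an IUPAC consensus or a JASPAR PFM (log-odds against the
  empirical background, FPR-bounded threshold), and test motif-bearing-gene
  enrichment with a one-sided Fisher exact test;
- **synthetic data** — toy genomes with TTAA sites at a controlled density,
  integration screens with planted suppressor enrichment, NB count matrices
  with planted disease/rescue effects, and promoter sets with planted motif
  occurrences — each paired with ground truth, so the whole pipeline is
  testable offline.

## Command line

Everything is under a single `pbscreen` entry point:

```sh
# simulate a screen and call candidates
pbscreen sim screen --n-chroms 4 --chrom-length 2200000 --ttaa-rate 0.6 \
    --n-genes 200 --suppressor gene0000 --multiplier 20 --seed 1 --outdir sim/
pbscreen screen call --bed sim/integrations.bed --gtf sim/genes.gtf \
    --fasta sim/genome.fa --window 20000 --min-experiments 2 --q 0.05 --outdir call/

# simulate counts, run DE, classify rescue
pbscreen sim counts --n-genes 2000 --seed 1 --outdir simc/
pbscreen de run --counts simc/counts.tsv --samples simc/samples.tsv \
    --contrast Q128:Q15 --lfc 0.5 --p 0.05 --outdir de/
pbscreen rescue classify --degs de/degs_Q128_vs_Q15.tsv \
    --vs-healthy de/de_Q128_Mtf1_vs_Q15.tsv --vs-disease de/de_Q128_Mtf1_vs_Q128.tsv \
    --out rescue.tsv

# motif scanning and enrichment
pbscreen motif scan --fasta sim/genome.fa --gtf sim/genes.gtf \
    --upstream 1000 --downstream 100 --outdir scan/
pbscreen motif enrich --hits scan/motif_gene_indicator.tsv --regulated regulated.txt

# gene-set overlap statistics
pbscreen rescue overlap --universe-size 11851 --set-a a.txt --set-b b.txt

# whole stage chains from one YAML config
pbscreen pipeline run --config pipeline.yaml --outdir out/ --seed 1
```

A pipeline config selects stages and parameters:

```yaml
seed: 11
stages: [sim_counts, de, rescue]
sim_counts: {n_genes: 2000, de_fraction: 0.15, rescue_fraction: 0.4}
de:
  contrasts: [[Q128, Q15], [Q128_Mtf1, Q15], [Q128_Mtf1, Q128]]
rescue: {healthy: Q15, disease: Q128, suppressor: Q128_Mtf1}
```

Every run writes a `manifest.json` with artifact paths, parameters and
sha256 checksums; all tabular outputs are TSV with `#` provenance headers.

## Notes

- All in-memory coordinates are 0-based half-open; GTF is converted on
  read/write, BED passes through unchanged.
- Wald p-values default to Student-t tails with residual degrees of
  freedom, which stay calibrated at 6–7 replicates; `tail="normal"` gives
  the asymptotic tails.
- The bundled `TGCRCNC` metal-responsive-element consensus is a fixture
  fallback; real analyses should supply a JASPAR PFM via `--motif`.
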