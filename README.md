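# ripseed

Target calling for RIP-Seq experiments and miRNA seed-site enrichment in
the 3'UTRs of the called targets — the computational core of studies that
ask whether an RNA-binding protein shares its mRNA targets with miRNAs.

## The problem

RNA immunoprecipitation followed by sequencing (RIP-Seq) recovers the RNAs
bound by a tagged protein. The design analysed here has three sample
classes: **IP** (tagged-protein immunoprecipitation, 3 replicates),
**CTRL** (tag-only control IP, 2 replicates) and **TOTAL** (pre-IP
whole-lysate RNA, 2 replicates). Two questions follow:

1. *Which transcripts are bound?* For each transcript, with adjusted counts
   defined as raw mapped reads over the library total, the IP-enrichment
   score is

   ```
   score = (AdjustedCounts(IP) − AdjustedCounts(CTRL)) / AdjustedCounts(Total)
   ```

   alongside a per-transcript negative-binomial Wald test of IP vs CTRL
   (median-of-ratios size factors; method-of-moments dispersions shrunk
   50/50 toward a fitted mean–dispersion trend; moderated-*t* reference).
   Transcripts with Benjamini–Hochberg *q* < 0.1 and positive log2 fold
   change are targets; a gene is a target if any of its isoforms is.

2. *Are the targets' 3'UTRs enriched for miRNA seed sites?* Canonical
   conserved site classes (8mer, 7mer-m8, 7mer-A1 — matches to miRNA seed
   positions 2–8, with or without the A opposite position 1) are scanned
   for each miRNA family, and each gene's site density is

   ```
   sites per 1000 bp = (median sites over isoforms / median UTR length) × 1000
   ```

   Target-set density is compared to the expressed-gene background, both
   for all families and for a designated subset of genetically interacting
   families; set overlaps are tested with an upper-tail hypergeometric
   test, and arrest-penetrance tables from enhancer screens with Fisher's
   exact test and the SE of a proportion.

Because real libraries are not bundled, the package ships a first-class
synthetic-study generator (`ripseed.simulate`) producing NB count tables
with a planted bound set, UTRs with exactly recorded planted seed sites,
and binomial phenotype tables — so the whole pipeline is testable end to
end against known ground truth.

## Worked example

```python
from ripseed import SimConfig, simulate_dataset, RIPEnrichment

data = simulate_dataset(SimConfig(rng_seed=1))   # 500 genes, 50 bound, 4x IP effect
res = RIPEnrichment(data.counts, data.gene_map).fit(q_threshold=0.1)
print(res.summary())
```

```
RIP-Seq enrichment results
========================================
transcripts analysed             975
q threshold                      0.1
enrichment-score filter        False
target transcripts                91
target genes                      51
undefined scores (Total=0)         0
median FC targets              3.775
mean FC targets                3.703
median FC all                  0.985
mean FC all                    1.248
```

Of the 51 called target genes, 49 of the 50 truly bound genes are
recovered (sensitivity 0.98) — the planted 4-fold IP enrichment shows up
as a median fold change near 4 among targets versus ~1 over all
transcripts. `res.frame` holds the full per-transcript table
(adjusted-count class means, enrichment score, log2FC, p, q, target call),
`res.target_genes()` the gene-level calls, and `res.plot_fold_change()` a
targets-vs-all box plot.

The same stages are available from the shell:

```sh
ripseed simulate --seed 1 --out sim/
ripseed enrich --counts sim/counts.tsv --genemap sim/gene_map.tsv --q 0.1 --out enr/
ripseed seedscan --utrs sim/utrs.fa --families sim/families.tsv \
    --genemap sim/gene_map.tsv --targets enr/target_genes.txt \
    --expressed sim/expressed_genes.txt --subset fam-01 --out scan/
ripseed run --seed 1 --out out/        # full pipeline + report.json
```

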