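# Methods

## Scope and data model

`ripseed` operates strictly at the transcript count-table level: read
trimming, quality filtering and alignment happen upstream and are outside
the package. The canonical inputs are a transcript × sample count matrix
whose column labels encode sample class and replicate (`IP:1`, `CTRL:2`,
`TOTAL:1`, …), a 3'UTR FASTA keyed by isoform ID with a gene→isoform map,
a miRNA family table (family, member, mature sequence), an expressed-gene
list, and phenotype-penetrance tables (genotype, n scored, n arrested).

## Target calling

**Adjusted counts.** Each cell is divided by its library total, giving
within-library proportions that sum to 1 per sample. A zero-total library
is a hard error naming the sample. For the enrichment score the adjusted
counts are first averaged across replicates within each class — the
minimal-variance symmetric way to collapse replicates when the score
formula is defined on one value per class.

**IP-enrichment score.** `(adj_IP − adj_CTRL) / adj_TOTAL`. When
`adj_TOTAL = 0` with a nonzero numerator the score is undefined and
reported as missing (excluded from summaries) rather than ±∞, which would
contaminate medians; `0/0` is defined as 0. The score is reported for
every transcript and can optionally gate target calls
(`use_enrichment_filter`), but by default the differential test alone
decides, since combining the two criteria is a user-level policy choice.

**NB differential test.** The IP-vs-CTRL comparison is an in-house
negative-binomial Wald test (external differential-expression programs are
deliberately not called; an installed reference implementation is used
only as a cross-check oracle in the test suite):

* *Size factors*: median-of-ratios over transcripts observed in all
  IP+CTRL samples, normalised to geometric mean 1. This also removes the
  composition shift a large bound fraction induces in fixed-depth IP
  libraries.
* *Dispersion*: per-transcript method of moments on size-factor-normalised
  counts, `α̂ = (s² − μ̄)/μ̄²` clipped to [0, 20], shrunk 50/50 toward a
  trend `α(μ) = a₀ + a₁/μ` fitted by least squares to binned medians
  (10 abundance-decile bins). The even split reflects that with 3 vs 2
  replicates the per-transcript estimate and the trend carry comparable
  information.
* *Test*: Wald statistic on the log scale with a +0.5 pseudocount,
  `Var(ln μ̂ᵍ) ≈ (1/nᵍ)(1/μᵍ + α)` per group, referred to a *t*
  distribution with residual-plus-prior degrees of freedom
  (`df = n_IP + n_CTRL − 2 + 5`). The prior df accounts for the
  information contributed by the trend, in the spirit of moderated-t
  approaches; it was fixed by a calibration study on the generator's null
  (target: uniform p-values), not per dataset. All-zero transcripts get
  `p = 1`, `log2FC = 0` and an `all_zero` flag.
* *Multiple testing*: Benjamini–Hochberg (delegated to statsmodels). The
  q < 0.1 threshold is the conventional FDR level for this assay.

**Calls.** A transcript is a target iff `q < q_threshold` and
`log2FC > 0` (enrichment only, never depletion); genes are called by an
any-isoform rule. Fold-change summaries (median/mean of `2^log2FC`) are
reported for targets and for all transcripts.

## Seed-site scanning and density

The seed is mature-miRNA positions 2–8. Site patterns on the UTR sense
strand are: 8mer = rc(seed 2–8)+A, 7mer-m8 = rc(seed 2–8),
7mer-A1 = rc(seed 2–7)+A. The scanner finds every occurrence of the 6-nt
seed core rc(positions 2–7) and classifies each occurrence once by its
flanks (8mer > 7mer-m8 > 7mer-A1; bare 6mers unreported). This "one site
per core occurrence" rule is exactly equivalent to a window scan in which
an 8mer suppresses the 7mer-m8 at its own start and the 7mer-A1 one base
downstream — the property the oracle tests assert. Coordinates are
0-based half-open; UTRs may be supplied as DNA or RNA (T↔U invariant).
Families whose members do not share a seed are rejected on load.

*Conservation semantics.* The scanner reports **all** exact seed matches
for the supplied families; "conserved" is a property of the family list
the user provides, not a computed filter. This differs from pipelines that
consume pre-computed cross-species conserved-site tables, and target-set
densities here are therefore comparable only against backgrounds scanned
the same way (which is what the package does).

Per gene, the density statistic pairs two independent medians over
isoforms — `(median site count / median UTR length) × 1000` — with the
even-count median defined as the mean of the middle two values (so
half-integer medians are legal). Set comparisons average per-gene density
after intersecting both sets with the expressed-gene list; fold change is
targets over background.

## Set and phenotype statistics

* Overlap of two gene sets in a universe of N: upper-tail hypergeometric
  `P(X ≥ k)` including the observed value (over-representation
  convention), with expected overlap `ab/N` and fold enrichment
  `k/(ab/N)`. N is an explicit input — the choice of universe is a
  scientific decision, not a default.
* Fisher's exact test, two-sided by the minimum-likelihood rule (scipy's
  convention). Only an all-zero table is an error; a table with one empty
  margin is degenerate with p = 1.
* SE of a proportion: `sqrt(p̂(1−p̂)/n)`.
* Enhancer screen: each genotype is compared against every reference with
  Fisher's test; a genotype is flagged an *enhancer* when its arrest
  proportion exceeds all references and every comparison has p < α
  (default α = 0.001, the conventional screen cutoff). P-values are raw by
  default, matching fixed-α screen practice; BH adjustment is available.

## Synthetic studies

The generator emulates the statistical structure of the experimental
design rather than its sequencing mechanics:

* **Design**: 3 IP / 2 CTRL / 2 TOTAL libraries at 10⁶ expected reads each
  (depth is not pinned by the design; this desk-scale default is fully
  configurable). 500 genes with 1–3 isoforms, 50 bound, 4-fold IP effect,
  NB dispersion α = 0.05 (variance = m + αm²; α = 0 gives Poisson).
* **Counts**: per-transcript log-normal baselines (σ = 1; a realistic
  dynamic range), bound transcripts multiplied by the IP effect in IP
  libraries, expected proportions renormalised to the configured library
  depth (what fixed-depth sequencing does), NB noise on top. Column sums
  therefore concentrate at the configured sizes; the induced composition
  bias is removed downstream by the size factors.
* **UTRs**: lengths N(200, 60) truncated at 60 nt; planted site counts per
  UTR are Poisson (or `fixed` for exact tests) with mean 3 for bound and
  1 for unbound genes. Bound genes' sites are allocated to the designated
  interacting families (5 of 10 by default) with weight 3:1, producing the
  subset-density > all-family-density > 1 ordering the analysis is meant
  to detect. Sites never overlap (≥1 nt spacing); after planting, each UTR
  is rescanned and free background bases inside any discrepant window are
  mutated until the scan equals the planted record exactly, and family
  seeds are drawn so that no family's pattern is a substring of
  another's — ground truth is exact, not approximate.
* **Expressed genes**: 90% of genes, always including the bound set.
* **Phenotypes**: binomial draws; default screen genotypes use arrest
  probabilities 0.01 (WT), 0.20 (single mutant) and 0.97 (double mutant)
  at n = 300, the penetrance regime the screen statistics are designed
  around.
* **Determinism**: one `numpy` Generator per stage, all seeded from
  `rng_seed` via `SeedSequence`; identical configs give bit-identical
  FASTA/TSV/JSON output.

What the generator does **not** emulate: read-level error, positional
coverage bias, isoform-assignment ambiguity, batch effects, and real UTR
base composition (background is i.i.d. uniform). Passing tests therefore
demonstrate correctness and calibration of the statistical machinery under
the assumed NB/Poisson model, not robustness to artefacts of real
libraries.

## Numerical choices and limitations

* Dispersion clipped to [1e-8, 20]; +0.5 pseudocount in log fold changes;
  BH applied over all transcripts including all-zero ones (which carry
  p = 1 and cannot be called).
* The problem sizes used by the test suite and `scripts/acceptance.py`
  (500-gene studies, a 2000-transcript null) are the package's default
  desk-scale study; all are configurable upward.
* With 2 CTRL replicates the per-transcript dispersion is weakly
  identified; calibration leans on the trend and the moderated df, and is
  verified empirically on the generator's null. On strongly
  non-NB-distributed real data the test's type-I error is not guaranteed.
* The pipeline reports density folds as undefined (null) when a study
  yields no expressed targets, rather than failing the run; the library
  function `density_comparison` itself raises on empty filtered sets.
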