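# Methods

## Methylome classification model

Each gene's methylation state is summarized from per-cytosine bisulfite
calls falling inside its coding-sequence (CDS) intervals. Cytosines are
kept strand-resolved and per-cytosine: the two cytosines of a symmetric
CG dinucleotide are separate sites, matching the granularity of
allc-style caller output. A site found in two overlapping genes' CDS
contributes to both, since no exclusion rule is defensible without
transcript-level evidence. Records with zero coverage are retained as
unobserved sites (they count toward `n_sites`, not `n_covered`).

The weighted methylation level of any read pool is the ratio of summed
methylated to summed total read counts; it is coverage-weighted by
construction, so deeply covered sites dominate, which is the intended
behaviour for read-level binomial testing.

Enrichment is modelled per context as reads drawn i.i.d. from a
Bernoulli with the genome-wide CDS background rate `p_bg` (pooled the
same read-weighted way over all genes). The gene-level statistic is the
one-sided upper tail `P(X >= m)` for `X ~ Binomial(n, p_bg)`; genes
with no reads in a context receive p = 1. The model ignores
overdispersion between sites within a gene; this makes the test
anti-conservative for genes with strongly heterogeneous methylation,
which is acceptable because the decision boundary (clearly enriched vs
background) is far from the bulk of either class in practice, and the
false-call rate is verified empirically under a pure null (the gbM call
rate among covered genes stays at or below the q threshold).

Multiple testing is corrected with Benjamini–Hochberg within each
context, across only the genes passing that context's coverage gate —
one test family per context, since the background is estimated per
context. The BH step-up is delegated to
`statsmodels.stats.multitest.multipletests` and checked in the tests
against a hand-rolled step-up oracle.

### Classification thresholds

| parameter | default | meaning |
|---|---|---|
| `min_reads_per_site` | 3 reads | a site counts as covered at this depth |
| `min_sites` | 20 sites | covered CG sites required to assess a gene |
| `q_threshold` | 0.05 | FDR level for significance in any context |

The gbM call requires CG significance *and* CHG/CHH non-significance.
Requiring non-CG quiescence separates gbM from transposon-like (teM)
methylation, mirroring how the UM definition already tests all three
contexts; without it, heavily teM genes would be called gbM, which is
biologically wrong. Genes passing the CG gate but failing a non-CG
context's own gate are treated as non-significant (q = 1) there rather
than discarded — the alternative (dropping them) would silently remove
genes from every downstream group. Degenerate backgrounds are clamped
to [1e-9, 1 − 1e-9] so the binomial test stays defined on pathological
inputs (all-methylated or all-unmethylated pools).

## Ortholog groups

One-to-one orthologs are reciprocal best hits (RBH) from paired BLAST
tabular searches; the best hit per query maximizes bitscore, breaking
ties by lower e-value and then lexicographic subject id so the pairing
is deterministic. Group labels quantify over *all* samples: Group 1 =
gbM in every set-A sample and UM in every set-B sample; Group 2 = UM
everywhere; Group 3 (within-species mode only) = gbM everywhere. A
missing, undetermined or teM-like call in any sample sends the pair to
`unassigned` — the groups are deliberately conservative, which is why
adding a sample can only shrink them.

## Expression statistics

FPKM is computed as `counts * 1e9 / (lib_size * length)` with library
sizes taken from column sums unless the caller supplies mapped-library
totals. Analyses run on `log10(FPKM + 1)`; the +1 pseudo-count keeps
zeros defined and the transform tag prevents accidental double
transformation.

* **Bootstrap test** (default 1,000 replicates): both gene sets are
  independently resampled with replacement at their original sizes;
  the two-sided p-value is the fraction of centered bootstrap
  differences at least as extreme as the observed difference, with a
  +1/(n_reps+1) continuity adjustment so p is never 0. Independent
  resampling (rather than resampling pairs) is used because the
  compared quantities are means of possibly unpaired, unequal-size
  gene-set distributions.
* **Wilcoxon signed-rank** on paired per-gene differences: zeros
  dropped, ties mid-ranked; the exact two-sided p-value is computed by
  a dynamic-programming enumeration of the sign-flip distribution
  (ranks doubled to integers, so mid-ranks are exact) for n <= 25, and
  a tie-corrected normal approximation above. The cutover at 25 keeps
  the exact path under ~2^25-equivalent work via the DP.
* **Cohen's d** uses the pooled-sample-SD definition with the
  conventional |d| bins 0.2 / 0.5 / 0.8.
* **Discrete difference classes** threshold the per-pair
  `log2((FPKM_x+1)/(FPKM_y+1))` at ±1 by default (boundary inclusive),
  in log2 units even though the surrounding analysis is log10 — the
  fold-change convention in the field is log2. Display clamping to
  ±1.0 is a separate helper and never feeds statistics.
* **Chi-square** on the 2×2 group-by-DEG table is Pearson's without
  Yates continuity correction; expected counts in the intended use are
  in the hundreds, where the correction only biases the statistic.
* **TMM factors** follow the published edgeR algorithm: reference
  sample by upper-quartile closeness to the mean, M/A computed on
  library-size-scaled proportions with zero-count genes removed, 30%
  two-sided trim on M and 5% on A, inverse delta-method-variance
  weighting, and a final rescaling to geometric mean 1. The
  implementation reproduces edgeR 4.0.16 `calcNormFactors` to ~1e-10
  relative on a frozen 200-gene toy (values frozen in the tests). TMM
  and the CPM filter prepare inputs for an external DEG caller; the
  quasi-likelihood F-test itself is out of scope and DEG calls are
  consumed as a table.
* **Coverage equalization** thins each library to a common depth by
  per-count binomial draws with p = target/lib_size, which is unbiased
  on the FPKM scale; the thinning scheme is this package's choice, as
  the operation is usually described without one.

Percent reporting rounds half-up to two decimals, matching how such
shares are conventionally printed.

## Synthetic data: what it does and does not emulate

The methylome generator draws gene classes (default gbM 0.25, UM 0.65,
teM-like 0.10 — a realistic mix for a Brassicaceae gene complement),
per-gene gbM CG levels uniform on [0.30, 0.60] (the range observed
across *A. thaliana* accessions), teM-like rates (CG 0.8 / CHG 0.6 /
CHH 0.1 — generator conventions, not estimates), Poisson site counts
(mean 30 per context per gene) and Poisson coverage (mean 20×), and
binomial reads at the class rate composed with a 0.5% non-conversion
error. Positions, classes and rates are fixed across samples; read
sampling is per-sample. It does **not** emulate chromosomal methylation
clustering, partially methylated genes, strand-asymmetric CG
methylation, or mapping artifacts — so passing recovery tests shows the
classifier's statistical machinery is correct under its own model, not
that real tissues will separate as cleanly.

The expression generator draws latent per-gene log10(FPKM+1) from
group-specific normals (Group 1 ~ N(1.0, 0.35), Group 2 ~ N(0.6,
0.55): gbM genes moderately and tightly expressed, UM genes lower and
more variable), adds the group's between-set shift (Group 1 default
−0.138 log10 units, the reported magnitude for the gbM-loss group in
the motivating comparison), per-sample accession offsets (SD 0.05) and
residual noise (SD 0.05), and realizes counts as gamma-Poisson with
dispersion 0.05 against log-normal gene lengths and library sizes of
2×10⁷ ± 20% (a realistic RNA-seq depth; at much shallower depths the
concavity of log10(·+1) visibly biases log-scale means). It does not
model isoforms, GC/length bias, or correlated genes.

A consequence worth noting for recovery checks: accession offsets are
shared across genes, so they do not average out over a 1,328-gene set.
The standard error of the recovered between-set shift therefore
includes an `offset_sd² (1/n_a + 1/n_b)` term alongside the per-gene
term, and the acceptance script averages over replicate simulations to
damp this component.

## Problem sizes and runtime

Tests and the acceptance script use 200–1,000 genes per methylome,
1,328 + 2,000 ortholog pairs per expression simulation, 500 simulation
rounds for type-I-error checks (bootstrap at 1,000 replicates each),
and 24 replicate simulations for shift recovery — sizes at which every
Monte Carlo band in the checks is comfortably resolved while the whole
suite runs in well under a minute on one CPU.

## Known limitations

* The binomial enrichment test treats reads within a gene as
  independent; PCR or clonal structure would violate this upstream.
* Backgrounds are genome-pooled; species with strong chromosomal
  methylation gradients would warrant stratified backgrounds.
* RBH is a heuristic for one-to-one orthology; recent paralogs can
  displace true orthologs, and no synteny evidence is used.
* The exact Wilcoxon path assumes the doubled ranks are exact
  integers, which holds for mid-ranked ties but not for arbitrary
  externally supplied rank vectors.
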