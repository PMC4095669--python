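# Methods

## The statistic

The package scores each gene's connectivity to a *grouped* seed set rather
than to individual genes. In a thresholded coexpression network with
universe size N containing K seed genes, a gene with degree n and k seed
neighbours is assigned the upper-tail hypergeometric probability
P(X ≥ k) — the chance of drawing at least k seeds in n draws without
replacement. The tail includes the observed k (the standard enrichment
reading), and the cutoff for calling a gene a coexpression "friend" is a
strict P < 10⁻⁸.

Three bookkeeping conventions matter:

- **Self-exclusion.** A gene cannot be its own neighbour, so every gene is
  tested against a population of N − 1; a seed gene is additionally tested
  against the K − 1 *other* seeds. This is what makes seed
  self-connectivity (is the module itself coexpressed?) a well-posed
  per-gene question.
- **N is the realized universe**, i.e. every gene of the filtered
  expression matrix including isolated nodes — not a nominal genome size.
  Enrichment is conditional on the genes actually assessed.
- **No multiple-testing correction for the friend call.** The fixed 10⁻⁸
  cutoff is the decision rule; Benjamini–Hochberg q-values are written to
  the friend table as an extra column for reference only.

The tail is computed from a cached log-factorial table with a
log-sum-exp reduction, so p-values far below the smallest normal double
(e.g. 10⁻⁹⁵) retain full relative precision; tables carry both the
(underflow-floored) linear p and `log10_p`. The test suite checks the
implementation against exact integer-arithmetic enumeration of the PMF
over every valid (k, n, K, N) with N ≤ 60 at relative error ≤ 10⁻¹⁰, and
against `scipy.stats.hypergeom.logsf` on random larger instances.

## Network construction

Pairwise association uses the Spearman rank correlation (average ranks
under ties), i.e. the Pearson correlation of the rank-transformed matrix;
Pearson on the raw values is available via `method="pearson"`. The default
edge rule is the *signed* ρ ≥ 0.3: a literal threshold that excludes
strong negative correlations. Because reasonable readers may want
anti-correlated partners too, `edge_rule="absolute"` keeps |ρ| ≥ t.
The rank transform is applied once and all pairs are correlated with a
single matrix product; only one full gene × gene coefficient matrix is
ever materialised, which is comfortable up to ~20k genes on a laptop.

Rows with any missing value are dropped at read time (logged), so every
pair is correlated over the same samples and the universe N is
unambiguous. Constant genes have no defined rank correlation and must be
removed with `filter_uninformative` before network construction. For
probe-level matrices, `collapse_probes` keeps, per gene symbol, the probe
with the highest mean expression (ties broken by lexicographically
smallest probe id).

## Over-representation analysis

`enrich` tests a query list against each term of a GMT collection with the
one-sided Fisher exact probability of the 2 × 2 overlap table — computed
through the same hypergeometric tail. The default is the EASE variant:
one observed success is removed (floored at zero) before testing, a
deliberately conservative convention for short lists popularised by the
DAVID server; `ease=False` gives plain Fisher. Term membership is
intersected with the population before counting, terms overlapping the
query in fewer than `min_count = 2` genes are dropped, and BH-adjusted
p-values are computed over the reported rows.

## Differential comparison

Friend sets from two conditions are compared purely as sets at the
threshold semantics: `in_both`, `only_a`, `only_b`. A gene absent from the
other condition's universe is flagged `unassessable` rather than counted
as condition-specific — absence of evidence is not loss of coexpression.
No significance test is attached to the difference itself; instead a
per-gene p-value change table is emitted so that collapses (e.g.
10⁻⁵⁴ → 0.2) can be inspected directly.

## Synthetic data generator

The generator emulates the paired study design the pipeline targets: a
"normal" condition (default 65 samples, one per tissue) and a "treated"
condition (default 130 samples, one per chemical exposure). Per sample,
one latent factor f ~ N(0,1) drives the module: gene g has expression
a_g·f + ε with ε ~ N(0, σ²) i.i.d., where a_g is `loading_seed` (default
0.9) for the 56 seed genes, `loading_friend` (default 0.8) for the 200
friend genes, and 0 for background genes. Two intact module genes then
have Pearson correlation a_g·a_h / √((a_g²+σ²)(a_h²+σ²)) — 0.45 for two
seeds at the defaults, safely above the 0.3 edge threshold — which the
tests verify empirically at large sample counts.

Treatment is modelled as decoupling: disrupted genes have their loading
set to 0 in the treated matrix. The disrupted set is the first
⌈disruption_fraction · |module|⌉ module genes in sorted gene-id order, so
ground truth is a pure function of the configuration. Gene ids are
assigned seeds-first, which means the disruption prefix covers the entire
seed set whenever disruption_fraction ≥ seed_size/|module| (≈ 0.22 at the
defaults); at the default disruption of 0.5 the treated condition
therefore retains friend–friend structure but no seed connectivity at
all. Fractions below ~0.2 disrupt only part of the seed set.

Default universe size is 2000 genes: large enough that the seed set is a
small fraction of the genome (K/N = 2.8%, preserving the character of the
hypergeometric test) while keeping 20-replicate all-pairs studies fast.

What the generator does **not** emulate: probe-level artifacts,
normalisation and batch effects, heavy-tailed expression distributions,
multiple overlapping modules, or dose–response structure across
treatments. Passing tests therefore demonstrate that the machinery
recovers block-correlated structure planted under the stated model — not
that any particular biological dataset will behave as cleanly.

## A known property of the single-factor model

With finitely many samples, a background gene whose noise vector
chance-correlates with the latent factor at r acquires realized
correlation ≈ 0.67·r with *every* module gene. At 65 samples,
P(r ≳ 0.3) ≈ 4·10⁻³ per background gene, and such a gene's neighbourhood
is then several-fold seed-enriched, so the hypergeometric test — correctly
describing the realized network — can push it below 10⁻⁸. A handful of
background genes per 2000-gene replicate are therefore called friends even
though their generative loading is zero. This is a property of the model
and sample size, not an artifact of the implementation: under a pure null
(all loadings zero) no gene approaches the cutoff, which the calibration
test verifies over 20 replicates. Friend precision at the defaults
remains ≈ 0.98.

## Numerical and interface choices

- Tail arguments are validated against 0 ≤ k ≤ min(n, K), n ≤ N, K ≤ N,
  with errors naming the violated inequality; k at or below the support
  minimum returns exactly 1.
- Result ordering is total and deterministic: ascending p (via log10_p),
  ties by gene id; edge files are written with gene_a < gene_b and sorted.
- Expression matrices are written with `%.17g`, and parsed with Python's
  correctly rounded `float`, so write → read is bit-exact and pipeline
  reruns with the same config and rng_seed are byte-identical.
- Friend calling uses a strict inequality at the cutoff; `alpha` is
  validated to (0, 1].
- The pipeline aborts on the first failing stage with the stage name in
  the error; exit codes distinguish configuration (2), data-format (3)
  and empty-result (4) failures.

## Problem sizes used by the test suite

Unit tests run on purpose-built graphs and matrices of tens of genes.
Study-scale checks use the default 2000-gene configuration: 20 replicates
for planted-module recovery and for disrupted-seed detection, 20
null-model replicates at 300 genes for calibration, and a full
1.15-million-point oracle grid for the tail statistic. The acceptance
script uses three replicates of the default configuration.
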