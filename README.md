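# coexnet

Seed-set coexpression network analysis for gene expression data.

Many gene groups — the motivating case is the nuclear-encoded subunits of
the mitochondrial respiratory complexes (MRC, complexes I–IV of oxidative
phosphorylation) — act as one functional unit, and the interesting question
is not whether two genes are correlated but whether a gene is connected to
the *group*. `coexnet` implements that analysis end to end:

1. **Network construction.** From a gene × sample expression matrix, every
   gene pair is scored with the Spearman rank correlation ρ (Pearson
   optionally) and an undirected edge is kept when ρ ≥ 0.3 (signed rule;
   |ρ| ≥ threshold available). Isolated genes remain in the universe.
2. **Seed-connectivity test.** Given a seed set of K genes in a universe of
   N, a gene with total degree n of which k neighbours are seeds is scored
   with the upper-tail hypergeometric probability

   P(X ≥ k) = Σ_{i=k}^{min(n,K)} C(K,i)·C(N−K, n−i) / C(N,n),

   computed in log space so that values like 1e−55 keep full relative
   precision. The tested gene is removed from its own population
   (N_eff = N−1) and, if it is a seed, from the seed set (K_eff = K−1).
   Genes with P < 10⁻⁸ are called coexpression **friends** of the seed set;
   seed genes passing the same test against the other seeds form the seed's
   **self-connectivity**.
3. **Differential comparison.** Friend sets (and seed self-connectivity)
   from two conditions — e.g. normal tissues vs chemically treated cells —
   are partitioned into shared and condition-specific genes, with genes
   absent from one condition's universe flagged unassessable. A per-gene
   p-value change table surfaces the largest collapses.
4. **Over-representation analysis.** Gene lists are tested against GMT
   annotation collections with a one-sided exact test on the overlap table,
   by default the EASE variant (one observed success removed), with
   Benjamini–Hochberg adjusted p-values over the reported terms.
5. **Synthetic data.** A single-factor generative model plants a seed
   module plus friend genes (expression = loading × latent factor + noise)
   and can decouple a configurable fraction of the module in a paired
   "treated" condition, so every stage can be validated against known
   ground truth; pairwise correlations are available in closed form.

## Worked example

`examples/seed_friend_scan.py` simulates a study at default scale (2000
genes, a 56-gene seed module with 200 friends, 65 samples), builds the
ρ ≥ 0.3 Spearman network and scores every gene:

```
top genes by seed-connectivity (gene, k seed neighbours, degree n, log10 p):
  G00191  k= 53  n=235  log10p=   -47.4
  G00013  k= 51  n=242  log10p=   -43.6
  G00236  k= 51  n=240  log10p=   -42.8
  G00235  k= 50  n=225  log10p=   -42.5
  G00040  k= 49  n=219  log10p=   -42.1
seed self-connectivity: 55/56 seed genes
friends called: 188; recall of planted friends: 0.92
```

The top genes have ~50 of their neighbours inside the 56-gene seed set —
astronomically unlikely under random draws from a 2000-gene universe,
hence log10 p near −45. Nearly every seed gene is significantly connected
to the rest of the seed set, and 92% of the planted friend genes are
recovered at the 10⁻⁸ cutoff. The other examples cover simulation,
network construction, the two-condition comparison and enrichment; each
prints a short interpretation of its numbers.

The same stages are available from the shell:

```sh
coexnet build --matrix expr.tsv --threshold 0.3 --out-edges E.tsv --out-nodes N.txt
coexnet friends --edges E.tsv --nodes N.txt --seed mrc.txt --out friends.tsv
coexnet compare --friends-a normal.tsv --friends-b treated.tsv --seed mrc.txt --out cmp.tsv
coexnet enrich --genes list.txt --population N.txt --gmt terms.gmt --out enrich.tsv
coexnet run --config study.yml        # the whole study from a YAML config
```

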