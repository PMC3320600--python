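# gencluster

Statistics for asking whether co-regulated genes are **positionally
clustered** along the chromosomes — the pattern seen when a chromatin
regulator acts on whole genomic neighbourhoods (for example the tightly
packed antimicrobial-peptide loci of *Drosophila*) rather than on
scattered individual promoters.

Given a genome annotation and a two-group log2 expression matrix
(mutant vs wild type), the package provides the full analysis chain:

1. **Differential expression** with an empirical-Bayes *moderated
   t-test*: per-gene variances $s_g^2$ (on $d_g$ degrees of freedom) are
   shrunk toward a prior $s_0^2$ carrying $d_0$ degrees of freedom,

   $$\tilde s_g^2 = \frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},
   \qquad
   \tilde t_g = \frac{\widehat{\mathrm{logFC}}_g}
   {\tilde s_g \sqrt{1/n_a + 1/n_b}} \sim t_{d_0 + d_g},$$

   with $(d_0, s_0^2)$ estimated by trigamma moment matching on
   $\log s_g^2$, followed by Benjamini–Hochberg FDR.  Significant genes:
   FDR $< 0.15$ and $|\log_2\text{FC}| > 0.1$ (strict inequalities).
2. **Positional cluster enrichment.**  Two genes are *clustered* when
   they overlap or lie within $w = 10\,000$ bp of each other on the same
   chromosome.  A list of $n$ genes is scored by its number of clustered
   pairs (or, alternatively, the number of genes in at least one pair);
   the null is the same score on 500 random $n$-gene lists drawn
   uniformly from the annotated universe ("the chip").  Reported are the
   ratio observed/expected, the add-one empirical p-value
   $p = (1 + \#\{\text{null} \ge \text{obs}\})/501$, BH FDR across
   lists, and the actual cluster groupings (connected components of the
   pair relation).
3. **Gene-set overlap and GO over-representation** via the upper-tail
   hypergeometric test, $P(X \ge k)$, with BH FDR over GO terms
   (significant at FDR $< 0.05$).
4. A **synthetic-data generator** that plants positional clusters,
   differential effects, list overlap and an enriched GO term with
   recorded ground truth, so the whole pipeline can be benchmarked
   end to end.

Audience: computational biologists analysing bulk two-group expression
experiments who want a self-contained, permutation-calibrated positional
clustering statistic alongside the standard DE/enrichment steps.

## Worked example

Plant 40 clusters of 5 consecutive genes in a 10,000-gene synthetic
genome and score the 200-gene list:

```python
import gencluster as gc

cfg = gc.SimConfig(seed=1)                       # 5 chromosomes x 2,000 genes
ann = gc.simulate_genome(cfg)
lst, truth = gc.plant_clustered_list(ann, 40, 5, 0, seed=2)
res = gc.enrichment(lst, ann, gc.ClusterParams(window=10_000,
                                               n_random=500, seed=3))
print(f"observed={res.observed}  expected={res.null_mean:.2f}  "
      f"ratio={res.ratio:.2f}  p_emp={res.p_emp:.4g}")
grouping = gc.cluster_groupings(lst, ann, gc.ClusterParams(window=10_000))
print(f"components={grouping.n_components}")
```

prints

```
observed=197  expected=4.31  ratio=45.71  p_emp=0.001996
components=40
```

— the planted list shows 197 clustered pairs where a random 200-gene
list averages 4.3, a ~46-fold enrichment at the smallest p the
501-permutation scheme can produce (1/501 ≈ 0.002), and the groupings
recover the 40 planted clusters exactly.

The same analysis is available from the shell:

```bash
gencluster benchmark --seed 5 -o bench/
# planted list clustering: observed=81, expected=2.73, ratio=29.69, p_emp=0.001996
```

which simulates two overlapping mutant-vs-wild-type conditions, runs
DE → significance lists → Venn/overlap → cluster enrichment →
groupings → GO, and writes the report bundle (`de_*.tsv`,
`cluster_enrichment.tsv`, `cluster_groupings.tsv`, `overlap.tsv`,
`go_enrichment.tsv`, `venn_counts.json`, `manifest.json`,
`recovery.json`) plus the generated data and `truth.json`.  The other
subcommands — `simulate`, `de`, `cluster`, `overlap`, `go`, `run` —
expose each stage separately; `gencluster run -c pipeline.yaml` drives a
real dataset from one YAML config.

## Layout

- `src/gencluster/annotation.py` — containers (1-based inclusive coordinates)
- `src/gencluster/io.py` — GFF3/BED/TSV/gene-list/GO-map readers and writers
- `src/gencluster/de.py` — moderated t, BH, significance filter, Venn comparison
- `src/gencluster/cluster.py` — gap/pair statistics, permutation null, groupings
- `src/gencluster/overlap.py` — hypergeometric overlap and GO enrichment
- `src/gencluster/synthetic.py` — generators with planted ground truth
- `src/gencluster/pipeline.py`, `cli.py` — orchestration and console interface

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
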