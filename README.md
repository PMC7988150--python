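# pmikit

Analysis of time-dependent, cell-type-selective transcriptional change
during the postmortem interval (PMI) of brain tissue.

When resected brain tissue sits at room temperature, its transcriptome
does not decay uniformly: activity-dependent neuronal transcripts
collapse within hours, glial (astrocyte/microglia) activation programs
rise reciprocally for at least 24 h, and classical housekeeping genes
barely move — which is precisely why RIN values and reference-gene
normalization fail to flag the change. `pmikit` is for researchers who
work with postmortem brain expression data (or any time-course of tissue
degradation) and want to quantify these dynamics: who is stable, who is
lost, how the losses concentrate in defined gene sets, and how samples
separate globally.

## What it computes

Given a genes × time-points expression matrix (FPKM-like, single
replicate per time point, e.g. 0, 1, 2, 4, 8, 12, 24 h) and replicated
two-group matrices (fresh vs postmortem, high vs low electrical
activity):

* **Stability classification** — replicate-free: per gene,
  d_t = log2((x_t+c)/(x_0+c)); a local noise scale σ̂ estimated across
  genes of similar intensity (sliding-window MAD); z_t = d_t/σ̂ with a
  Šidák-combined best time point and BH-FDR. Calls are *stable* /
  *not-stable* / *indeterminate* (q ≤ 1% and max|d| ≥ log2 1.3 for
  not-stable).
* **Activity-set enrichment** among not-stable genes, the ratio of
  ratios E = (A_ns/A_s)/(N_ns/N_s), at activity-set cutoffs |FC| ≥ 1.3,
  1.4, 1.5; and the mirror-image housekeeping stability ratio.
* **Co-expression kernels** — Pearson graph on log2 profiles
  (r > 0.95, p < 0.001, n = 7, positive correlations only) clustered
  with a re-implemented MCODE (k-core vertex weighting, VWP-gated greedy
  expansion, haircut), yielding the reciprocal falling-neuronal /
  rising-glial kernels with weighted mean ± weighted-SEM profiles.
* **Hypergeometric enrichment** — E = (k/n)/(K/N) with exact upper-tail
  p, including ordered-bin enrichment of the most postmortem-
  downregulated genes (4 bins of 500 by fresh/postmortem ratio).
* **Sample ordination** — PCA on a gene panel with group barycenters and
  80% confidence ellipses (semi-axes √(eigenvalue · χ²₂(0.80)),
  χ²₂(0.80) ≈ 3.2189).
* **Synthetic data** — a first-class generator planting decaying
  neuronal, rising glial, stable background and housekeeping genes with
  multiplicative log2-normal noise, so the whole chain is testable
  without any download. See `docs/methods.md` for the model and every
  default.

## Worked example

```python
from pmikit import (SynthConfig, generate_timecourse, classify_stability,
                    stability_enrichment, correlation_graph, mcode_vertex_weights,
                    mcode_find_clusters, summarize_cluster, enrichment_from_counts)
from pmikit.simulate import activity_truth_at_cutoff
from pmikit.stability import stability_counts

cfg = SynthConfig(seed=1)                     # 5000 genes, 7 time points
tc, truth = generate_timecourse(cfg)

calls = classify_stability(tc)                # stable / not-stable / indeterminate
print(stability_counts(calls))

act = activity_truth_at_cutoff(truth, 1.5)    # activity genes at |FC| >= 1.5
e = stability_enrichment(calls, act, fc_cutoff=1.5)
print(f"E = {e.E:.2f}")

cg = correlation_graph(tc)                    # r > 0.95, p < 0.001, n = 7
w = mcode_vertex_weights(cg)
for c in mcode_find_clusters(cg, weights=w)[:2]:
    c = summarize_cluster(tc, c, weights=w)
    print(len(c), c.direction, f"{c.mean_profile[-1]:.2f}")

print(f"{enrichment_from_counts(356, 99, 5947, 6754).E:.2f}")
```

prints

```
{'stable': 3186, 'not_stable': 752, 'indeterminate': 1062}
E = 25.09
399 rising 4.97
295 falling 0.05
4.08
```

Reading the output: of 5000 simulated genes, 3186 are stable and 752
not-stable (the rest clear only one of the two bars). Activity-dependent
genes at the strictest cutoff are 25-fold over-represented among
not-stable genes relative to the all-gene background — the planted
effect is strong because most planted activity genes are neuronal. The
two largest co-expression kernels are a 399-gene rising (glial) kernel
ending at 5.0× baseline and a 295-gene falling (neuronal) kernel ending
at 0.05× — the reciprocal pattern. The last line recomputes the
enrichment ratio from published class counts (356/99 against 5947/6754),
giving E = 4.08 ≈ 4.1.

The same stages are available from the shell:

```sh
pmikit simulate --seed 1 --outdir out/
pmikit stability --timecourse out/timecourse.tsv --activity-set out/activity_fc1.5.txt
pmikit cluster --timecourse out/timecourse.tsv --out-graphml net.graphml
pmikit run-all --seed 1 --outdir run/      # full pipeline -> run/report.json
```

All file formats are plain text: TSV matrices, one-ID-per-line gene
sets, GraphML networks, JSON reports.

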