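# trnsel

Selection on coding and *cis*-regulatory sequences across a transcriptional
regulatory network (TRN).

## The problem

How does a gene's position in a regulatory network shape the selection
pressures acting on its protein-coding sequence and on its upstream
regulatory sequence?  Answering this requires (i) per-gene estimates of the
population-scaled selection coefficient γ for both sequence classes, from
polymorphism and divergence data, and (ii) network statistics —
connectedness, hub status, betweenness and eigenvector centrality — for the
same genes.  `trnsel` implements the full analysis as a tested pipeline for
population-genetic and systems-biology researchers: McDonald–Kreitman (MK)
count tabulation from genome annotation, a Poisson random-effects selection
model, scale-free network analysis with discrete power-law tail fitting,
and the hub/centrality group comparisons — plus a synthetic-data generator
with known ground truth so every stage can be validated end to end without
any external dataset.

## The model

For gene *i* the MK data are four Poisson counts: silent polymorphic (PS)
and fixed (FS) sites, and polymorphic/fixed counts in a *selected* class —
replacement sites for the coding context, or the ≤1 kb window upstream of
the start codon (truncated at complementary-strand gene bodies) for the
regulatory context.  Expected counts follow a log-linear mixed model

    log E[y_ic] = log L_ic + μ + β_F·I_fixed + (β_R + r_i)·I_sel
                  + (β_RF + s_i)·I_fixed·I_sel + a_i

with independent normal gene-level random effects (a_i, r_i, s_i) and site
opportunities L_ic (Nei–Gojobori-style for coding sites).  The gene-level
log fixation-rate ratio e_i = β_RF + s_i maps to γ through the
Poisson-random-field fixation-probability ratio

    g(γ) = γ / (1 − e^(−γ)),      γ_i = g⁻¹(exp(e_i)),

so e_i = 0 is neutrality (γ = 0).  Genes are classed as near-neutral
(−1 ≤ γ ≤ 1), negative (γ < −1) or positive (γ > 1).  The fit is a
deterministic Laplace-approximate marginal likelihood (the per-gene 3-D
integrals factorise), giving shrinkage estimates of γ per gene.

On the network side, connectedness k is TF out-degree / target in-degree;
hubs are the top 20% of each role class (strict threshold, so ties at the
80th percentile are not hubs); the tail of the connectedness distribution
is fitted as a discrete power law P(k) ∝ k^(−α) above an x_min chosen by
KS-distance minimisation, with a semi-parametric bootstrap goodness-of-fit
p-value; betweenness (min–max rescaled to [0, 1]) and eigenvector
centrality locate genes between core and periphery.

## Worked example

A fully synthetic run with the default study conditions (200 TFs, 1500
targets, scale-free out-degrees, the "paper-regulatory" γ mixture of 93%
near-neutral / 6% negative / 1% positive genes with mixture mean ≈ −0.4):

```python
import trnsel

cfg = trnsel.PipelineConfig(outdir="demo", seed=1, n_boot=100)
art = trnsel.run_pipeline(cfg)

pl = art["power_law"]
print(f"power law: x_min={pl.x_min} alpha={pl.alpha:.2f} gof_p={pl.gof_p:.2f}")
s = art["summaries"]["regulatory"]
print(s["mean_gamma"], s["fractions"])
```

prints

```
power law: x_min=1 alpha=3.09 gof_p=0.05
-0.377 {'near_neutral': 0.921, 'negative': 0.067, 'positive': 0.012}
```

i.e. the degree tail is recovered near its planted exponent (3.0) and the
fitted regulatory γ distribution reproduces the planted mixture: mean
γ ≈ −0.38 and 92% of genes called near-neutral against 93% planted.  The
output directory holds the MK count tables, per-gene γ tables with 95%
intervals and selection classes, node metrics with hub flags, the
power-law fit, all hub/centrality comparisons (Wilcoxon one-tailed for hub
γ contrasts, Yates chi-square for negative-γ enrichment, two-tailed
Wilcoxon for betweenness by selection class), a γ-distribution summary and
a config echo + run log for provenance.  The same stages are available as
CLI subcommands (`trnsel simulate|annotate|fit|network|compare|run-all`)
for file-based inputs (GFF3 + FASTA + variant TSV/VCF, TSV edge lists).

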