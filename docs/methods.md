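# Methods

## Scope and data flow

`trnsel` estimates per-gene population-scaled selection coefficients (γ)
for coding and putative *cis*-regulatory sequences from
polymorphism/divergence count data, and relates them to the topology of a
directed transcription-factor → target network.  The stages are:

1. **variant_annotation** — gene models (GFF3) + genome (FASTA) + labelled
   variant sites (TSV/VCF) → per-gene MK count tables;
2. **selection_model** — count tables → per-gene γ with intervals and
   selection classes;
3. **network_analysis** — edge lists (and optionally probe→gene mapping)
   → degree, hub flags, betweenness, eigenvector centrality, power-law
   tail fit;
4. **group_stats** — γ tables + node metrics → hub/centrality group
   comparisons;
5. **pipeline** — orchestration, provenance, plain TSV/JSON reports;
6. **synthetic_data** — generative counterparts of every input, with a
   ground-truth ledger.

SNP calling, polarisation and alignment are out of scope: variant status
(polymorphic within the focal population vs fixed against the outgroup) is
an input label.

## Regulatory regions

The putative *cis*-regulatory region is the 1000 bp window immediately 5′
of the start codon on the gene's own strand.  Portions overlapping
complementary-strand gene bodies are truncated away (keeping the part
adjacent to the start codon); this is implemented as truncation rather
than whole-region exclusion because the analysis concept is a sub-window
average region length, and whole-region exclusion is kept behind a flag.
Same-strand upstream overlaps are flagged but not truncated.  Regions
empty after truncation drop their gene.  All internal coordinates are
0-based half-open; GFF3 and variant-table I/O convert from the 1-based
inclusive file conventions at the boundary, which confines off-by-one risk
to two functions.

## MK counting rules

Coding variants are classified by strand-aware codon translation under the
standard genetic code; silent means synonymous only.  Nonsense changes
(stop gain or loss) are reported but excluded from the replacement counts
— a conservative choice, since their fitness effects are not described by
the replacement-site model.  Site opportunities are Nei–Gojobori style:
each codon contributes the fraction of its 9 point mutations that are
silent to L_syn and the remainder to L_repl, so L_syn + L_repl equals the
CDS length exactly.  Every variant lands in at most one (gene, class)
cell: coding containment takes precedence over regulatory containment; a
variant inside the CDS of two genes, or equidistant between two
overlapping upstream windows, is excluded and logged; a site inside two
overlapping upstream windows is resolved to the strictly nearest start
codon.  Duplicate positions with conflicting status raise a
data-integrity error rather than being silently resolved.

## Selection model

For gene *i* and cell *c* ∈ {PS, FS, P_sel, F_sel}:

    log E[y_ic] = log L_ic + μ + β_F x_F + (β_R + r_i) x_R
                  + (β_RF + s_i) x_F x_R + a_i,

with a_i ~ N(0, σ_a²), r_i ~ N(0, σ_r²), s_i ~ N(0, σ_s²) independent
(diagonal random-effect covariance; genes independent).  a_i absorbs
per-gene diversity, r_i the per-gene constraint of the selected class, and
s_i the gene-specific log fixation-rate excess.  The γ mapping uses only
the divergence-side fixation-probability ratio g(γ) = γ/(1 − e^(−γ)); the
polymorphism-side dependence on γ present in full Poisson-random-field
treatments is deliberately absorbed into r_i, keeping the estimator
self-consistent with the generator.  g is evaluated through expm1 with a
series expansion below |γ| = 1e−8, and inverted by bracketed Brent root
finding to |g(γ) − r| < 1e−10.

Fitting maximises the Laplace-approximate marginal likelihood: because the
random effects are independent across genes the 3-dimensional integrals
factorise, and each gene's integrand is strictly log-concave, so the inner
posterior modes are found by damped Newton iterations (vectorised across
genes, linear predictors capped at ±30 to guard the exponential).  The
outer problem (4 fixed effects + 3 log standard deviations, the latter
bounded to [e⁻⁶, e²]) is solved with L-BFGS-B from moment-based starting
values, warm-starting the inner modes between evaluations.  The default
backend is therefore fully deterministic; there is no sampling step.
Per-gene intervals are conditional: e_i ± 1.96 sd(s_i | data) pushed
through the monotone mapping, ignoring fixed-effect uncertainty (small at
the gene numbers the model is intended for, and stated here so nobody
mistakes them for joint intervals).

Genes with zero silent counts in both status classes are dropped with a
logged reason (their offset carries no information); fewer than 30 usable
genes triggers a warning; a single gene is refused unless forced.
Classification uses point estimates with the closed interval [−1, 1] as
near-neutral; interval-based classification was considered and rejected as
the default because the downstream class-fraction summaries are defined on
point estimates.

## Network statistics

Connectedness is out-degree for TFs and in-degree for targets; the pooled
vector of both is the default input to the power-law fit (a TF-only mode
exists because only TF degrees reach large values in a TRN).  Hubs are
k > empirical 80th percentile within the role class — strictly greater, so
ties at the threshold are non-hubs and the hub set never exceeds
⌈0.20·n⌉.  Betweenness uses Brandes' algorithm on the directed graph
(regulation has direction), then min–max rescaling to [0, 1] so "1" reads
as network core and "0" as periphery; an undirected option exists.
Eigenvector centrality is computed on the symmetrised adjacency because on
a near-bipartite directed TRN the directed variant collapses to zero on
all source nodes; power iteration runs on A + I (same eigenvectors, but
immune to the ±λ oscillation of bipartite spectra) to tolerance 1e−10
with a 10⁴ iteration cap, normalised to max 1.

The degree-tail fit is the standard discrete-MLE procedure: for each
candidate x_min among observed values, α̂ maximises
−α Σ ln k_i − n ln ζ(α, x_min) (bounded search on [1.01, 6]); x_min
minimises the KS distance between the empirical and fitted tail CDFs,
evaluated at the integer step points where the supremum can occur.
Goodness of fit is a semi-parametric bootstrap: replicates resample the
body empirically and draw the tail from the fitted law (exact inverse-CDF
via the Hurwitz zeta survival function, truncated only below survival
1e−12), refit x_min and α, and p is the fraction of replicate KS values at
or above the observed one.

## Group comparisons

Hub-vs-non-hub γ contrasts are one-tailed Wilcoxon rank-sum tests
(alternative: hub γ lower), run separately for TFs and targets and for
coding and regulatory γ; the enrichment of hubs for genes under negative
coding selection is a Yates-corrected 2×2 chi-square, with "negative"
meaning γ < 0 (the stricter γ < −1 variant is a flag).  Betweenness is
compared two-tailed between positive (γ > 1) and negative (γ < −1)
classes, near-neutral genes excluded.  The exact Wilcoxon backend
(enumeration) is used when both groups have ≤ 8 untied observations;
otherwise the normal approximation with midranks, tie correction and
continuity correction.  No multiple-testing correction is applied, by
design.  Every comparison row carries n, mean and SEM (sd/√n) per group.

## Synthetic data: what it emulates and what it does not

The generator plants: (i) scale-free TF out-degrees from a discrete power
law on [x_min, k_max] (inverse-CDF over the normalised finite support),
targets sampled without replacement so edges are unique; (ii) per-gene γ
from truncated-normal mixtures; (iii) Poisson MK counts whose expectations
follow exactly the log-linear structure above, with
FS/PS = e^δ and F_sel carrying the extra factor g(γ_i); (iv) small genome
fixtures where every planted variant occupies a concrete genomic site
whose annotation class and status are verified against the annotation
module's own assignment rule before being written, so round-trips are
exact by construction.  Fixture gene sets include both strands, one
mid-codon split CDS, and a head-to-head opposite-strand pair with a
shared, truncated upstream gap.

Mixture presets: "paper-regulatory" has weights (0.93, 0.06, 0.01),
component means (−0.2, −4, +2), sds (0.2, 0.75, 0.5) and truncations
(−1, 1), (−∞, −1], [1, ∞) — the weights fix the class fractions, the
means are chosen so the mixture mean is ≈ −0.41, and the sds make the
near-neutral component sharply peaked.  "paper-coding" is symmetric
(weights 0.92/0.04/0.04, means 0/−2/+2) with mean 0.

Count-scale defaults are stated per site and per gene: θ = 0.08 expected
segregating silent sites per site in the sample (a deep, ~40-genome
sample of a hyperdiverse population: pairwise diversity times the
harmonic-number factor of the sample size), log divergence ratio δ = 0.8,
selected-class constraint ρ = −0.1 (sd 0.3 across genes), per-gene
diversity log-normal with sd 0.3, L_syn = 500, L_repl = 1500, L_reg = 905
(the sub-window average after truncation).  These give tens of counts per
cell, enough information per gene that the shrinkage estimator can
separate the mixture components; they are configuration, not constants,
and real datasets with shallower sampling will show stronger shrinkage
toward the overall mean than the recovery tests exhibit.

The generator does **not** simulate linkage, recombination, demography,
site-frequency spectra or alignment/coverage filtering: counts are drawn
at the Poisson-summary level the inference model assumes.  Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under its own assumptions, not robustness to the ascertainment
biases of real resequencing data (e.g. loss of fast-evolving regulatory
regions to alignment filters, which real analyses must keep in mind when
comparing coding and regulatory γ directly).

`hub_gamma_shift` adds a constant to the true γ of genes in the top 20% of
their role class (both contexts), enabling power analyses of the hub
contrasts; default 0.

## Numerical and reproducibility notes

All randomness flows through `numpy.random.Generator` seeded from a single
integer; pipeline stages receive independent spawned streams, so outputs
are bit-identical across reruns of the same configuration.  The test suite
and the acceptance script use moderate problem sizes chosen as adequate
for their statistical assertions: 2000 genes for mixture recovery, 100
replicates for calibration bands, 20 replicates for power checks, 200
small digraphs for the exact betweenness oracle.

## Known limitations

* The per-gene intervals are conditional (posterior sd of s_i only).
* The normal prior on s_i is mis-specified under the heavy-tailed mixture
  truth; shrinkage then biases extreme γ toward zero, which the recovery
  tolerances account for.
* Eigenvector centrality on directed near-bipartite graphs has no
  canonical convention; the symmetrised choice here is stated, not argued
  to be unique.
* The bootstrap GoF p-value inherits the usual discreteness of
  resampling tests at small n_boot.
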