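# Methods

This note documents the statistical models, the parameter choices, and the
design decisions behind `targetfuse`, and states what the synthetic-data
tests do and do not demonstrate about real data.

## Coordinates and data model

All coordinates are 0-based half-open (BED convention) everywhere; 1-based
GTF input is converted on read and nothing downstream reinterprets
positions.  Genes carry one TSS derived from the gene interval and strand
(`start` on +, `end − 1` on −); transcript-level TSSs are out of scope.
Peaks are located by their interval midpoint `floor((start + end − 1)/2)`;
no summit column is required.  Peaks and genes on chromosomes unknown to
the other side are allowed and simply never associate.

## Differential expression

The DE stage is a deliberately simple negative-binomial test, not a
re-implementation of any published package; the *thresholds* — linear fold
change ≥ 2 and BH FDR ≤ 0.05, both inclusive, with "fold change ≥ |2|"
read as `max(FC, 1/FC) ≥ 2` — define the pipeline downstream.

* **Filtering**: a gene is expressed when CPM ≥ 5 in ≥ 3 samples
  (inclusive), computed on raw library sizes.
* **Normalization**: TMM factors (log-ratio trim 30%, intensity trim 5%,
  precision weights, geometric mean 1) computed by hand; the
  implementation agrees with the reference R implementation to six
  decimals on a frozen fixture.  The NB test operates on counts scaled to
  a common effective library size ("pseudo-equalization").
* **Dispersion**: one common dispersion φ (variance μ + φμ²) for all
  genes, estimated by conditional maximum likelihood (qCML) on the
  within-group counts given their group totals, pooled over every
  replicate group in the design.  The mean parameter is conditioned out,
  so the estimator is nearly unbiased at 3 replicates (0.1008 ± 0.002 at
  a true 0.1 in simulation).  A method-of-moments variant
  (`method="moments"`) is kept for reference; it is biased low by a few
  percent at small replicate numbers, which measurably inflated the
  false-positive rate of the test, and is therefore not the default.
* **Test**: exact conditional two-sided test of the group-A sum given the
  total.  The sum of n iid NB(μ, φ) is NB(nμ, φ/n); conditioning on the
  total gives a discrete law whose two-sided p-value is the summed
  probability of all outcomes no more likely than the observed one
  (small-p method).  As φ → 0 this law converges to
  Binomial(t, n_A/(n_A+n_B)), which the tests verify against an
  independent binomial oracle.
* **Fold change**: ratio of TMM-normalized mean CPMs with a 0.1-CPM
  pseudocount.  No shrinkage is applied; reported fold changes of very
  low-expressed genes are accordingly noisy.

## Response classes and clustering

The factor-dependent/independent partition of dysregulated genes is
defined per gene from the two contrasts: a gene called up in the
knockout-IR contrast is class B (factor-independent) regardless of its WT
call; up only in WT-IR is class A; any other dysregulated gene is class C
(repression).  This mirrors the definition of the target set — genes
dysregulated after irradiation in wild type but not in the knockout — at
the gene level.

Hierarchical clustering (distance 1 − Pearson r, complete linkage, cut
into k = 3 clusters; ties in the reference handled deterministically) is
implemented and oracle-tested for organizing the dysregulated genes as in
an expression heatmap, including an overcluster-and-merge variant
(`cluster_and_label`) that cuts the tree into 2k subclusters and merges
subclusters sharing a response label.  It is not used for target-calling
eligibility: classes A and B differ only in the knockout-IR coordinate,
which a correlation distance over four condition means down-weights, and
in simulation a hard 3-cut intermittently fused the A and B programs
(planted-label agreement dropping to ~0.5 in 2–3 of 15 runs).  The
gene-level contrast rule has no such failure mode (agreement ≥ 0.98 on
every simulated run).

Relative expression for clustering and reporting is
`log2(CPM + 1)` quantile-normalized (ties averaged, preprocessCore-style)
and centred on the mean of the untreated wild-type samples; profiles are
replicate-averaged to condition means before distances are computed.

## Peak dynamics

Binding fold change per peak is `(s_IR + 0.5)/(s_UT + 0.5)`; the
pseudocount guards zero-signal windows and is configurable.  Signals may
come from BED columns 5–6 or be summarized as the length-weighted mean
coverage over the peak interval from two bedGraph tracks; both paths share
all downstream code.  Group I is fc ≥ 1.5, Group III fc ≤ 1/1.5 (both
inclusive), Group II strictly between, so the three groups partition the
axis.  Proximity is TSS distance ≤ 1 kb, inclusive.  Binned signal
matrices around peak centers support heatmap-style exports.

## Peak-to-gene association and enrichment

The default association rule is peak-center-to-TSS distance ≤ 10 kb
(inclusive); GREAT-style basal-plus-extension domains (basal 2 kb up /
2 kb down of the TSS, strand-oriented; extension up to 200 kb stopping at
the nearest neighboring basal region; clipped to the chromosome) are a
separate selectable mapping mode.  Measuring from the peak center rather
than the peak edge is a choice; at typical peak widths (a few hundred bp)
it moves the boundary by under half a peak width.

Fold enrichment for a (class, peak-group) cell is the class's association
rate divided by the mean rate over 10 random sets of 200 genes drawn
without replacement (sets may overlap each other) from the expressed
population.  The Fisher 2 × 2 pools the random sets into one comparison
group — the simplest construction consistent with a test against random
gene sets — and this pooling is recorded in the output metadata.  The
two-tailed p-value enumerates the hypergeometric law and sums
probabilities ≤ that of the observed table.  BH across the nine grid
cells is reported alongside the raw p, which remains the headline
statistic.

Exact tests on discrete tables are conservative by construction: their
p-values are stochastically *larger* than uniform, so a raw KS uniformity
check would fail for any correct implementation.  Calibration is
therefore assessed on the randomized ("smoothed") p-value transform
`P(less likely) + U·P(equally likely)`, which is exactly Uniform(0,1)
when the conditional null model holds; the raw p-values are additionally
checked for anticonservativeness (fraction ≤ 0.05 bounded above).  The
null-calibration fixture keeps the gene population an order of magnitude
larger than the cluster and set sizes — as in the motivating design,
where 200-gene sets are drawn from >13k expressed genes — so
finite-population and set-overlap correlations stay negligible.

## Direct targets and triage

A direct target is a class A or C gene (configurable) with ≥ 1 peak
center within the association distance of its TSS; supporting peaks and
distances are recorded.  Triage marks a target **novel** when it appears
in none of the supplied known-target lists and has zero records in the
literature index co-mentioning the gene symbol and the factor term
("p53"), both matched as whole words, case-insensitively — a stated
approximation of a title/abstract database query, with no synonym
expansion.  Druggability is membership in a file-based drug–gene list.
All resources are plain-text inputs; nothing is fetched from the network.

## Synthetic scenarios

The generator emulates the study conditions: one 50-Mb chromosome, 2,000
genes placed with non-overlapping basal domains, a 2-genotype ×
2-treatment design with 3 replicates, NB counts at dispersion 0.1, and
planted programs — 150 A-like genes (log2FC ~ N(+2, 0.5) in WT-IR only),
50 B-like (same effect in both IR conditions), 80 C-like (N(−2, 0.5)) —
plus 600/50/100 Group I/II/III peaks, 70% of A-like genes receiving a
planted Group-I peak within 10 kb of the TSS.  Per-peak signals are the
group's drawn fold change under multiplicative log-normal noise
(σ = 0.15); coverage tracks carry matching rectangular bumps.  Baseline
mean counts are log-normal — LogNormal(ln 50, 1.3) for null genes, and
LogNormal(ln 100, 0.7) floored at 10 for program genes, since detectable
responders are by construction expressed genes.  Sample depths vary
uniformly ±30% to exercise normalization.

The truth manifest lists each gene's program and drawn effects, each
peak's group and planted link, and the **true direct targets**: A/C-program
genes whose drawn effect magnitude meets the 2-fold dysregulation
definition and that have a peak center within the association distance.
A planted gene whose drawn effect falls below the study's own definition
of dysregulation is not a true target — the program label is the sampling
mechanism, not the truth criterion.

What passing the synthetic tests shows: the stages are wired correctly,
the statistics are calibrated under the model they assume, and planted
structure of realistic effect size is recovered with precision and recall
above 0.9.  What it does not show: robustness to features real data have
and the generator does not — per-gene dispersion variation, batch
effects, correlated genes, peak-width and background-signal structure,
mappability artifacts, or annotation errors.

## Determinism and numerics

One pipeline seed drives every stochastic step through fixed-order
derivations; identical configuration and seed give byte-identical outputs
regardless of the output directory.  Conditional NB probabilities are
computed in log space and normalized; two-sided sums use a 1 + 10⁻⁷
relative tolerance when grouping equiprobable outcomes, matching common
practice for exact tests.  Degenerate inputs are defined: empty totals
give p = 1, all-zero tables p = 1, constant expression profiles are
excluded from clustering with a warning, and a TMM pair with fewer than
10 usable genes falls back to factor 1 with a warning.

## Problem sizes

The bundled tests and the acceptance script run desk-scale problems
chosen to exercise every code path at full statistical fidelity: default
scenarios of 2,000 genes and 750 peaks for recovery (five seeded
replicates, reported as means), 200 null scenarios of 300 genes for DE
calibration, and 200 association grids over 8,000-gene populations for
enrichment calibration.
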