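# Methods

This note documents the models, conventions and numerical choices behind
each stage of the pipeline, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Compound catalog and property comparison

A compound table carries six pharmacology properties: molecular weight
(MW, Da), Moriguchi logP (MLOGP, dimensionless), H-bond donor/acceptor
counts (nHDon/nHAcc, non-negative integers), oral bioavailability (OB,
percent) and drug-likeness (DL, in [0, 1]). OB and DL may be missing
(published tables mark unrecorded values with "-"); missingness is a
first-class state encoded as NaN, never as zero. Missing values are
excluded from summaries and can never satisfy a screening threshold — a
compound with unrecorded OB/DL reaches downstream analysis only through
the rescue mechanism.

Between-ingredient property comparison is a two-sample t-test. The
unequal-variance (Welch) form is the default: ingredient libraries differ
in size and spread, and Welch is the robust choice when homoscedasticity
is not established; the pooled form is selectable (`equal_var=True`). The
degenerate zero-variance case returns p = 1 when the means coincide and
raises otherwise, since the statistic is undefined. Under the null the
test is calibrated: the suite verifies a ~5% rejection rate at α = 0.05
over 1000 simulated pairs.

## Screening

Drug-likeness against a reference profile is the Tanimoto similarity
f(a, b) = a·b / (|a|² + |b|² − a·b), defined for non-negative vectors,
symmetric, in [0, 1] (the denominator exceeds the numerator by
|a − b|² ≥ 0), and 1 iff a = b. Both-zero vectors are rejected as
undefined rather than given a conventional value.

The screening rule is `ob >= ob_min AND dl >= dl_min` with *inclusive*
comparisons — chosen so that a compound sitting exactly at the DL = 0.10
threshold passes, matching the ≥ symbols of the published rule. DL is
normally consumed as a precomputed column (the original study took it
from a database); computing it from descriptor vectors against a supplied
reference profile is the alternative path (`compute_dl`).

Rescue is deliberately not a rule: the study rescued failing compounds by
narrative literature citation, so the implementation takes an explicit
whitelist plus a per-compound boolean evidence flag. The screen output
partitions the input ids into passed / rescued / rejected.

The packaged candidate table is treated as the post-rescue candidate list
(32 rows); the two animal-ingredient compounds (Taurine, Lumbrokinase)
ship as a separate two-row table because they have no recorded OB/DL and
enter only by evidence. Screening the combined 34-row table with the full
rescue whitelist yields 22 strict passers + 12 rescued = 34 potential
compounds.

## Networks

C-T networks are undirected, unweighted bipartite graphs: the published
figures show neither direction nor weight, and repeated literature
mentions of the same compound–target pair collapse to a single edge.
Target symbols are normalized to stripped uppercase (the official-symbol
convention). Only degree statistics are computed — the source analysis
uses only degree-like quantities, so betweenness and other centralities
are out of scope.

The mean compound degree is reported as the exact ratio edges/compounds.
For the reference network (102 compounds, 200 targets, 1018 edges) this
is 9.98; the originally printed 9.92 is inconsistent with its own counts
and is not reproduced.

Category fractions are computed as 100·count/total with decimal half-up
rounding to two decimals (e.g. 681/1436 → 47.42%), implemented with exact
decimal arithmetic rather than binary-float round-half-even. Pathology
annotation is many-to-many: a target in two categories counts once in
each, so category totals may exceed the target count. Assignments to
targets absent from the network raise a single warning with a count —
they are expected when a curated category map is applied to a subnetwork.

Exports: SIF (`compound interacts target`), GraphML (with node kind and
category attributes), and an edge TSV that round-trips exactly.

## Enrichment

The over-representation statistic is the upper-tail hypergeometric
probability P(X ≥ k) for overlap k between a query of size n and a term
of size K in a universe of N genes, computed via the survival function
(no 1 − cdf cancellation); k = 0 gives exactly 1. The universe size is a
catalog property (an annotation source covers more genes than any one
term union). Benjamini–Hochberg is the default adjustment at α = 0.05;
the original tool's statistic is not documented, so these are documented
defaults, not an inference of the authors' settings, and both are
configurable. Only terms with k ≥ 1 are reported, sorted by p.

Kappa grouping: for each pair of significant terms, Cohen's kappa is
computed from the 2×2 membership table of the N universe genes
(a = |A∩B|, b = |A\B|, c = |B\A|, d = N − |A∪B|). Pairs with kappa at or
above the threshold (default 0.4, the convention popularized by
functional-annotation tools) are linked and *connected components* form
the groups — chosen over iterative merge heuristics for determinism and
testability. Each group's leading term is its smallest-p member, ties
broken by larger overlap k, then lexicographic name, so the labeling is
fully deterministic. Kappa is undefined (raises) when expected agreement
is 1, i.e. both sets empty or both equal to the whole universe.

## Factorial combination analysis

The design is a full 2^k factorial with two dose levels per compound
coded −1/+1 (low dose → −1). Effects are reported on the response scale
per coded unit: effect(T) = contrast(T)/2^(k−1) is the mean response
change from low to high level of the term.

The ANOVA uses the pooled within-cell mean square as the error term for
every effect (1 df each; residual df = 2^k(n−1)); p-values are F(1, df)
tails with no multiple-testing correction across the 2^k − 1 terms,
matching per-term reporting conventions. Only balanced designs with a
common n are accepted — the summary-statistic reconstruction
SS(T) = n·contrast²/2^k is exact only under balance, and the published
plates are balanced. Unbalanced input raises rather than silently
approximating.

Both entry paths (cell summaries; long-format replicates) reduce to the
same contrast core; their equality on balanced data is an algebraic
identity and is verified to 1e-10 relative tolerance against raw
replicates constructed to match each cell's (n, mean, sd) exactly, and
against statsmodels OLS/anova_lm as an independent oracle.

The ± column of a published summary carries no universal convention. The
default reading here is standard deviation (`dispersion_is="sd"`), under
which the two headline first-order interactions of the reference plates
reconstruct to p < 0.01 (Taurine×Paeonol p = 0.0042 with n = 5;
Rg1×Rb1 p = 8.6e-06 with n = 6). The sem reading is selectable; note that
under the sd reading the Taurine×Geniposide (p = 0.012) and
Paeonol×Geniposide (p = 0.022) interactions do *not* reach 0.01 even
though the source text claims they do — the reconstruction reports what
the numbers give and does not force agreement.

Degenerate inputs: zero within-cell variance yields F = ∞, p → 0 for any
nonzero contrast (noiseless synthetic data), and F = 0, p = 1 for zero
contrasts.

## Synthetic data

Generators are pure functions of their config (seed included): rerunning
with the same config is bit-identical. Defaults encode the reference
study's scales:

- **Library**: per-ingredient counts {PR 120, RO 93, RG 77, PS 56, PN 120,
  AT 106} (572 compounds). MW is log-normal around a per-ingredient
  location (σ_log = 0.45) — molecular weights are positive and
  right-skewed; MLOGP ~ N(2.3, 1.6); OB ~ N(30, 14) clipped at 0;
  DL ~ N(0.28, 0.2) clipped to [0, 1]; donor/acceptor counts are Poisson
  (rates 3.2 / 5.6). 3% of compounds have OB/DL unrecorded. These are
  plausible scales for natural-product libraries, not claims about any
  real database.
- **Edges**: independent per-pair Bernoulli draws with p = mean_degree /
  n_targets (simple, with analyzable expectations), defaults 102
  compounds × 200 targets at mean degree 10. Any isolated node then
  receives one uniform edge so the realized network covers every declared
  node; at these defaults the patch adds ~1 edge in expectation and
  perturbs the mean degree negligibly. A mean degree of 0 yields no edges.
- **Catalog**: 50 terms of size 10–60 over a 9841-gene universe, query of
  146; 5 planted terms draw round(0.8 × size) of their genes from the
  query, background terms are uniform.
- **Plate**: cell mean = baseline + Σ coded·(main/2) + Σ ∏coded·
  (interaction/2), plus N(0, sd) noise, n per cell. The default spec
  inverts the contrast algebra of the reference Taurine/Paeonol/Geniposide
  block (baseline 1.4295, noise sd 0.065 ≈ the pooled within-cell sd), so
  a noiseless draw reproduces its printed cell means exactly.

What the generators do **not** emulate: real compound identifiers or
chemical realism of descriptors; correlated gene-set structure (real
pathway catalogs overlap hierarchically — planted terms here overlap only
through the query); target-degree heterogeneity (hub proteins); plate
effects or non-Gaussian assay noise. Passing calibration tests therefore
demonstrates correctness of the statistical machinery under the stated
models, not robustness to the messiness of real curated databases.

## Problem sizes in the test suite

Calibration suites use 1000 replicates for the factorial type-I error
(accepted band 3.5–6.5% at α = 0.05), 200 replicates each for null ORA
rates and planted-term recovery, and exhaustive small-universe oracle
checks (all hypergeometric instances with N ≤ 12; true subset enumeration
up to N ≤ 8 plus sampled instances at N ≤ 12). These sizes give tight
Monte-Carlo error on the checked bands while keeping the default test run
fast.

## Known limitations

- Only degree-based network statistics; no centrality or module analysis.
- The enrichment grouping is a deterministic approximation of iterative
  merge heuristics used by interactive tools; group boundaries can differ
  from theirs even at the same kappa threshold.
- Factorial analysis is strictly 2-level and balanced; no dose–response
  modeling or formal synergy indices (Bliss/Loewe).
- OB and DL are inputs: the package screens on them but does not predict
  them from structure.
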