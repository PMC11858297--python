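# Methods

This note documents the models, numerical choices and limitations behind
each stage of the package, and what the synthetic benchmark does and does
not establish about real data.

## Synthetic communities

The generator emulates amplicon count tables whose taxa form correlated
modules, plus soil/plant covariates driven by a known causal structure.

**Latent intensity model.** Each taxon's per-sample intensity is
log-normal: `λᵢ = exp(μᵢ + zᵢ)` with `μᵢ ~ N(0, 1)` drawn once per
scenario (a realistic spread of mean abundances across roughly two orders
of magnitude) and `z` a unit-variance Gaussian with block-correlation
structure. The correlation matrix is built from an explicit factor
decomposition — one global factor shared by all modules plus one factor
per module, with module factors correlated at
`r = between_module_corr / within_module_corr` — so it is positive
semi-definite by construction for any admissible parameter choice. A
regular taxon of module *m* has communality `within_module_corr` on
factor *m*; two same-module taxa then correlate at exactly
`within_module_corr`, two taxa of different modules at
`between_module_corr`. Because the copula is Gaussian and the map from
latent Gaussian to counts is monotone (up to sampling noise), the
Spearman structure downstream is controlled by these parameters.

**Planted hubs.** A `module_hub` taxon is given communality
`min(0.95, within + 0.2)`, which raises its correlation with *every*
member of its block (e.g. 0.79 vs 0.70 at the default `within = 0.7`), so
its within-module degree — and hence Zi — is stochastically larger than a
regular member's. A `connector` splits a 0.9 communality budget over two
module factors, a `network_hub` over all of them; their cross-block
correlations sit near the edge threshold by construction, which makes
them genuinely hard cases rather than giveaways.

**Compositional closure.** Counts are drawn per sample from a multinomial
at a fixed `sequencing_depth` (default 50,000 reads), so column sums are
exact and all the usual closure artifacts are present — including a
systematic *negative* correlation between distinct modules, because a
sample in which one module's factor is high assigns proportionally fewer
reads to everyone else. This is deliberate: it is the main compositional
failure mode a correlation-based network method has to survive, and it is
what motivates the module-detection default described below.

**Covariates.** The soil/plant table follows a recursive linear path
model: variables with no incoming path are standard normal; each
endogenous variable is the stated linear combination of its parents plus
Gaussian noise with a configured disturbance sd. With all disturbances
zero the endogenous columns are exact linear combinations — used as an
exactness oracle in the tests. The default structure encodes the causal
hypotheses fertilization studies typically test — nitrate and sodium
suppressing microbial richness and network connectivity directly and via
root growth, ammonium aiding root growth — with illustrative coefficient
magnitudes; `examples/fixture/sem_model.txt` carries the matching demo
model spec.

**Default scenario.** 60 taxa in 3 equal modules, 30 samples, depth
50,000, `within = 0.7`, `between = 0.05`, three planted module hubs and
one connector. These are the benchmark conditions for everything the
acceptance script measures. Seeding uses one root seed with fixed
per-stage offsets (abundances +0, covariates +1) so each table can be
regenerated independently.

**What passing does not show.** Real amplicon data have overdispersion
beyond multinomial (PCR and extraction noise), taxon-specific depth
biases, zero inflation at low abundance, and non-Gaussian dependence; the
generator has none of these. Recovery results here certify the
*machinery* (thresholds, FDR control, modularity, Zi/Pi, ML fitting) on a
clean but compositionally honest substrate, not performance on any
particular real dataset.

## Diversity

Chao1 uses the bias-corrected denominator `2(F2 + 1)`, which stays
defined when no doubletons are observed and matches common amplicon
defaults; the classic `F1²/(2F2)` variant differs when doubletons are
rare, which is documented here rather than hidden. Shannon entropy is in
natural-log units by default (a base flag is provided); published tables
in this domain rarely state the base, and nat units are assumed
throughout, including in Pielou's `J = H/ln S`. Bray–Curtis is computed
on raw counts between samples; samples with zero totals are rejected by
name.

UPGMA is implemented directly rather than through a linkage wrapper so
its tie-break is part of the contract: among pairs at the minimal
distance, the pair whose lexicographically smallest leaf labels sort
first merges first, making trees reproducible across platforms. Cluster
heights are half the average inter-cluster distance, so output trees are
ultrametric for any valid input (property-tested on random matrices, and
heights cross-checked against scipy's average linkage).

## Co-occurrence networks

Correlations are tie-corrected Spearman on relative abundances (a CLR
option exists behind a flag, off by default), two-sided p-values from the
t-approximation, and BH adjustment over all tested pairs jointly. The
edge rule `|ρ| ≥ 0.6` and `q ≤ 0.05` is a default, not a claim about any
particular published analysis — studies in this area frequently leave
their thresholds unstated, so both are explicit configuration. An exact
permutation p-value is available for n ≤ 10 samples, where the
t-approximation is at its weakest. Constant taxa are excluded with a
warning since their correlation is undefined.

The topology report intentionally emits three versions of "degree
centralization": raw Freeman centralization `Σ(d_max − dᵢ)`, its
normalization by `(n−1)(n−2)` (1 for a star, 0 for regular graphs), and
total degree `2|E|`. Published "centralization" magnitudes in the
thousands are incompatible with the normalized index, so all candidate
readings are reported side by side. For n < 3 the normalized index is
reported as 0 by convention.

## Modules, Zi/Pi and keystone taxa

Module detection defaults to deterministic greedy modularity
maximization (no seed sensitivity; Louvain is available as an
alternative) on the unweighted simple subgraph of **positive** edges. The
restriction to positive edges is a considered default: a negative
correlation is evidence of exclusion, not of co-membership, and under
compositional closure distinct modules are systematically anticorrelated
(see above), so counting negative edges as ties merges genuinely separate
modules. On the benchmark scenario the positive-subgraph default recovers
planted modules at mean adjusted Rand ≈ 0.97 over 10 seeds versus ≈ 0.86
when negative edges are included. Negative edges remain in the network
and still count toward degree, Zi and Pi, which are computed on the full
unsigned graph. `positive_only=False` restores the all-edge behavior.

Zi uses the population standard deviation of within-module degrees (the
original node-role convention) with `Zi = 0` when a module is
degree-homogeneous; `Pi = 1 − Σ_t (κ_it/kᵢ)²` with `Pi = 0` for isolated
nodes. Role thresholds `z* = 2.5`, `p* = 0.62` are strict inequalities —
a node exactly at a threshold is peripheral — and are configurable.
Keystone = non-peripheral; the phylum-level summary counts connectors,
module hubs and network hubs, with unannotated nodes grouped as
"unidentified". On the benchmark scenario planted hubs clearly top the Zi
ranking (margin ≈ 1.9 over non-hubs) but only sometimes cross 2.5: with
20-member modules the hub's correlation advantage (0.79 vs 0.70) buys a
moderate degree advantage, and 2.5 population sds is a conservative bar.
That behavior is faithful to how these thresholds work on real networks,
where keystone sets are small.

## Correlation screen

Pairwise-complete Spearman over an arbitrary variable list, with per-pair
n recorded, BH-adjusted q-values reported alongside raw p, and
significance stars (`*` p < 0.05, `**` p < 0.01, `***` p < 0.001, strict)
computed from *raw* p — the convention of the heatmap figures this screen
feeds, which typically show no multiplicity correction; q is there for
readers who want it. Pairs with fewer than 4 complete observations are
rejected rather than silently reported.

## Path models

Only observed-variable recursive models are supported: no latent
constructs, no correlated disturbances, no nonrecursive loops. The
identifiability convention is the standard one for path analysis:
exogenous variances and covariances free (saturated exogenous block),
disturbances mutually uncorrelated. Free-parameter count
`t = #paths + #exo-variances + #exo-covariances + #disturbances` and
`df = p(p+1)/2 − t` hold by construction on every parsed model.

**Estimation.** The ML discrepancy is minimized by BFGS with starting
values from per-equation least squares on S and variances from sample
moments. For this model class the likelihood factorizes per equation, so
those starts are already the ML solution and the optimizer's role is
verification and polish; convergence is declared at gradient norm
below 1e-6 (target 1e-10, 500 iterations cap) and non-convergence is
flagged, never silent. Non-positive-definite trial covariances are
repelled by a large objective value rather than a hard constraint, which
is safe because optimization starts at an admissible point. The same
factorization, coded independently, is the cross-check oracle in the test
suite: estimates, χ², CFI and RMSEA agree to 1e-4 on random models.

**Conventions.** `χ² = (N−1)·F_min` (the Wishart-likelihood convention of
mainstream SEM software; an N multiplier is available behind a flag). N
is a required user input when fitting from a covariance matrix, since the
effective sample size behind a published S is often not recoverable. GFI
is the ML variant `1 − tr[(Σ̂⁻¹S − I)²]/tr[(Σ̂⁻¹S)²]`; the CFI baseline
fixes all covariances at zero with free variances (`df_b = p(p−1)/2`);
RMSEA is 0 by convention when `df = 0`, and whenever `χ² ≤ df` the
formulas force `RMSEA = 0` and `CFI = 1` — a structural property the test
suite asserts, since "CFI = 1, RMSEA = 0" lines in publications are
exactly this consequence.

**Degenerate input.** A singular sample covariance is rejected — unless
the closed-form solution reproduces S exactly, which is the
zero-disturbance limit (data generated with no noise); then the fit is
returned with `F_min = 0` and an explanatory message. This keeps both the
"refuse non-PD input" contract and exact recovery on noiseless data.

## Pipeline

Stages run in order diversity → network → keystone → correlation screen →
path model; each stage reads only declared inputs and prior outputs, a
failing stage halts the run with partial outputs retained and the failure
recorded, and input validation (file existence, sample-ID agreement,
taxonomy coverage, SEM variable availability) happens before any
computation. Identical config + seed yields byte-identical numeric
outputs; wall-clock timings live only in `run_report.json`, which also
echoes every parameter and input checksum so a report alone documents a
run.

## Problem sizes

The benchmark quantities are measured at: 10 communities of 60 taxa × 30
samples for module recovery; 200 null tables of 30 taxa × 20 samples for
the false-edge fraction; 100 random graphs (n ≤ 50) for Zi/Pi agreement;
200 random matrices for ultrametricity; n = 5000 for path-coefficient
recovery; 300–500 replicates at n = 500 for χ² calibration; 20 random
models for closed-form agreement. These sizes give Monte-Carlo error
comfortably below the decision margins they are compared against.
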