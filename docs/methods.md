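# Methods

This note documents the models implemented in `amfassembly`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
choices that affect results.

## Input model

The pipeline starts from a samples × OTUs count table, a rooted
phylogeny whose tips cover the table's OTUs, and per-sample metadata
(habitat category among urban/suburban/exurban/rural, distance to the
urban center in km, soil variables, and Cd/Zn/Fe/Cu/Pb concentrations in
mg/kg with per-element regional background values supplied separately).
Orientation of the table on disk is declared by the caller, never
guessed — silent transposition is the classic OTU-table failure mode.
All-zero rows and columns are dropped at ingest with a warning rather
than rejected, because un-rarefied pipelines produce them routinely.
Tables are stored dense: at the target scale (tens of samples, hundreds
of OTUs) sparse structures buy nothing.

How the phylogeny over ITS-derived OTUs is built is outside this
package's scope; any user-supplied newick tree with branch lengths is
accepted, and the βNTI results are conditional on that tree.

## Generalists and specialists (Levins' breadth)

For one OTU with abundances `a_j` across `n` samples, `P_j = a_j/Σa` and
`B = 1/Σ P_j²`, ranging from 1 (single-sample specialist) to `n`
(perfectly even generalist). `B` is invariant to rescaling the OTU's
abundances.

Classification compares observed breadth with the (α/2, 1−α/2) empirical
quantiles (type-7 linear interpolation) of a permutation null, with
strict inequalities so a breadth exactly on a bound stays neutral.
Defaults: 1000 permutations, α = 0.05 two-sided.

**Null model.** The default null redraws the whole table with fixed row
(sample) and column (OTU) totals using Patefield's contingency-table
algorithm. An OTU's total abundance is preserved while its placement is
randomised conditional on sample depths, which is the established null
family for this classifier. Note that the superficially attractive
alternative — permuting each OTU's abundance vector across samples
independently — leaves `B` mathematically unchanged (breadth depends
only on the multiset of values, not their positions) and therefore
classifies everything as neutral; it is implemented as
`null_model="per_otu_shuffle"` for occupancy-style statistics and as a
documented degenerate case, but must not be used to classify by breadth.
The margin-preserving null requires integer counts. We use Patefield
draws (fill is free) rather than a fill-preserving swap MCMC; the swap
variant conditions on one extra statistic but has no vetted scipy
implementation and mixes slowly.

A consequence worth knowing: an OTU spread by *random* multinomial
placement is exactly the null's own behaviour, so "generalist" here
means *more even than random placement given its total* — near-uniform
deterministic spread — and "specialist" means more concentrated than
random placement. Under the Sloan neutral model with realistic drift
(`N·m` small), placement is overdispersed relative to multinomial, so
many truly neutral OTUs are flagged as specialists; that is a real
property of the classifier (drift concentrates OTUs in space), not an
artifact.

## βMNTD, βNTI and assembly fractions

Patristic distances are path sums of branch lengths between tips.
Weighted βMNTD between samples j and k averages, over each community's
taxa with relative-abundance weights, the distance to the nearest taxon
in the other community; the unweighted variant uses 1/richness weights.
Identical communities give βMNTD = 0.

The null shuffles the tip labels of the distance matrix uniformly at
random (999 iterations by default) and recomputes βMNTD for every pair;
βNTI is the z-score (null sd with ddof = 1). Shuffling permutes the
rows/columns of the patristic matrix rather than re-traversing the tree;
the distribution is identical and a test asserts the fast matrix-product
path agrees with the plain per-pair form to 1e−12. Pairs with null
sd = 0 (e.g. a star phylogeny, or two samples with identical OTU sets —
every taxon's nearest neighbour is itself under any relabelling) are
flagged degenerate with βNTI = NaN, never ±∞, and are excluded from the
assembly fractions. The deterministic fraction counts |βNTI| > 2 over
non-degenerate pairs; with thresholds at ±2 the split is deterministic
(variable selection for βNTI > 2, homogeneous selection for < −2)
versus stochastic in between. Group-wise runs (all / generalists /
specialists) subset the OTU columns, renormalise relative abundances
within the subset, and drop samples emptied by subsetting with a logged
warning.

The abundance-weighted form is the default because the analyses this
package supports use abundance data throughout; iteration count and
weighting are configurable since the underlying literature varies.

## Sloan neutral community model

With community size N (taken as the mean read depth per sample),
migration rate m and detection limit d̄ (detection threshold in
relative-abundance units, default 1 read / N), the stationary
distribution of an OTU with metacommunity relative abundance p is
Beta(Nm·p, Nm·(1−p)), and its predicted occurrence frequency is the
upper tail F(p) = 1 − I_d̄(Nm·p, Nm·(1−p)). The single free parameter
Nm is fitted by least squares on (p, observed frequency) pairs using
bounded scalar minimisation of log Nm on [log 0.1, log 10⁶] split into
five brackets (deterministic, xatol 1e−8); m = Nm/N. Parameterising by
Nm avoids the N–m confounding: Nm is what the data identify. R² =
1 − SSE/SST may be negative and is reported unclamped. If every OTU has
the same occurrence frequency (SST = 0, e.g. a saturated group present
in every sample) the model is unidentifiable and the fit raises instead
of returning a boundary estimate.

95% bands are Wilson score intervals on F(p)·n successes out of n
samples — Wilson rather than Wald because frequencies near 0/1 are
routine and Wald collapses there. Frequencies exactly on a band edge
count as neutral, mirroring the classifier's tie convention. The bands
are approximate: F(p) thresholds the Beta variable at d̄ while real
detection is read sampling (≥ d reads out of N), and p is estimated from
the same table. On matched neutral simulations at the default study
scale the bands cover ~85–90% of observed frequencies at nominal 95%;
the neutral fraction should be read with that slight liberality in mind.

## Nemerow pollution index

`P_i = C_i/S_i` per element; `Pn = √((mean(P)² + max(P)²)/2)`. The
quadratic-mean form guarantees mean(P) ≤ Pn ≤ max(P), is invariant to
common rescaling of concentrations and backgrounds, and never decreases
when any concentration rises. "Polluted" means Pn strictly greater
than 1. Background values are a required input: they are regional
reference data and deliberately not constants of this package.

## Correlation layer

Alpha diversity is richness and Shannon H (natural log). Bray-Curtis
acts on relative abundances. The Mantel test correlates upper triangles
with simultaneous row/column permutation of the second matrix and the
+1-corrected p-value (never exactly 0); the environmental distance
offered per metal is one-dimensional Euclidean. Spearman uses average
ranks with the t-approximation p-value; constant variables yield NaN
flags rather than failing a batch. The βNTI~Pn regression is OLS of the
pairwise βNTI on a pairwise summary of the per-sample Pn — the mean of
the two samples' Pn by default, |ΔPn| as an option, both recorded in the
output — because a pairwise response needs a pairwise predictor and
either mapping is defensible. Significance stars follow the ***/**/*
convention at 0.001/0.01/0.05 with no multiple-testing correction by
default (a Benjamini-Hochberg helper can be applied downstream). Venn
regions partition observed OTUs by category presence (count > 0 in ≥ 1
sample of the category). NMDS is delegated to external tools: the
pipeline emits the Bray-Curtis matrix and validates only that supplied
ordination coordinates have one row per sample.

## Synthetic data: what it emulates, and what it does not

Defaults mirror the target study design: 60 samples in four distance-
quartile categories on a 0–40 km transect, a few hundred OTUs, 1000
reads per sample, long-tailed (log-series, shape 0.995) metacommunity,
migration rate 0.05.

* **Neutral tables** draw local relative abundances directly from the
  Sloan stationary Beta, renormalise within samples and sample reads
  multinomially. Matching the fitted model exactly makes parameter
  recovery a clean test; a dynamic birth-death simulator is out of
  scope.
* **Selection tables** evolve per-OTU environmental optima on the tree
  by Brownian motion (standardised to zero mean/unit variance), then
  down-weight the neutral draws by a Gaussian mismatch
  exp(−s·(E_j−μ_i)²/2σ²) against a per-sample gradient (default evenly
  spaced on [−2, 2], or tied to simulated distance). Brownian evolution
  is what makes selection *phylogenetically* detectable — βNTI has power
  only against conserved niches. `selection_strength = 0` skips the
  weighting and reproduces the neutral generator's draws bit for bit
  (separate random streams for trait evolution and sampling).
* **Sampling-only tables** are plain multinomial draws from the
  metacommunity — the no-assembly baseline whose distribution matches
  the niche classifier's margin-preserving null.
* **Metadata** places metals at background·(1 + gradient + lognormal
  noise) with the gradient decaying (or growing) with distance, and soil
  variables with mild distance trends. Background defaults are
  synthetic placeholders, not measured reference values.
* **Planting** overwrites chosen OTU columns with an exactly uniform
  generalist or a single-sample specialist at roughly the median OTU
  total. Exact uniformity is deliberate: randomly-placed near-uniform
  OTUs are the null's own behaviour and are invisible to the classifier
  by construction.

Not emulated: read-level sequencing error, chimeras and clustering
artifacts; spatially explicit dispersal; temporal dynamics; interactions
between taxa; correlated multi-element pollution sources. Passing tests
on these generators shows the statistics behave correctly under their
own model assumptions — it does not validate the upstream
bioinformatics, nor guarantee the models fit any particular real
community.

## Study conditions used by tests and the acceptance script

Simulation-backed checks run at deliberately modest problem sizes chosen
as realistic desk-scale study conditions: NCM recovery at 60 samples ×
300 OTUs × 10 seeds (median fitted m within ±25% of 0.05); βNTI neutral
calibration at 20 samples × 60 OTUs with 999 nulls (≥ 80% of pairs
stochastic); the strong-selection condition at 20 samples × 150 OTUs
(lognormal σ = 0.5 metacommunity, m = 1.0, s = 1.5, niche σ = 0.4) — the
150-taxon pool is used because a 60-tip tree carries too little
phylogenetic signal for a stable z-score, and m = 1 minimises
demographic noise so the measured signal is selection, not drift;
planted-label recovery at 60 samples with ~200 sampling-only background
OTUs and 1000 permutations; Mantel type-I calibration over 500
replicates at 199 permutations. The acceptance script's showcase study
is 60 samples × 250 OTUs with moderate selection (s = 1.0, σ = 0.4,
m = 0.3, lognormal σ = 1.0) and 15 + 15 planted OTUs.

## Reproducibility

Every stochastic routine takes an explicit seed; the pipeline derives
per-stage sub-seeds from a stable CRC32 hash of (stage name, global
seed) so stage reordering cannot change any stage's stream. Reruns with
the same configuration are byte-identical in every numeric artifact.

## Known limitations

* βNTI conclusions inherit the quality of the input phylogeny; for
  ITS-based OTUs, tree reconstruction is uncertain and the package
  deliberately takes the tree as given.
* The stochastic fraction is not further partitioned into dispersal
  limitation / homogenising dispersal / drift (no Raup-Crick stage).
* The NCM prediction bands slightly under-cover (see above); neutral
  fractions are mildly liberal.
* The margins null flags drift-concentrated OTUs as specialists; on
  strongly drift- or selection-structured communities most taxa will be
  non-neutral, and the generalist/specialist split should be interpreted
  against that baseline.
* Pn aggregates five metals with equal weight; no toxicity weighting.
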