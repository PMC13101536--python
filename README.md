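# amfassembly

Community-assembly analysis for arbuscular mycorrhizal fungi (AMF) OTU
tables sampled along urban heavy-metal pollution gradients — and for any
microbiome survey with the same shape: a samples × OTUs count table, a
rooted phylogeny over the OTUs, and per-sample environmental metadata.

The package answers the question *"is this community assembled by
deterministic selection or by stochastic processes, and does pollution
shift that balance?"* with four linked inferences:

1. **Generalist/specialist classification.** Levins' niche breadth
   `B = 1 / Σ_j P_j²` (with `P_j` the OTU's share of its total abundance
   in sample *j*) is compared per OTU against a permutation null that
   randomises the whole table conditional on sample depths and OTU totals
   (Patefield's algorithm). OTUs above the null's 97.5% quantile are
   habitat generalists, below the 2.5% quantile specialists.
2. **βNTI phylogenetic null models.** Between every sample pair, the
   abundance-weighted beta mean nearest taxon distance
   `βMNTD(j,k) = ½[Σ_{i∈j} f_ij · min_{i'∈k} d(i,i') + Σ_{i'∈k} f_i'k ·
   min_{i∈j} d(i',i)]` is standardised against a tip-label-shuffling null
   to give `βNTI = (βMNTD_obs − μ_null)/σ_null`. Pairs with |βNTI| ≤ 2
   indicate stochastic assembly; βNTI > 2 or < −2 indicate deterministic
   selection.
3. **Sloan neutral community model (NCM).** Each OTU's occurrence
   frequency across samples is predicted from its mean relative abundance
   *p* by the Beta-distribution tail `F(p) = 1 − I_d̄(Nm·p, Nm·(1−p))`;
   the migration rate *m* is fitted by nonlinear least squares and OTUs
   are partitioned into above/within/below the 95% prediction bands.
4. **Nemerow pollution indexing and the correlation layer.** Per-sample
   single-factor indices `P_i = C_i/S_i` combine into
   `Pn = √((mean(P)² + max(P)²)/2)`; βNTI is regressed on pairwise Pn,
   and Mantel/Spearman tests link composition and assembly to the metals.

A synthetic-data module generates communities with *known* assembly
process — neutral tables drawn from the Sloan stationary distribution,
selection-structured tables with Brownian-conserved niche optima, planted
generalists/specialists, and metal gradients along an urban-rural
transect — so every stage is verifiable without any sequencing data.

## Worked example

Simulate a 60-sample, 250-OTU study with conserved environmental
selection along the gradient and 15 planted generalists/specialists, then
run the full pipeline:

```sh
amfassembly simulate --mode selection --n-samples 60 --n-otus 250 \
    --reads 1000 --migration 0.3 --selection-strength 1.0 \
    --plant-generalists 15 --plant-specialists 15 --seed 42 --out demo

amfassembly run-all --table demo/table.tsv --tree demo/tree.nwk \
    --metadata demo/metadata.csv --backgrounds demo/backgrounds.csv \
    --seed 7 --out demo_run
```

The run prints (abridged):

```json
{
  "assembly_fractions": {
    "all":         {"deterministic": 0.440, "stochastic": 0.560},
    "generalists": null,
    "specialists": {"deterministic": 0.501, "stochastic": 0.499}
  },
  "ncm": {
    "all":         {"m": 0.0826, "r_squared": 0.219, "neutral_fraction": 0.496},
    "specialists": {"m": 0.0466, "r_squared": 0.585, "neutral_fraction": 0.445}
  }
}
```

Reading the numbers: about 44% of sample pairs exceed the |βNTI| = 2
threshold for the whole community and ~50% for the specialists —
deterministic selection is strong, as expected for a community simulated
with Gaussian environmental filtering. The planted generalists occupy
every sample identically, so their group has no phylogenetic turnover
(assembly fractions undefined) and no occupancy variation for the NCM to
fit — the pipeline reports both degeneracies instead of inventing values.
The fitted migration rate is higher for the whole community (0.083) than
for the dispersal-limited specialists (0.047).

`demo_run/` also contains per-OTU niche labels, long-format βNTI tables,
per-sample Nemerow indices (`pollution.tsv`), diversity and Bray-Curtis
matrices, per-metal Mantel tests, the βNTI~Pn regression
(`regression.json`), Venn region counts and a run manifest with input
checksums. Rerunning with the same seed reproduces every numeric output
byte for byte.

The same stages are available as `simulate | pollution | niche | bnti |
ncm | stats | run-all` subcommands and as plain library functions
(`amfassembly.classify_otus`, `amfassembly.beta_nti_from_tree`,
`amfassembly.fit_ncm`, ...).

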