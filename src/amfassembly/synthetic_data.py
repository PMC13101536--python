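"""Synthetic communities with known assembly process and pollution structure.

Every analysis stage in this package is verified against data whose ground
truth is known by construction:

* a Yule (pure-birth) phylogeny over OTU tips;
* neutral local communities drawn from the stationary distribution of the
  Sloan neutral community model — for OTU *i* with metacommunity relative
  abundance ``p_i``, local relative abundance is Beta(N*m*p_i, N*m*(1-p_i)),
  renormalised within each sample and sampled to read counts with a
  multinomial of depth N;
* selection-structured communities in which each OTU carries an
  environmental optimum evolved on the tree by Brownian motion (conserved
  niches), and expected abundance is down-weighted by a Gaussian mismatch
  between the optimum and the sample's position on an environmental
  gradient — with ``selection_strength = 0`` this is bit-for-bit the
  neutral generator;
* site metadata with heavy-metal concentrations following a spatial
  gradient away from an urban center.

Defaults mirror the study design this package targets: 60 samples in four
urbanization categories, a few hundred OTUs with a long-tailed (log-series)
metacommunity, read depth 1000 and migration rate 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

from .community_io import CATEGORIES, METALS, SOIL_VARS, OtuTable, SampleMetadata

#: Plausible background concentrations (mg/kg) for the five metals in the
#: synthetic metadata generator.  These are synthetic defaults for simulated
#: soils, not measured reference values; real analyses must supply their own.
DEFAULT_BACKGROUNDS = {"Cd": 0.07, "Zn": 60.0, "Fe": 27000.0, "Cu": 20.0, "Pb": 22.0}


class SimSpecError(ValueError):
    """A simulation spec violates its invariants."""


@dataclass
class NeutralSimSpec:
    """Parameters of the neutral (Sloan stationary) community generator."""

    n_samples: int = 60
    n_otus: int = 300
    reads_per_sample: int = 1000
    migration_rate: float = 0.05
    metacommunity_distribution: str = "logseries"
    logseries_p: float = 0.995   # log-series shape; closer to 1 = longer tail
    lognormal_sigma: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_otus < 2:
            raise SimSpecError("need at least 2 samples and 2 OTUs")
        if not (0 < self.migration_rate <= 1):
            raise SimSpecError("migration_rate must be in (0, 1]")
        if self.reads_per_sample < 1:
            raise SimSpecError("reads_per_sample must be >= 1")
        if self.reads_per_sample * self.migration_rate <= 0:
            raise SimSpecError("N*m must be positive")
        if self.metacommunity_distribution not in ("logseries", "lognormal"):
            raise SimSpecError(
                f"unknown metacommunity distribution {self.metacommunity_distribution!r}"
            )


@dataclass
class SelectionSimSpec(NeutralSimSpec):
    """Neutral generator plus Gaussian environmental filtering.

    ``selection_strength = 0`` reduces exactly to the neutral generator
    (same random draws).  Optima are evolved on ``tree`` by Brownian motion
    with rate ``trait_conservatism`` and standardised to zero mean / unit
    variance, so ``env_gradient`` should live on roughly the same scale
    (default: evenly spaced on [-2, 2]).
    """

    env_gradient: np.ndarray | None = None
    niche_breadth: float = 0.5        # sigma of the Gaussian filter
    selection_strength: float = 1.0
    trait_conservatism: float = 1.0   # Brownian-motion rate on the tree
    tree: dendropy.Tree | None = None

    def validate(self) -> None:
        super().validate()
        if self.niche_breadth <= 0:
            raise SimSpecError("niche_breadth (sigma) must be > 0")
        if self.selection_strength < 0:
            raise SimSpecError("selection_strength must be >= 0")
        if self.env_gradient is not None and len(self.env_gradient) != self.n_samples:
            raise SimSpecError("env_gradient length must equal n_samples")


# ---------------------------------------------------------------------------
# Phylogeny simulation
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_otus: int, seed: int, birth_rate: float = 1.0) -> dendropy.Tree:
    """Simulate an ultrametric Yule (pure-birth) tree with tips OTU_1..OTU_n.

    Forward simulation: starting from a single lineage, each of the k active
    lineages splits after an exponential waiting time with total rate
    ``k * birth_rate``; once n tips exist a final waiting interval is drawn
    and all tips are extended to the present, making the tree ultrametric.
    """
    if n_otus < 2:
        raise SimSpecError("n_otus must be >= 2")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # active leaves with the time at which their subtending branch started
    birth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    t = 0.0
    while len(birth) < n_otus:
        k = len(birth)
        t += rng.exponential(1.0 / (birth_rate * k))
        node = list(birth)[rng.integers(k)]
        start = birth.pop(node)
        node.edge.length = t - start if node.parent_node is not None else None
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[child] = t
    t += rng.exponential(1.0 / (birth_rate * n_otus))
    leaves = sorted(birth, key=lambda nd: birth[nd])
    for i, leaf in enumerate(leaves, start=1):
        leaf.edge.length = t - birth[leaf]
        leaf.taxon = taxa.new_taxon(label=f"OTU_{i}")
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Metacommunity and neutral tables
# ---------------------------------------------------------------------------

def metacommunity_abundances(spec: NeutralSimSpec) -> np.ndarray:
    """Metacommunity relative abundances p (sum to 1), long-tailed.

    Deterministic in ``spec.seed``; the community generators below consume a
    *different* stream, so tests can re-derive p independently.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 0])
    if spec.metacommunity_distribution == "logseries":
        raw = stats.logser.rvs(spec.logseries_p, size=spec.n_otus, random_state=rng).astype(float)
    else:
        raw = rng.lognormal(mean=0.0, sigma=spec.lognormal_sigma, size=spec.n_otus)
    # sort descending so OTU_1 is the most abundant — convenient, not essential
    raw = np.sort(raw)[::-1]
    return raw / raw.sum()


def simulate_neutral_table(spec: NeutralSimSpec) -> OtuTable:
    """Draw an OTU table from the Sloan stationary neutral model."""
    spec.validate()
    p = metacommunity_abundances(spec)
    return _sample_table(spec, p, weights=None)


def simulate_sampling_table(spec: NeutralSimSpec) -> OtuTable:
    """Multinomial sampling of the metacommunity with *no* assembly process.

    Every sample is an independent multinomial draw of ``reads_per_sample``
    reads from the metacommunity relative abundances — pure sampling noise,
    no drift, selection or dispersal limitation.  This is the no-signal
    baseline for permutation classifiers whose null randomises placement
    conditional on margins (``migration_rate`` is ignored).
    """
    spec.validate()
    p = metacommunity_abundances(spec)
    rng = np.random.default_rng([spec.seed, 5])
    counts = rng.multinomial(spec.reads_per_sample, p, size=spec.n_samples).astype(float)
    sample_ids = [f"S{j+1:02d}" for j in range(spec.n_samples)]
    otu_ids = [f"OTU_{i+1}" for i in range(spec.n_otus)]
    return OtuTable(sample_ids, otu_ids, counts)


def _sample_table(spec: NeutralSimSpec, p: np.ndarray, weights: np.ndarray | None) -> OtuTable:
    """Shared sampling core: Beta local abundances, optional selection
    weights (n_samples x n_otus), renormalisation, multinomial reads."""
    rng = np.random.default_rng([spec.seed, 1])
    nm = spec.reads_per_sample * spec.migration_rate
    a = nm * p
    b = nm * (1.0 - p)
    if np.any(a <= 0) or np.any(b <= 0):
        raise SimSpecError("Beta parameters N*m*p and N*m*(1-p) must be positive")
    x = rng.beta(a[None, :], b[None, :], size=(spec.n_samples, spec.n_otus))
    if weights is not None:
        x = x * weights
    totals = x.sum(axis=1, keepdims=True)
    # a sample where every Beta draw is ~0 is astronomically unlikely but guard anyway
    totals[totals == 0] = 1.0
    x = x / totals
    counts = np.empty((spec.n_samples, spec.n_otus), dtype=float)
    for j in range(spec.n_samples):
        counts[j] = rng.multinomial(spec.reads_per_sample, x[j])
    sample_ids = [f"S{j+1:02d}" for j in range(spec.n_samples)]
    otu_ids = [f"OTU_{i+1}" for i in range(spec.n_otus)]
    return OtuTable(sample_ids, otu_ids, counts)


# ---------------------------------------------------------------------------
# Selection-structured tables
# ---------------------------------------------------------------------------

def brownian_optima(tree: dendropy.Tree, rate: float, seed: int) -> dict[str, float]:
    """Evolve a continuous trait on the tree by Brownian motion.

    Root value 0; each edge adds N(0, rate * branch_length).  Returns raw
    (unstandardised) tip values keyed by tip label.
    """
    rng = np.random.default_rng([seed, 2])
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    optima: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        val = values[id(node.parent_node)] + rng.normal(0.0, math.sqrt(max(rate * bl, 0.0)))
        values[id(node)] = val
        if node.is_leaf():
            optima[node.taxon.label] = val
    return optima


def simulate_selected_table(spec: SelectionSimSpec) -> tuple[OtuTable, dict[str, float]]:
    """Draw a table under Gaussian environmental filtering of conserved niches.

    Expected local abundance of OTU i in sample j is proportional to
    ``x_ij * exp(-s * (E_j - mu_i)^2 / (2 sigma^2))`` where x_ij is the
    neutral Beta draw, E_j the sample's gradient position and mu_i the
    OTU's (standardised) Brownian optimum.  Returns the table and the true
    optima for test assertions.
    """
    spec.validate()
    p = metacommunity_abundances(spec)
    tree = spec.tree if spec.tree is not None else simulate_phylogeny(spec.n_otus, spec.seed)
    raw = brownian_optima(tree, spec.trait_conservatism, spec.seed)
    vals = np.array([raw[f"OTU_{i+1}"] for i in range(spec.n_otus)])
    sd = vals.std()
    mu = (vals - vals.mean()) / sd if sd > 0 else vals * 0.0
    optima = {f"OTU_{i+1}": float(mu[i]) for i in range(spec.n_otus)}

    env = spec.env_gradient
    if env is None:
        env = np.linspace(-2.0, 2.0, spec.n_samples)
    env = np.asarray(env, dtype=float)

    if spec.selection_strength == 0:
        weights = None  # identical draws to the neutral generator
    else:
        mism = (env[:, None] - mu[None, :]) ** 2
        weights = np.exp(-spec.selection_strength * mism / (2.0 * spec.niche_breadth**2))
    table = _sample_table(spec, p, weights)
    return table, optima


# ---------------------------------------------------------------------------
# Metadata simulation
# ---------------------------------------------------------------------------

def simulate_metadata(
    n_samples: int,
    pollution_profile: str = "decreasing_with_distance",
    seed: int = 0,
    backgrounds: dict[str, float] | None = None,
    noise_sigma: float = 0.25,
) -> list[SampleMetadata]:
    """Simulate site metadata along a 0-40 km urban-rural transect.

    Distances are sorted uniform draws on [0, 40]; categories are assigned
    by distance quartile (nearest quarter = urban ... farthest = rural).
    Metal concentrations are ``background * (1 + gradient + lognormal
    noise)`` where the gradient term decays (or grows) with distance per
    ``pollution_profile``; soil variables get mild distance correlations.
    """
    if n_samples < 4:
        raise SimSpecError("n_samples must be >= 4")
    if pollution_profile not in ("increasing_with_distance", "decreasing_with_distance"):
        raise SimSpecError(f"unknown pollution profile {pollution_profile!r}")
    bg = dict(DEFAULT_BACKGROUNDS if backgrounds is None else backgrounds)
    rng = np.random.default_rng([seed, 3])
    dist = np.sort(rng.uniform(0.0, 40.0, size=n_samples))
    quart = np.searchsorted(np.quantile(dist, [0.25, 0.5, 0.75]), dist, side="left")
    records = []
    for j in range(n_samples):
        d = float(dist[j])
        if pollution_profile == "decreasing_with_distance":
            grad = 2.0 * math.exp(-d / 15.0)
        else:
            grad = 2.0 * d / 40.0
        metals = {}
        for m in METALS:
            noise = rng.lognormal(mean=0.0, sigma=noise_sigma)
            metals[m] = bg[m] * (1.0 + grad) * noise
        soil = {
            "SOM": max(0.5, 20.0 + 0.1 * d + rng.normal(0, 2.0)),
            "AP": max(0.5, 15.0 + 0.15 * d + rng.normal(0, 3.0)),
            "SMC": min(0.6, max(0.02, 0.15 + 0.001 * d + rng.normal(0, 0.03))),
            "AK": max(5.0, 120.0 + 0.5 * d + rng.normal(0, 15.0)),
            "pH": min(9.5, max(4.5, 7.8 + 0.005 * d + rng.normal(0, 0.2))),
            "TN": max(0.05, 1.2 + 0.005 * d + rng.normal(0, 0.15)),
        }
        records.append(
            SampleMetadata(f"S{j+1:02d}", CATEGORIES[quart[j]], d, soil, metals)
        )
    return records


# ---------------------------------------------------------------------------
# Planted generalists / specialists
# ---------------------------------------------------------------------------

def plant_generalists_specialists(
    table: OtuTable,
    n_generalists: int,
    n_specialists: int,
    seed: int,
) -> tuple[OtuTable, dict[str, str]]:
    """Overwrite OTU columns with textbook generalists and specialists.

    Planted generalists get exactly equal counts in every sample (Levins'
    breadth = n_samples); planted specialists get their whole total in a
    single sample (breadth = 1).  Planted totals are set near the median
    positive OTU total so the plants are not give-aways by abundance
    alone.  Returns the modified table and ground-truth labels.

    Note that a *randomly placed* near-uniform OTU (multinomial over
    samples) is indistinguishable from the margin-preserving null by
    construction; detectable generalists must be spread more evenly than
    random placement, which the deterministic uniform plant provides.
    """
    if n_generalists + n_specialists > table.n_otus:
        raise SimSpecError("more planted OTUs requested than columns available")
    rng = np.random.default_rng([seed, 4])
    counts = table.counts.copy()
    totals = counts.sum(axis=0)
    median_total = float(np.median(totals[totals > 0])) if np.any(totals > 0) else float(table.n_samples)
    chosen = rng.choice(table.n_otus, size=n_generalists + n_specialists, replace=False)
    labels: dict[str, str] = {}
    per_sample = max(1, int(round(median_total / table.n_samples)))
    for idx in chosen[:n_generalists]:
        counts[:, idx] = per_sample
        labels[table.otu_ids[idx]] = "generalist"
    for idx in chosen[n_generalists:]:
        counts[:, idx] = 0.0
        home = rng.integers(table.n_samples)
        counts[home, idx] = max(1, int(round(median_total)))
        labels[table.otu_ids[idx]] = "specialist"
    return OtuTable(list(table.sample_ids), list(table.otu_ids), counts), labels
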