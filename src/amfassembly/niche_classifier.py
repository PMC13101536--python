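"""Levins' niche breadth and generalist/specialist classification.

For one OTU with per-sample relative use P_j = a_j / sum(a), Levins' niche
breadth is B = 1 / sum_j P_j^2, ranging from 1 (all abundance in one
sample, an extreme habitat specialist) to n_samples (perfectly even use of
every sample, an extreme generalist).

Classification compares each OTU's observed breadth with a permutation
null distribution of breadths: OTUs above the null's 97.5% quantile are
generalists, below the 2.5% quantile specialists, the rest neutral (at the
default two-sided alpha of 0.05 and 1000 permutations).

Null models
-----------
``margins`` (default): each permutation draws a whole random table with the
observed row (sample) and column (OTU) totals via Patefield's algorithm,
then recomputes every OTU's breadth.  This is the matrix-level
randomisation family behind the established generalist/specialist
permutation test: an OTU's total abundance is preserved but its placement
across samples is randomised conditional on sample depths.

``per_otu_shuffle``: permutes each OTU's abundance values across samples
independently.  Levins' B depends only on the multiset of values, not
their positions, so this null is *degenerate* for B (null breadth equals
observed breadth for every OTU and every label comes out neutral).  It is
provided for completeness and as the building block for occupancy-based
statistics; do not use it to classify by breadth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community_io import ConfigError, OtuTable

LABELS = ("generalist", "specialist", "neutral")


@dataclass
class NicheClassification:
    otu_id: str
    breadth: float
    null_lower: float
    null_upper: float
    label: str


def levins_breadth(abundances: np.ndarray | list[float]) -> float:
    """B = 1 / sum(P_j^2) with P_j the OTU's share of its total in sample j."""
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("breadth undefined for an all-zero abundance vector")
    p = a / total
    return float(1.0 / np.sum(p * p))


def _breadths_matrix(counts: np.ndarray) -> np.ndarray:
    """Levins' breadth of every column of a samples x OTUs matrix."""
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("breadth undefined for all-zero OTU column")
    return totals**2 / np.sum(counts**2, axis=0)


def classify_otus(
    table: OtuTable,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    null_model: str = "margins",
) -> list[NicheClassification]:
    """Classify every OTU as generalist / specialist / neutral.

    Empirical (alpha/2, 1-alpha/2) quantiles of the per-OTU null breadths
    (linear/type-7 interpolation) form the bounds; labels use strict
    inequalities, so a breadth exactly on a bound is neutral.  The
    ``margins`` null requires (near-)integer counts.
    """
    if table.n_samples < 3:
        raise ConfigError("classification needs at least 3 samples")
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100 (quantiles unstable below that)")
    if not (0 < alpha < 1):
        raise ConfigError("alpha must be in (0, 1)")
    if null_model not in ("margins", "per_otu_shuffle"):
        raise ConfigError(f"unknown null model {null_model!r}")

    counts = table.counts
    observed = _breadths_matrix(counts)
    rng = np.random.default_rng(seed)
    null_b = np.empty((n_perm, table.n_otus))

    if null_model == "margins":
        ints = np.round(counts)
        if not np.allclose(counts, ints, atol=1e-6):
            raise ConfigError("the 'margins' null model requires integer counts")
        row_tot = ints.sum(axis=1).astype(np.int64)
        col_tot = ints.sum(axis=0).astype(np.int64)
        sampler = stats.random_table(row_tot, col_tot)
        for k in range(n_perm):
            r = sampler.rvs(method="patefield", random_state=rng)
            null_b[k] = _breadths_matrix(np.asarray(r, dtype=float))
    else:  # per_otu_shuffle — see module docstring: degenerate for B
        for k in range(n_perm):
            shuffled = counts.copy()
            for i in range(table.n_otus):
                rng.shuffle(shuffled[:, i])
            null_b[k] = _breadths_matrix(shuffled)

    lower = np.quantile(null_b, alpha / 2.0, axis=0, method="linear")
    upper = np.quantile(null_b, 1.0 - alpha / 2.0, axis=0, method="linear")

    out = []
    for i, otu in enumerate(table.otu_ids):
        b = float(observed[i])
        if b > upper[i]:
            label = "generalist"
        elif b < lower[i]:
            label = "specialist"
        else:
            label = "neutral"
        out.append(NicheClassification(otu, b, float(lower[i]), float(upper[i]), label))
    return out


def classification_frame(results: list[NicheClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"otu_id": r.otu_id, "breadth": r.breadth, "null_lower": r.null_lower,
             "null_upper": r.null_upper, "label": r.label}
            for r in results
        ]
    ).set_index("otu_id")


def labels_dict(results: list[NicheClassification]) -> dict[str, str]:
    return {r.otu_id: r.label for r in results}
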