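"""Diversity, dissimilarity, Mantel, Spearman, regression and Venn layers.

Everything here is the standard statistical toolkit that links the
assembly inference to the pollution gradient: alpha diversity (richness,
Shannon with natural log), Bray-Curtis dissimilarity, the Mantel
permutation test between distance matrices, Spearman rank correlation
batches, the ordinary least-squares regression of βNTI on the Nemerow
index, and shared/unique OTU partitions across habitat categories.

NMDS is delegated: the pipeline emits the Bray-Curtis matrix and accepts
externally computed ordination coordinates; :func:`check_ordination` is
the only contract enforced (one coordinate row per sample).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .community_io import CATEGORIES, ConfigError, OtuTable, SampleMetadata
from .phylo_turnover import BntiResult
from .pollution_index import PollutionResult


@dataclass
class DiversityProfile:
    sample_id: str
    richness: int
    shannon: float


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    tail: str


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def significance_stars(p: float) -> str:
    """Conventional significance stars: *** <0.001, ** <0.01, * <0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Alpha diversity & Bray-Curtis
# ---------------------------------------------------------------------------

def alpha_diversity(table: OtuTable) -> list[DiversityProfile]:
    """Richness (observed OTUs) and Shannon H (natural log) per sample."""
    out = []
    for j, sid in enumerate(table.sample_ids):
        row = table.counts[j]
        nz = row[row > 0]
        h = float(stats.entropy(nz)) if nz.size else 0.0
        out.append(DiversityProfile(sid, int(nz.size), h))
    return out


def diversity_frame(profiles: list[DiversityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": d.sample_id, "richness": d.richness, "shannon": d.shannon}
         for d in profiles]
    ).set_index("sample_id")


def bray_curtis(table: OtuTable) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity on relative abundances, in [0,1]."""
    return squareform(pdist(table.relative_abundances(), metric="braycurtis"))


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Permutation test for correlation between two distance matrices.

    r is the Pearson correlation of the upper triangles; the null permutes
    rows and columns of d2 simultaneously.  The p-value carries the +1
    correction, p = (1 + #{null >= observed}) / (1 + n_perm), so it can
    never be exactly 0.
    """
    if tail not in ("greater", "two_sided"):
        raise ConfigError(f"unknown tail {tail!r}")
    d1 = _check_distance_matrix(d1, "d1")
    d2 = _check_distance_matrix(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must share a sample set")
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d1[iu]
    if x.std() == 0 or d2[iu].std() == 0:
        raise ValueError("constant upper triangle: Mantel r undefined")

    xc = x - x.mean()
    xnorm = np.sqrt(np.sum(xc * xc))

    def corr(mat: np.ndarray) -> float:
        y = mat[iu]
        yc = y - y.mean()
        denom = xnorm * np.sqrt(np.sum(yc * yc))
        return float(np.sum(xc * yc) / denom) if denom > 0 else float("nan")

    r_obs = corr(d2)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_null = corr(d2[np.ix_(perm, perm)])
        if tail == "greater":
            hits += r_null >= r_obs
        else:
            hits += abs(r_null) >= abs(r_obs)
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r_obs, float(p), n_perm, tail)


# ---------------------------------------------------------------------------
# Spearman batches
# ---------------------------------------------------------------------------

def spearman_matrix(x: pd.DataFrame, y: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and p for every (x-column, y-column) pair.

    Average ranks for ties; p from the t approximation.  Constant columns
    yield NaN entries rather than failing the batch.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have the same number of rows")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    rho = pd.DataFrame(index=x.columns, columns=y.columns, dtype=float)
    pval = pd.DataFrame(index=x.columns, columns=y.columns, dtype=float)
    for cx in x.columns:
        for cy in y.columns:
            a, b = x[cx].to_numpy(float), y[cy].to_numpy(float)
            if np.std(a) == 0 or np.std(b) == 0:
                rho.loc[cx, cy] = np.nan
                pval.loc[cx, cy] = np.nan
                continue
            res = stats.spearmanr(a, b)
            rho.loc[cx, cy] = res.statistic
            pval.loc[cx, cy] = res.pvalue
    return rho, pval


# ---------------------------------------------------------------------------
# βNTI ~ pollution regression
# ---------------------------------------------------------------------------

def bnti_vs_pollution(
    bnti: list[BntiResult],
    pollution: list[PollutionResult],
    pairing: str = "pair_mean",
) -> RegressionResult:
    """OLS of pairwise βNTI on a pairwise summary of the per-sample Pn.

    ``pairing`` maps the two samples' Nemerow indices to one predictor:
    ``pair_mean`` (default) or ``pair_abs_difference``.  Degenerate βNTI
    pairs are excluded.
    """
    if pairing not in ("pair_mean", "pair_abs_difference"):
        raise ConfigError(f"unknown pairing {pairing!r}")
    pn = {p.sample_id: p.pn for p in pollution}
    xs, ys = [], []
    for r in bnti:
        if r.degenerate or not np.isfinite(r.bnti):
            continue
        if r.sample_a not in pn or r.sample_b not in pn:
            raise ValueError(f"no pollution record for pair ({r.sample_a}, {r.sample_b})")
        a, b = pn[r.sample_a], pn[r.sample_b]
        xs.append((a + b) / 2.0 if pairing == "pair_mean" else abs(a - b))
        ys.append(r.bnti)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 usable pairs, got {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.std() == 0:
        raise ValueError("constant predictor: slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue**2), float(fit.pvalue), len(x))


# ---------------------------------------------------------------------------
# Shared/unique OTU partition (Venn regions)
# ---------------------------------------------------------------------------

def shared_otu_partition(
    table: OtuTable, records: list[SampleMetadata]
) -> dict:
    """Counts for every non-empty intersection region of the category sets.

    An OTU belongs to a category if it has a positive count in at least one
    of its samples.  Region keys are '&'-joined category names in canonical
    order; the regions partition the observed OTUs (disjoint, exhaustive).
    Also reports the fraction of OTUs shared by all non-empty categories.
    """
    by_id = {r.sample_id: r for r in records}
    missing = [s for s in table.sample_ids if s not in by_id]
    if missing:
        raise ValueError(f"uncategorised sample(s), e.g. {missing[:3]}")
    cats_present = [c for c in CATEGORIES
                    if any(by_id[s].category == c for s in table.sample_ids)]
    if len(cats_present) < len(CATEGORIES):
        import logging
        logging.getLogger("amfassembly").warning(
            "empty categor(ies): %s; regions computed over the rest",
            sorted(set(CATEGORIES) - set(cats_present)),
        )
    masks = {
        c: np.array([by_id[s].category == c for s in table.sample_ids])
        for c in cats_present
    }
    presence = {c: (table.counts[masks[c]] > 0).any(axis=0) for c in cats_present}
    regions: dict[str, int] = {}
    observed = np.zeros(table.n_otus, dtype=bool)
    for c in cats_present:
        observed |= presence[c]
    for i in range(table.n_otus):
        if not observed[i]:
            continue
        member = tuple(c for c in cats_present if presence[c][i])
        key = "&".join(member)
        regions[key] = regions.get(key, 0) + 1
    all_key = "&".join(cats_present)
    n_obs = int(observed.sum())
    shared_all = regions.get(all_key, 0)
    return {
        "regions": regions,
        "n_otus_observed": n_obs,
        "shared_by_all": shared_all,
        "shared_by_all_fraction": shared_all / n_obs if n_obs else float("nan"),
        "categories": list(cats_present),
    }


# ---------------------------------------------------------------------------
# Ordination contract
# ---------------------------------------------------------------------------

def check_ordination(coords: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Validate externally computed ordination coordinates (e.g. NMDS):
    one row per sample, reordered to the table's sample order."""
    missing = [s for s in sample_ids if s not in coords.index]
    if missing:
        raise ValueError(f"ordination missing sample(s), e.g. {missing[:3]}")
    return coords.loc[sample_ids]
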