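"""Sloan neutral community model: fit, goodness of fit, neutral partition.

The model predicts the occurrence frequency of a taxon across local
communities from its mean relative abundance p in the metacommunity.  With
community size N (here: mean reads per sample), migration rate m and a
detection limit dbar (detection threshold in relative-abundance units),
the predicted frequency is the upper tail of the stationary Beta
distribution:

    F(p) = 1 - I_dbar(N*m*p, N*m*(1-p))

where I is the regularised incomplete beta function.  A single free
parameter Nm is fitted by nonlinear least squares of observed frequencies
on F(p); m = Nm / N.  R^2 = 1 - SSE/SST measures fit quality (it may be
negative and is reported as such).  95% bands around the prediction are
Wilson score intervals on F(p) * n_samples successes out of n_samples;
OTUs above / within / below the bands are classified above / neutral /
below, and the neutral fraction is the share of OTUs inside the bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.proportion import proportion_confint

from .community_io import OtuTable

_LOG_NM_LO, _LOG_NM_HI = np.log(0.1), np.log(1e6)


class FitError(RuntimeError):
    """The NCM optimiser failed to converge."""


@dataclass
class NcmFit:
    nm: float                 # fitted N*m
    m: float                  # migration rate, nm / n_reads
    n_reads: float            # mean reads per sample (community size N)
    r_squared: float
    d_reads: int              # detection limit in reads
    dbar: float               # detection limit as relative abundance
    n_samples: int
    per_otu: pd.DataFrame     # otu_id, p, observed_freq, predicted_freq,
                              # lower95, upper95, partition
    neutral_fraction: float

    def summary(self) -> dict:
        return {
            "Nm": self.nm, "m": self.m, "N": self.n_reads,
            "r_squared": self.r_squared, "d_reads": self.d_reads,
            "n_otus": int(len(self.per_otu)),
            "neutral_fraction": self.neutral_fraction,
        }


def occurrence_frequency(table: OtuTable, d_reads: int = 1) -> pd.DataFrame:
    """Per-OTU mean relative abundance p and occurrence frequency.

    p averages count/sample-total over samples; frequency is the share of
    samples where the OTU has at least ``d_reads`` reads.  OTUs never
    detected (frequency 0) are dropped.
    """
    if d_reads < 1:
        raise ValueError("detection limit must be >= 1 read")
    rel = table.relative_abundances()
    p = rel.mean(axis=0)
    freq = (table.counts >= d_reads).mean(axis=0)
    df = pd.DataFrame({"otu_id": table.otu_ids, "p": p, "observed_freq": freq})
    return df[df.observed_freq > 0].reset_index(drop=True)


def predicted_frequency(p, nm: float, dbar: float):
    """F(p) = 1 - I_dbar(Nm*p, Nm*(1-p)); accepts scalars or arrays."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly inside (0, 1)")
    if nm <= 0:
        raise ValueError("Nm must be > 0")
    if not (0 < dbar < 1):
        raise ValueError("dbar must lie strictly inside (0, 1)")
    out = 1.0 - special.betainc(nm * p, nm * (1.0 - p), dbar)
    return float(out) if out.ndim == 0 else out


def fit_frequency_curve(
    p: np.ndarray,
    freq: np.ndarray,
    dbar: float,
    xatol: float = 1e-8,
    n_starts: int = 5,
) -> tuple[float, float]:
    """Least-squares fit of Nm on (p, frequency) pairs.

    Bounded scalar minimisation on log(Nm) in [log 0.1, log 1e6], with the
    range split into ``n_starts`` brackets to dodge local minima; returns
    (Nm, R^2).  R^2 may be negative (fit worse than the mean) and is not
    clamped.
    """
    p = np.asarray(p, dtype=float)
    freq = np.asarray(freq, dtype=float)
    if p.shape != freq.shape or p.ndim != 1:
        raise ValueError("p and freq must be matching 1-D arrays")

    sst = float(np.sum((freq - freq.mean()) ** 2))
    if sst == 0:
        # e.g. every OTU observed in every sample: nothing identifies Nm
        raise FitError("occurrence frequencies have no variation; Nm unidentifiable")

    def sse(log_nm: float) -> float:
        pred = predicted_frequency(p, float(np.exp(log_nm)), dbar)
        return float(np.sum((freq - pred) ** 2))

    edges = np.linspace(_LOG_NM_LO, _LOG_NM_HI, n_starts + 1)
    best = None
    for lo, hi in zip(edges[:-1], edges[1:]):
        res = optimize.minimize_scalar(
            sse, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
        )
        if not res.success:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError("bounded scalar minimisation failed in every bracket")
    nm = float(np.exp(best.x))
    return nm, 1.0 - best.fun / sst


def fit_ncm(table: OtuTable, d_reads: int = 1) -> NcmFit:
    """Fit the neutral model to a table and partition its OTUs."""
    df = occurrence_frequency(table, d_reads)
    if len(df) < 10:
        raise ValueError(f"need >= 10 detected OTUs to fit, got {len(df)}")
    n_reads = float(table.sample_totals().mean())
    dbar = d_reads / n_reads
    nm, r2 = fit_frequency_curve(df.p.to_numpy(), df.observed_freq.to_numpy(), dbar)

    n = table.n_samples
    pred = predicted_frequency(df.p.to_numpy(), nm, dbar)
    lower, upper = proportion_confint(pred * n, n, alpha=0.05, method="wilson")
    partition = np.where(
        df.observed_freq.to_numpy() > upper, "above",
        np.where(df.observed_freq.to_numpy() < lower, "below", "neutral"),
    )
    per_otu = df.assign(predicted_freq=pred, lower95=lower, upper95=upper,
                        partition=partition)
    neutral_fraction = float((partition == "neutral").mean())
    return NcmFit(nm, nm / n_reads, n_reads, r2, d_reads, dbar, n,
                  per_otu, neutral_fraction)


def compare_group_fits(fits: dict[str, NcmFit]) -> pd.DataFrame:
    """Side-by-side (group, m, R^2, neutral fraction) sorted by m, descending."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    rows = [
        {"group": g, "m": f.m, "Nm": f.nm, "r_squared": f.r_squared,
         "neutral_fraction": f.neutral_fraction, "n_otus": len(f.per_otu)}
        for g, f in fits.items()
    ]
    return (
        pd.DataFrame(rows)
        .sort_values("m", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
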