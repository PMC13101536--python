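"""Single-factor and Nemerow composite pollution indices.

The single-factor index of element *i* is P_i = C_i / S_i, the measured
concentration over the regional background value.  The Nemerow composite
index aggregates the per-element indices of a sample as

    Pn = sqrt( (mean(P)^2 + max(P)^2) / 2 )

which emphasises the most severely polluting element while retaining the
average.  Pn strictly greater than 1 flags the sample as contaminated.
Background values are a required input — they are regional reference data,
never constants of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community_io import METALS, SampleMetadata


@dataclass
class PollutionResult:
    sample_id: str
    single_factor: dict[str, float]
    pn: float
    polluted: bool


def single_factor_index(concentration: float, background: float) -> float:
    """P_i = C_i / S_i; requires S_i > 0 and C_i >= 0."""
    if background <= 0:
        raise ValueError(f"background value must be > 0, got {background}")
    if concentration < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration}")
    return concentration / background


def nemerow_index(single_factor: np.ndarray | list[float]) -> float:
    """Pn = sqrt((mean(P)^2 + max(P)^2) / 2) over per-element indices."""
    p = np.asarray(single_factor, dtype=float)
    if p.size == 0:
        raise ValueError("nemerow_index requires at least one single-factor index")
    if np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ValueError("single-factor indices must be finite and >= 0")
    return float(np.sqrt((p.mean() ** 2 + p.max() ** 2) / 2.0))


def classify_pollution(pn: float) -> bool:
    """True iff Pn strictly exceeds 1 (a value of exactly 1 is clean)."""
    if pn < 0:
        raise ValueError("Pn must be >= 0")
    return pn > 1.0


def compute_pollution(
    records: list[SampleMetadata],
    backgrounds: dict[str, float],
    elements: tuple[str, ...] = METALS,
) -> list[PollutionResult]:
    """Per-sample pollution indices over the requested elements."""
    missing_bg = [e for e in elements if e not in backgrounds]
    if missing_bg:
        raise ValueError(f"missing background value(s) for: {missing_bg}")
    results = []
    for rec in records:
        missing = [e for e in elements if e not in rec.metals]
        if missing:
            raise ValueError(
                f"sample {rec.sample_id} missing metal concentration(s): {missing}"
            )
        pi = {e: single_factor_index(rec.metals[e], backgrounds[e]) for e in elements}
        pn = nemerow_index(list(pi.values()))
        results.append(PollutionResult(rec.sample_id, pi, pn, classify_pollution(pn)))
    return results


def pollution_frame(results: list[PollutionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id}
        row.update({f"P_{e}": v for e, v in r.single_factor.items()})
        row["Pn"] = r.pn
        row["polluted"] = r.polluted
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")
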