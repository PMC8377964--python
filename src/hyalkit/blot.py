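"""HC-HA immunoblot quantification.

HC-HA complex (heavy chains covalently bound to hyaluronan) cannot enter an
SDS-PAGE gel, so each sample is run twice: an undigested lane ("-") showing
only endogenous free heavy chain, and a hyaluronidase-digested lane ("+")
where HA-bound heavy chain has been released.  Band densities are
normalized per lane to the Pre-I-alpha-I band, and the HC-HA relative
absorbance unit is

    a.u. = HC(+)/PreIaI(+) - HC(-)/PreIaI(-).

Negative values can arise from digestion/loading noise and are retained
(flagged, not clamped); group summaries use medians, which are robust to
this choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["BlotLanePair", "NormalizationError", "hcha_au", "batch_hcha"]


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class BlotLanePair:
    """Band densities (a.u.) for one sample's paired immunoblot lanes."""

    sample_id: str
    hc_minus: float
    preiai_minus: float
    hc_plus: float
    preiai_plus: float

    def __post_init__(self) -> None:
        for name in ("hc_minus", "preiai_minus", "hc_plus", "preiai_plus"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


def hcha_au(pair: BlotLanePair) -> float:
    """HC-HA relative absorbance: per-lane Pre-IaI-normalized HC difference."""
    if pair.preiai_plus <= 0:
        raise NormalizationError(
            f"sample {pair.sample_id}: non-positive Pre-IaI density in digested lane '+'"
        )
    if pair.preiai_minus <= 0:
        raise NormalizationError(
            f"sample {pair.sample_id}: non-positive Pre-IaI density in undigested lane '-'"
        )
    return pair.hc_plus / pair.preiai_plus - pair.hc_minus / pair.preiai_minus


def batch_hcha(table: pd.DataFrame, group_col: Optional[str] = "group") -> pd.DataFrame:
    """Vectorized HC-HA quantification over a table of lane pairs.

    ``table`` needs columns sample_id, hc_minus, preiai_minus, hc_plus,
    preiai_plus (and optionally ``group_col``).  Rows with a non-positive
    Pre-IaI density are flagged and get NaN rather than aborting the batch;
    negative a.u. values are flagged but kept.  The result carries group
    medians and IQRs as ``DataFrame.attrs["group_summary"]`` when a group
    column is present.
    """
    out = table.copy()
    aus = np.full(len(table), np.nan)
    flags = [""] * len(table)
    for i, row in enumerate(table.itertuples(index=False)):
        try:
            pair = BlotLanePair(
                str(row.sample_id),
                float(row.hc_minus),
                float(row.preiai_minus),
                float(row.hc_plus),
                float(row.preiai_plus),
            )
            aus[i] = hcha_au(pair)
            if aus[i] < 0:
                flags[i] = "negative"
        except (NormalizationError, ValueError) as exc:
            flags[i] = f"error: {exc}"
    out["hcha_au"] = aus
    out["flag"] = flags
    if group_col is not None and group_col in out.columns:
        summary = {}
        for grp, sub in out.groupby(group_col):
            vals = sub["hcha_au"].dropna()
            q1, med, q3 = vals.quantile([0.25, 0.5, 0.75])
            summary[grp] = {"median": float(med), "iqr": float(q3 - q1), "n": int(len(vals))}
        out.attrs["group_summary"] = summary
    return out
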