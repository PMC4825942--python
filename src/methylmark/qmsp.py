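"""Percent methylation at a single CpG locus from qMSP Ct triplets.

Quantitative methylation-specific PCR runs three parallel reactions per
bisulfite-converted sample: one with a methylation-specific primer, one with
an unmethylation-specific primer, and one internal control that amplifies
regardless of methylation state.  Each reaction is normalized to the internal
control on the threshold-cycle (Ct) scale and the two normalized signals are
combined into a percent methylation::

    dCt_meth   = Ct_meth   - Ct_internal
    dCt_unmeth = Ct_unmeth - Ct_internal
    % methylation = 100 / (1 + 2**(dCt_meth - dCt_unmeth))

With perfect doubling per cycle, 2**(-dCt) is proportional to the template
amount, so the expression is the methylated fraction of total template,
scaled to percent.  The estimate lives in the open interval (0, 100): a Ct
difference can make one allele arbitrarily rare but never literally absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QmspTriplet",
    "MethylationEstimate",
    "percent_methylation",
    "batch_percent_methylation",
]


@dataclass(frozen=True)
class QmspTriplet:
    """One replicate of the three qMSP reactions for one sample."""

    sample_id: str
    ct_meth: float
    ct_unmeth: float
    ct_internal: float
    replicate: int = 0

    def __post_init__(self) -> None:
        for name in ("ct_meth", "ct_unmeth", "ct_internal"):
            v = getattr(self, name)
            if not math.isnan(v) and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")


@dataclass(frozen=True)
class MethylationEstimate:
    """Percent methylation with the normalized Ct differences behind it."""

    sample_id: str
    percent_methylation: float
    delta_ct_meth: float
    delta_ct_unmeth: float


def percent_methylation(
    triplet: QmspTriplet | tuple[float, float, float],
    sample_id: str = "sample",
) -> MethylationEstimate:
    """Compute percent methylation from one Ct triplet.

    Accepts a :class:`QmspTriplet` or a plain ``(ct_meth, ct_unmeth,
    ct_internal)`` tuple.  Non-finite Cts (undetermined reactions) raise;
    use :func:`batch_percent_methylation` to propagate them as missing.
    """
    if isinstance(triplet, QmspTriplet):
        ct_m, ct_u, ct_i = triplet.ct_meth, triplet.ct_unmeth, triplet.ct_internal
        sample_id = triplet.sample_id
    else:
        ct_m, ct_u, ct_i = triplet
    for name, v in (("ct_meth", ct_m), ("ct_unmeth", ct_u), ("ct_internal", ct_i)):
        if not math.isfinite(v):
            raise ValueError(f"non-finite {name} for sample {sample_id!r}: {v}")
    d_meth = ct_m - ct_i
    d_unmeth = ct_u - ct_i
    pct = 100.0 / (1.0 + 2.0 ** (d_meth - d_unmeth))
    return MethylationEstimate(sample_id, pct, d_meth, d_unmeth)


_CHANNELS = ("ct_meth", "ct_unmeth", "ct_internal")


def batch_percent_methylation(triplets: pd.DataFrame) -> pd.DataFrame:
    """Per-sample percent methylation from a replicate Ct table.

    Parameters
    ----------
    triplets
        Columns ``sample_id, ct_meth, ct_unmeth, ct_internal`` (a
        ``replicate`` column is allowed and ignored for grouping).

    Replicate Cts are averaged per sample on the Ct scale — where the noise
    is approximately additive — before the nonlinear percent transform is
    applied once per sample.  A sample whose channel is entirely NaN
    (undetermined reactions) yields a missing estimate rather than 0% or
    100%; a structurally absent channel column is an error.

    Returns
    -------
    DataFrame with columns ``sample_id, percent_methylation, delta_ct_meth,
    delta_ct_unmeth``, one row per sample in first-appearance order.
    """
    missing_cols = [c for c in ("sample_id", *_CHANNELS) if c not in triplets.columns]
    if missing_cols:
        raise ValueError(f"triplet table missing columns: {missing_cols}")
    if triplets.empty:
        raise ValueError("empty triplet table")

    rows = []
    for sample_id, grp in triplets.groupby("sample_id", sort=False):
        means = {}
        for ch in _CHANNELS:
            vals = grp[ch].to_numpy(dtype=float)
            if vals.size == 0 or np.all(np.isnan(vals)):
                means[ch] = np.nan
            else:
                means[ch] = float(np.nanmean(vals))
        d_meth = means["ct_meth"] - means["ct_internal"]
        d_unmeth = means["ct_unmeth"] - means["ct_internal"]
        if np.isnan(d_meth) or np.isnan(d_unmeth):
            pct = np.nan
        else:
            pct = 100.0 / (1.0 + 2.0 ** (d_meth - d_unmeth))
        rows.append(
            {
                "sample_id": sample_id,
                "percent_methylation": pct,
                "delta_ct_meth": d_meth,
                "delta_ct_unmeth": d_unmeth,
            }
        )
    return pd.DataFrame(rows)
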