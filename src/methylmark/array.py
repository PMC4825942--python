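"""Methylation-array beta values, detection filtering, and the delta-beta screen.

Each probe of a two-channel methylation array reports a methylated (M) and an
unmethylated (U) signal intensity plus a background level estimated from
negative controls.  The methylation fraction is the background-corrected
ratio::

    beta = max(M - bg, 0) / (max(M - bg, 0) + max(U - bg, 0))

(plain ratio, no denominator offset).  Probes whose detection p-value exceeds
a threshold in any record are excluded wholesale, and differential
methylation between two groups is called from the difference of group-mean
beta values against a fixed |delta beta| threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ArrayProbe",
    "DifferentialCall",
    "beta_value",
    "compute_betas",
    "detection_filter",
    "differential_screen",
]

logger = logging.getLogger(__name__)

DELTA_BETA_THRESHOLD = 0.06
DETECTION_ALPHA = 0.05

PROBE_COLUMNS = (
    "probe_id",
    "group",
    "replicate",
    "signal_meth",
    "signal_unmeth",
    "background",
    "detection_p",
)


@dataclass(frozen=True)
class ArrayProbe:
    probe_id: str
    group: str
    replicate: int
    signal_meth: float
    signal_unmeth: float
    background: float
    detection_p: float

    def __post_init__(self) -> None:
        if min(self.signal_meth, self.signal_unmeth, self.background) < 0:
            raise ValueError(f"negative intensity for probe {self.probe_id!r}")
        if not 0.0 <= self.detection_p <= 1.0:
            raise ValueError(f"detection_p outside [0,1] for probe {self.probe_id!r}")


@dataclass(frozen=True)
class DifferentialCall:
    probe_id: str
    mean_beta_a: float
    mean_beta_b: float
    delta_beta: float
    call: str  # hyper | hypo | unchanged


def beta_value(signal_meth, signal_unmeth, background=0.0, offset: float = 0.0):
    """Background-corrected methylation fraction, vectorized.

    ``offset`` is an optional stabilizing constant added to the denominator
    (Illumina convention uses 100); the default 0 gives the plain ratio.
    Returns NaN where both corrected channels are zero (dead probe) — never
    0, which would fabricate hypomethylation.
    """
    m = np.asarray(signal_meth, dtype=float)
    u = np.asarray(signal_unmeth, dtype=float)
    bg = np.asarray(background, dtype=float)
    if np.any(m < 0) or np.any(u < 0) or np.any(bg < 0):
        raise ValueError("raw intensities and background must be non-negative")
    mc = np.maximum(m - bg, 0.0)
    uc = np.maximum(u - bg, 0.0)
    denom = mc + uc + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, mc / np.where(denom > 0, denom, 1.0), np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def compute_betas(probes: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Return a copy of the probe table with a ``beta`` column appended."""
    out = probes.copy()
    out["beta"] = beta_value(
        probes["signal_meth"], probes["signal_unmeth"], probes["background"], offset
    )
    return out


def detection_filter(
    probes: pd.DataFrame, alpha: float = DETECTION_ALPHA
) -> tuple[pd.DataFrame, list]:
    """Split the probe table into (retained, excluded probe ids).

    A probe is excluded iff its detection p-value is strictly greater than
    ``alpha`` in *any* record (any group or replicate); exclusion is
    probe-wise, mirroring array QC where an undetected target is dropped
    from every sample.  Retained rows plus excluded ids partition the input.
    """
    if "detection_p" not in probes.columns:
        raise ValueError("probe table missing column 'detection_p'")
    if probes["detection_p"].isna().any():
        raise ValueError("detection_p must be present for all probes")
    failing = probes.loc[probes["detection_p"] > alpha, "probe_id"].unique()
    failing_set = set(failing)
    retained = probes.loc[~probes["probe_id"].isin(failing_set)].copy()
    return retained, sorted(failing_set)


def differential_screen(
    retained: pd.DataFrame,
    group_a: str,
    group_b: str,
    threshold: float = DELTA_BETA_THRESHOLD,
) -> pd.DataFrame:
    """Delta-beta differential methylation calls between two groups.

    For each probe, ``delta_beta = mean beta(group_b) - mean beta(group_a)``
    over non-missing replicate betas.  Calls use strict thresholds:
    ``hyper`` if delta > threshold, ``hypo`` if delta < -threshold, else
    ``unchanged``.  Probes with no informative beta in one of the two groups
    are dropped from the output (the count is logged).

    Input must carry a ``beta`` column (see :func:`compute_betas`).
    """
    if "beta" not in retained.columns:
        raise ValueError("run compute_betas first: no 'beta' column")
    for g in (group_a, group_b):
        if g not in set(retained["group"]):
            raise ValueError(f"group {g!r} absent from probe table")

    sub = retained[retained["group"].isin([group_a, group_b])]
    means = (
        sub.pivot_table(index="probe_id", columns="group", values="beta", aggfunc="mean")
        .reindex(columns=[group_a, group_b])
    )
    informative = means.dropna()
    n_dropped = len(means) - len(informative)
    if n_dropped:
        logger.info("differential_screen: dropped %d probes missing in one group", n_dropped)

    delta = informative[group_b] - informative[group_a]
    call = np.where(delta > threshold, "hyper", np.where(delta < -threshold, "hypo", "unchanged"))
    out = pd.DataFrame(
        {
            "probe_id": informative.index,
            "mean_beta_a": informative[group_a].to_numpy(),
            "mean_beta_b": informative[group_b].to_numpy(),
            "delta_beta": delta.to_numpy(),
            "call": call,
        }
    ).reset_index(drop=True)
    return out
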