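"""Relative expression from qPCR Ct tables by the comparative ddCt method.

A target gene is normalized to a reference gene (here GAPDH-style internal
control) within each condition, and the normalized signals of two conditions
are compared:

    dCt(condition)  = mean Ct_target - mean Ct_reference
    ddCt            = dCt(case) - dCt(control)
    fold change     = 2**(-ddCt)

Amplification efficiency is assumed to be 2 per cycle (no efficiency
correction), which is the assumption the comparative-Ct method rests on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QpcrMeasurement", "FoldChangeResult", "delta_delta_ct"]

CONDITIONS = ("case", "control")
GENE_ROLES = ("target", "reference")


@dataclass(frozen=True)
class QpcrMeasurement:
    sample_id: str
    condition: str  # case | control
    gene_role: str  # target | reference
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.gene_role not in GENE_ROLES:
            raise ValueError(f"gene_role must be one of {GENE_ROLES}")
        if not self.ct > 0:
            raise ValueError(f"ct must be positive, got {self.ct}")


@dataclass(frozen=True)
class FoldChangeResult:
    delta_ct_case: float
    delta_ct_control: float
    delta_delta_ct: float
    fold_change: float
    replicate_sd: float


def delta_delta_ct(
    measurements: pd.DataFrame, mode: str = "mean_ct"
) -> FoldChangeResult:
    """Comparative-Ct fold change of case over control.

    Parameters
    ----------
    measurements
        Long table with columns ``condition`` ({case, control}),
        ``gene_role`` ({target, reference}) and ``ct``.
    mode
        ``"mean_ct"`` (default): replicate Cts are averaged per
        (condition, gene_role) cell before differencing — standard
        comparative-Ct practice.  ``"per_replicate"``: a ddCt is formed per
        replicate index and the fold change is the geometric mean of the
        per-replicate folds; requires equal replicate counts in all cells.

    Raises
    ------
    ValueError
        If any (condition, gene_role) cell has no measurements; the message
        names the missing cell.
    """
    if mode not in ("mean_ct", "per_replicate"):
        raise ValueError(f"unknown mode {mode!r}")
    for col in ("condition", "gene_role", "ct"):
        if col not in measurements.columns:
            raise ValueError(f"measurement table missing column {col!r}")

    cells: dict[tuple[str, str], np.ndarray] = {}
    for cond in CONDITIONS:
        for role in GENE_ROLES:
            mask = (measurements["condition"] == cond) & (
                measurements["gene_role"] == role
            )
            cts = measurements.loc[mask, "ct"].to_numpy(dtype=float)
            if cts.size == 0:
                raise ValueError(f"no measurements for condition={cond!r}, gene_role={role!r}")
            cells[(cond, role)] = cts

    # pooled within-cell replicate scatter, as a QC number
    sds = [cts.std(ddof=1) if cts.size > 1 else 0.0 for cts in cells.values()]
    replicate_sd = float(np.mean(sds))

    if mode == "mean_ct":
        mean = {k: float(v.mean()) for k, v in cells.items()}
        d_case = mean[("case", "target")] - mean[("case", "reference")]
        d_control = mean[("control", "target")] - mean[("control", "reference")]
        ddct = d_case - d_control
    else:
        sizes = {len(v) for v in cells.values()}
        if len(sizes) != 1:
            raise ValueError("per_replicate mode requires equal replicate counts in all cells")
        d_case_r = cells[("case", "target")] - cells[("case", "reference")]
        d_ctrl_r = cells[("control", "target")] - cells[("control", "reference")]
        ddct_r = d_case_r - d_ctrl_r
        d_case = float(d_case_r.mean())
        d_control = float(d_ctrl_r.mean())
        ddct = float(ddct_r.mean())  # arithmetic mean ddCt == geometric mean fold

    return FoldChangeResult(
        delta_ct_case=float(d_case),
        delta_ct_control=float(d_control),
        delta_delta_ct=float(ddct),
        fold_change=float(2.0 ** (-ddct)),
        replicate_sd=replicate_sd,
    )
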