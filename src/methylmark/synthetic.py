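"""Synthetic inputs for every stage of the methylation-biomarker pipeline.

This module generates, from summary statistics alone, data with the same
structure the pipeline sees in a real study: a three-group patient cohort
(AD / MCI / control) with correlated age, MMSE and blood methylation;
qMSP Ct triplets consistent with the percent-methylation formula; qPCR Ct
tables consistent with the comparative-ddCt model; two-group methylation
array intensities with planted delta-beta effects and detection failures;
a promoter reference sequence carrying CpGs at prescribed TSS-relative
offsets; and bisulfite reads from that reference with per-site methylation
probabilities, imperfect conversion, and sequencing errors.

Every simulator is the exact inverse of its downstream quantifier at zero
noise, so planted parameters round-trip exactly — the backbone of the test
suite.  All randomness flows from explicit integer seeds; a fixed seed
gives byte-identical output.

Cohort model
------------
Within each clinical group the three continuous traits (age, MMSE,
methylation %) follow truncated-normal marginals coupled by a Gaussian
copula.  The parent (mu, sigma) of each marginal is moment-matched so the
*truncated* distribution reproduces the configured mean and SD inside the
configured range.  The within-group latent correlation is calibrated from
the pooled targets by removing the between-group component implied by the
configured group means and sizes (pooled covariance = mean within-group
covariance + covariance of group means), because published correlations
are pooled over all subjects.  The methylation-MMSE coupling is configured
as a partial correlation given age and converted to a raw pooled target by
inverting the first-order partial-correlation formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .bisulfite import BisulfiteRead, ReferenceSequence, find_cpg_sites

__all__ = [
    "TraitSpec",
    "GroupConfig",
    "CohortConfig",
    "AssaySimConfig",
    "CopulaCalibrationError",
    "study_cohort_config",
    "generate_cohort",
    "simulate_qmsp_triplets",
    "simulate_expression_cts",
    "simulate_array",
    "make_reference",
    "simulate_bisulfite_reads",
    "generate_dataset",
    "STUDY_CPG_TSS_OFFSETS",
    "STUDY_AMPLICON",
]

# Promoter amplicon geometry used throughout the study-scale fixtures:
# chr22:35,380,082-35,381,037 (GRCh38, 956 bp) with 17 promoter CpGs at
# these TSS-relative offsets.  The implied TSS (start - min offset) is
# 35,381,041.
STUDY_CPG_TSS_OFFSETS = (
    -959, -919, -876, -791, -743, -706, -628, -602, -374, -341,
    -97, -92, -83, -81, -71, -59, -55,
)
STUDY_AMPLICON = {"chrom": "chr22", "start": 35_380_082, "end": 35_381_037, "tss": 35_381_041}


class CopulaCalibrationError(ValueError):
    """Raised when pooled correlation targets imply an infeasible

    within-group latent correlation matrix."""


@dataclass(frozen=True)
class TraitSpec:
    """Truncated-normal marginal for one trait of one group."""

    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if not self.min <= self.mean <= self.max:
            raise ValueError(f"need min <= mean <= max, got {self.min}, {self.mean}, {self.max}")


@dataclass(frozen=True)
class GroupConfig:
    label: str
    n: int
    methylation_pct: TraitSpec
    mmse: TraitSpec
    age: TraitSpec
    female_fraction: float
    apoe4_fraction: float
    apoe4_missing_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: n must be >= 1")
        for name in ("female_fraction", "apoe4_fraction", "apoe4_missing_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"group {self.label!r}: {name} outside [0,1]")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition plus pooled cross-trait correlation targets.

    ``methylation_mmse_partial_r`` is the pooled methylation-MMSE
    correlation *given age* — the form such studies report — and is
    internally converted to a raw pooled target.
    """

    groups: tuple[GroupConfig, ...]
    age_mmse_r: float = -0.589
    age_methylation_r: float = -0.465
    methylation_mmse_partial_r: float = 0.203
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for name in ("age_mmse_r", "age_methylation_r", "methylation_mmse_partial_r"):
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [-1,1]")


def study_cohort_config(seed: int = 0) -> CohortConfig:
    """The three-group cohort at the published study's composition.

    105 AD / 13 MCI / 10 control subjects; group means, SDs and ranges as
    printed in the demographics table and results (methylation % has no
    printed range and is bounded by its natural (0,100) scale); pooled
    age-MMSE r = -0.589, age-methylation r = -0.465, and age-adjusted
    methylation-MMSE partial r = 0.203.  APOE fractions follow the printed
    carrier counts; 14 of the AD subjects have missing APOE status.
    """
    return CohortConfig(
        groups=(
            GroupConfig(
                label="AD",
                n=105,
                methylation_pct=TraitSpec(77.94, 12.97, 0.0, 100.0),
                mmse=TraitSpec(13.71, 5.32, 1, 28),
                age=TraitSpec(81.26, 5.44, 64, 93),
                female_fraction=79 / 105,
                apoe4_fraction=24 / 91,  # 24 carriers of 91 with known status
                apoe4_missing_fraction=14 / 105,
            ),
            GroupConfig(
                label="MCI",
                n=13,
                methylation_pct=TraitSpec(89.15, 5.85, 0.0, 100.0),
                mmse=TraitSpec(22.15, 3.56, 16, 26),
                age=TraitSpec(73.62, 6.19, 58, 80),
                female_fraction=6 / 13,
                apoe4_fraction=4 / 13,
            ),
            GroupConfig(
                label="control",
                n=10,
                methylation_pct=TraitSpec(87.20, 3.06, 0.0, 100.0),
                mmse=TraitSpec(26.10, 1.73, 24, 29),
                age=TraitSpec(72.10, 7.40, 60, 84),
                female_fraction=2 / 10,
                apoe4_fraction=3 / 10,
            ),
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# truncated-normal moment matching


@lru_cache(maxsize=256)
def _match_truncnorm(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent (mu, sigma) whose [lo,hi]-truncation reproduces the target moments.

    The truncated mean is matched exactly (it is monotone in mu for any
    sigma, so a bracketed root always exists for mean strictly inside the
    range); sigma is then chosen to bring the truncated SD as close to the
    target as the family allows.  Published summary statistics can sit
    slightly outside the truncated-normal moment region (a heavy-tailed
    sample can have a larger SD than any truncated normal with the same
    mean and range); in that case the closest achievable SD is used and the
    mean still holds.
    """
    if sd == 0.0:
        return mean, 0.0
    if not lo < mean < hi:
        raise ValueError(f"mean {mean} must lie strictly inside [{lo},{hi}] when sd > 0")

    def mu_for_mean(sigma: float) -> float:
        def f(mu):
            a, b = (lo - mu) / sigma, (hi - mu) / sigma
            return float(sps.truncnorm.mean(a, b, loc=mu, scale=sigma)) - mean

        span = 50.0 * sigma + (hi - lo)
        return optimize.brentq(f, lo - span, hi + span, xtol=1e-10)

    def sd_error(log_sigma: float) -> float:
        sigma = math.exp(log_sigma)
        mu = mu_for_mean(sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return (float(sps.truncnorm.std(a, b, loc=mu, scale=sigma)) - sd) ** 2

    res = optimize.minimize_scalar(
        sd_error, bounds=(math.log(sd / 20.0), math.log(sd * 20.0)), method="bounded",
        options={"xatol": 1e-8},
    )
    sigma = math.exp(res.x)
    return mu_for_mean(sigma), sigma


def _truncnorm_ppf(u: np.ndarray, spec: TraitSpec) -> np.ndarray:
    if spec.sd == 0.0:
        return np.full_like(u, spec.mean)
    mu, sigma = _match_truncnorm(spec.mean, spec.sd, spec.min, spec.max)
    a, b = (spec.min - mu) / sigma, (spec.max - mu) / sigma
    return sps.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


# ---------------------------------------------------------------------------
# copula calibration

_TRAITS = ("age", "mmse", "methylation_pct")


def _pooled_to_within(cfg: CohortConfig) -> np.ndarray:
    """Within-group latent correlation matrix for (age, mmse, methylation).

    Decomposes each pooled covariance target into between-group (from the
    configured group means/sizes) and within-group parts, assuming a common
    within-group correlation across groups, and solves for it.
    """
    n = np.array([g.n for g in cfg.groups], dtype=float)
    w = n / n.sum()
    means = {t: np.array([getattr(g, t).mean for g in cfg.groups]) for t in _TRAITS}
    sds = {t: np.array([getattr(g, t).sd for g in cfg.groups]) for t in _TRAITS}

    def between(tx, ty):
        mx, my = means[tx], means[ty]
        return float(np.sum(w * (mx - np.sum(w * mx)) * (my - np.sum(w * my))))

    def pooled_var(t):
        return float(np.sum(w * sds[t] ** 2)) + between(t, t)

    # invert r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)) for the
    # raw pooled methylation<->mmse target (x=methylation, y=mmse, z=age)
    r_mh_raw = (
        cfg.methylation_mmse_partial_r
        * math.sqrt((1 - cfg.age_methylation_r**2) * (1 - cfg.age_mmse_r**2))
        + cfg.age_methylation_r * cfg.age_mmse_r
    )
    if not -1.0 <= r_mh_raw <= 1.0:
        raise CopulaCalibrationError(
            f"partial target implies raw mmse<->methylation correlation {r_mh_raw:+.3f}"
        )

    targets = {
        ("age", "mmse"): cfg.age_mmse_r,
        ("age", "methylation_pct"): cfg.age_methylation_r,
        ("mmse", "methylation_pct"): r_mh_raw,
    }

    rho = np.eye(3)
    idx = {t: i for i, t in enumerate(_TRAITS)}
    for (tx, ty), r_target in targets.items():
        within_scale = float(np.sum(w * sds[tx] * sds[ty]))
        numer = r_target * math.sqrt(pooled_var(tx) * pooled_var(ty)) - between(tx, ty)
        if within_scale == 0.0:
            if abs(numer) > 1e-9:
                raise CopulaCalibrationError(
                    f"pooled target for {tx}<->{ty} unreachable: zero within-group variance"
                )
            r_w = 0.0
        else:
            r_w = numer / within_scale
        if not -1.0 <= r_w <= 1.0:
            raise CopulaCalibrationError(
                f"pooled target {r_target:+.3f} for {tx}<->{ty} implies within-group "
                f"correlation {r_w:+.3f} outside [-1,1]"
            )
        rho[idx[tx], idx[ty]] = rho[idx[ty], idx[tx]] = r_w

    eigvals = np.linalg.eigvalsh(rho)
    if eigvals.min() < -1e-10:
        raise CopulaCalibrationError(
            "within-group correlation matrix not positive semi-definite; the "
            "mmse<->methylation_pct target conflicts with the two age couplings"
        )
    return rho


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a subject table with the configured group structure.

    Returns a DataFrame with columns ``subject_id, group, age, sex, mmse,
    apoe4, methylation_pct``.  MMSE is rounded to the instrument's integer
    scale; methylation % stays continuous.  Deterministic under the config
    seed.
    """
    rho = _pooled_to_within(config)
    chol = np.linalg.cholesky(rho + 1e-12 * np.eye(3))
    rng = np.random.default_rng(config.seed)

    frames = []
    for g in config.groups:
        z = rng.standard_normal((g.n, 3)) @ chol.T
        u = sps.norm.cdf(z)
        age = _truncnorm_ppf(u[:, 0], g.age)
        mmse = np.rint(_truncnorm_ppf(u[:, 1], g.mmse)).astype(int)
        mmse = np.clip(mmse, int(round(g.mmse.min)), int(round(g.mmse.max)))
        meth = _truncnorm_ppf(u[:, 2], g.methylation_pct)
        sex = np.where(rng.random(g.n) < g.female_fraction, "F", "M")
        apoe = np.where(rng.random(g.n) < g.apoe4_fraction, "carrier", "non-carrier")
        if g.apoe4_missing_fraction > 0:
            apoe = np.where(rng.random(g.n) < g.apoe4_missing_fraction, "missing", apoe)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{g.label}_{i:03d}" for i in range(g.n)],
                    "group": g.label,
                    "age": age,
                    "sex": sex,
                    "mmse": mmse,
                    "apoe4": apoe,
                    "methylation_pct": meth,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# assay simulators


@dataclass(frozen=True)
class AssaySimConfig:
    """Noise and scale parameters for the wet-assay simulators.

    Defaults emulate the study's assays: triplicate reactions, an internal
    control around Ct 22, a 27,578-probe two-group array with 43 detection
    failures, and clone-scale bisulfite sequencing with near-complete
    conversion.
    """

    # qMSP
    qmsp_noise_sd: float = 0.15
    qmsp_replicates: int = 3
    qmsp_internal_baseline_ct: float = 22.0
    qmsp_unmeth_offset_ct: float = 2.0
    # expression qPCR
    expression_fold_change: float = 12.2
    expression_baseline_ct: float = 18.0
    expression_target_offset_ct: float = 6.0
    expression_noise_sd: float = 0.15
    expression_replicates: int = 3
    # array
    array_n_probes: int = 27_578
    array_n_failing: int = 43
    array_planted_delta_beta: tuple[tuple[int, float], ...] = ()
    array_beta_noise_sd: float = 0.0
    array_replicates: int = 2
    array_total_intensity: float = 2000.0
    array_background: float = 100.0
    # bisulfite sequencing
    bisulfite_n_reads: int = 200
    conversion_efficiency: float = 0.99
    sequencing_error_rate: float = 0.001
    read_fragmentation: bool = False
    fragment_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("qmsp_noise_sd", "expression_noise_sd", "array_beta_noise_sd",
                     "sequencing_error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("conversion_efficiency", "sequencing_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")
        if self.array_n_failing > self.array_n_probes:
            raise ValueError("array_n_failing exceeds array_n_probes")
        if self.expression_fold_change <= 0:
            raise ValueError("expression_fold_change must be positive")


def _rng(cfg: AssaySimConfig, stream: int) -> np.random.Generator:
    # one shared seed per dataset, split into independent per-simulator streams
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(stream + 1)[stream])


def simulate_qmsp_triplets(
    true_methylation_pct, cfg: AssaySimConfig, sample_ids=None
) -> pd.DataFrame:
    """Ct triplets whose noise-free percent-methylation readout equals the input.

    Per sample the internal control sits at its baseline Ct, the
    unmethylated channel at a fixed offset above it, and the methylated
    channel is placed so that ``dCt_meth - dCt_unmeth = log2((100-m)/m)``
    before noise — the exact inverse of the percent-methylation formula.
    Independent Gaussian Ct noise is added per replicate and channel.
    """
    m = np.asarray(true_methylation_pct, dtype=float)
    if np.any((m <= 0) | (m >= 100)):
        raise ValueError("true methylation must lie strictly inside (0, 100)")
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(m.size)]
    rng = _rng(cfg, 0)

    rows = []
    d = np.log2((100.0 - m) / m)
    for i, sid in enumerate(sample_ids):
        for rep in range(cfg.qmsp_replicates):
            noise = rng.normal(0.0, cfg.qmsp_noise_sd, 3) if cfg.qmsp_noise_sd > 0 else np.zeros(3)
            ct_internal = cfg.qmsp_internal_baseline_ct + noise[0]
            ct_unmeth = cfg.qmsp_internal_baseline_ct + cfg.qmsp_unmeth_offset_ct + noise[1]
            ct_meth = (
                cfg.qmsp_internal_baseline_ct + cfg.qmsp_unmeth_offset_ct + d[i] + noise[2]
            )
            rows.append(
                {
                    "sample_id": sid,
                    "replicate": rep,
                    "ct_meth": ct_meth,
                    "ct_unmeth": ct_unmeth,
                    "ct_internal": ct_internal,
                }
            )
    return pd.DataFrame(rows)


def simulate_expression_cts(fold_change: float, cfg: AssaySimConfig) -> pd.DataFrame:
    """Case/control qPCR Ct table whose noise-free ddCt recovers the fold change.

    The reference gene sits at the baseline Ct in both conditions; the
    control-condition target sits a fixed offset above it and the case
    target ``log2(fold_change)`` cycles below that, so that
    ddCt = -log2(fold_change) exactly before noise.
    """
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    rng = _rng(cfg, 1)
    rows = []
    ct = {
        ("control", "reference"): cfg.expression_baseline_ct,
        ("control", "target"): cfg.expression_baseline_ct + cfg.expression_target_offset_ct,
        ("case", "reference"): cfg.expression_baseline_ct,
        ("case", "target"): cfg.expression_baseline_ct
        + cfg.expression_target_offset_ct
        - math.log2(fold_change),
    }
    for (cond, role), base in ct.items():
        for rep in range(cfg.expression_replicates):
            noise = rng.normal(0.0, cfg.expression_noise_sd) if cfg.expression_noise_sd else 0.0
            rows.append(
                {
                    "sample_id": f"{cond}_pool",
                    "condition": cond,
                    "gene_role": role,
                    "replicate": rep,
                    "ct": base + noise,
                }
            )
    return pd.DataFrame(rows)


def simulate_array(
    cfg: AssaySimConfig, group_a: str = "A", group_b: str = "B"
) -> pd.DataFrame:
    """Two-group replicated array probe table with planted delta-beta effects.

    Each probe gets a baseline methylation fraction; probes listed in
    ``array_planted_delta_beta`` carry ``beta + delta`` in group B.  Signal
    pairs share a constant background chosen so the noise-free beta
    computation returns the true beta exactly.  Exactly
    ``array_n_failing`` probes receive detection p-values above 0.05 (in
    every record, so probe-wise filtering removes precisely that many).
    The hidden ``true_beta`` column carries the planted group-B-vs-A truth
    for validation.
    """
    rng = _rng(cfg, 2)
    n = cfg.array_n_probes
    base = rng.uniform(0.05, 0.95, n)
    beta = {group_a: base.copy(), group_b: base.copy()}
    for probe_idx, delta in cfg.array_planted_delta_beta:
        if not 0 <= probe_idx < n:
            raise ValueError(f"planted probe index {probe_idx} outside [0,{n})")
        # redraw the baseline inside the feasible band so beta + delta stays in [0,1]
        lo, hi = max(0.05, -delta + 0.01), min(0.95, 1.0 - delta - 0.01)
        if lo >= hi:
            raise ValueError(
                f"planted delta_beta {delta:+.3f} at probe {probe_idx} cannot keep "
                f"beta within [0,1]"
            )
        b0 = rng.uniform(lo, hi)
        beta[group_a][probe_idx] = b0
        beta[group_b][probe_idx] = b0 + delta

    failing = rng.choice(n, size=cfg.array_n_failing, replace=False)
    failing_mask = np.zeros(n, dtype=bool)
    failing_mask[failing] = True

    probe_ids = np.array([f"cg{i:08d}" for i in range(n)])
    frames = []
    for group in (group_a, group_b):
        for rep in range(cfg.array_replicates):
            b = beta[group]
            if cfg.array_beta_noise_sd > 0:
                b = np.clip(b + rng.normal(0.0, cfg.array_beta_noise_sd, n), 0.0, 1.0)
            bg = cfg.array_background
            total = cfg.array_total_intensity
            det_p = np.where(
                failing_mask,
                0.05 + 0.95 * rng.random(n),  # strictly > 0.05
                0.04 * rng.random(n),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": probe_ids,
                        "group": group,
                        "replicate": rep,
                        "signal_meth": bg + b * total,
                        "signal_unmeth": bg + (1.0 - b) * total,
                        "background": bg,
                        "detection_p": det_p,
                        "true_beta": beta[group],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# reference & reads


def make_reference(
    cpg_tss_offsets,
    length: int = 956,
    tss_genomic_coord: int = STUDY_AMPLICON["tss"],
    seed: int = 0,
    chrom: str = "chr22",
    start: int | None = None,
    non_cpg_c_density: float = 0.15,
) -> ReferenceSequence:
    """Random promoter reference with CG dinucleotides exactly at the

    requested TSS-relative offsets and nowhere else.

    The sequence is anchored so that, by default, the most upstream offset
    maps to the first base (start = tss + min(offset)); with the 17
    study offsets and length 956 this reproduces the printed amplicon
    interval.  Remaining bases are drawn from {A, T, G} plus non-CpG
    cytosines at ``non_cpg_c_density`` (they are what the
    conversion-efficiency QC reads out); any accidental CG created by the
    random fill is broken.
    """
    offsets = sorted(int(o) for o in cpg_tss_offsets)
    if len(set(offsets)) != len(offsets):
        raise ValueError("duplicate CpG offsets")
    for a, b in zip(offsets, offsets[1:]):
        if b - a < 2:
            raise ValueError(f"offsets {a} and {b} would create overlapping CG dinucleotides")
    if start is None:
        start = tss_genomic_coord + (offsets[0] if offsets else -length)
    end = start + length - 1

    bad = [o for o in offsets
           if not (start <= tss_genomic_coord + o and tss_genomic_coord + o + 1 <= end)]
    if bad:
        raise ValueError(f"offsets outside the reference interval: {bad}")

    rng = np.random.default_rng(seed)
    p_other = (1.0 - non_cpg_c_density) / 3.0
    bases = rng.choice(
        np.array(list("ATGC")), size=length, p=[p_other, p_other, p_other, non_cpg_c_density]
    )
    # break accidental CGs from the random fill (turn the G into an A)
    for i in range(length - 1):
        if bases[i] == "C" and bases[i + 1] == "G":
            bases[i + 1] = "A"
    # stamp the requested sites; neighbours cannot recreate a stray CG
    for o in offsets:
        i = tss_genomic_coord + o - start
        bases[i] = "C"
        bases[i + 1] = "G"

    ref = ReferenceSequence(
        chrom=chrom, start=start, end=end, tss=tss_genomic_coord, bases="".join(bases)
    )
    found = {s.tss_offset for s in find_cpg_sites(ref)}
    assert found == set(offsets), "internal error: CpG placement failed"
    return ref


def simulate_bisulfite_reads(
    ref: ReferenceSequence, site_probs, cfg: AssaySimConfig
) -> list[BisulfiteRead]:
    """Bisulfite-converted reads from the reference top strand.

    Each read keeps every CpG cytosine as C with its site's methylation
    probability (else T), converts every non-CpG cytosine to T with
    probability ``conversion_efficiency``, and then suffers independent
    per-base substitution errors at ``sequencing_error_rate``.  With
    ``read_fragmentation`` enabled, reads are random
    ``fragment_length``-windows of the amplicon (454-style partial reads);
    by default each read spans the full amplicon (clone sequencing).
    """
    sites = find_cpg_sites(ref)
    probs = np.asarray(site_probs, dtype=float)
    if probs.size != len(sites):
        raise ValueError(
            f"site_probs has {probs.size} entries but the reference has {len(sites)} CpG sites"
        )
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("site probabilities must lie in [0,1]")

    rng = _rng(cfg, 3)
    seq = np.array(list(ref.bases.upper()))
    site_pos = np.array([s.index_in_ref for s in sites], dtype=int)
    is_c = seq == "C"
    non_cpg_c = np.flatnonzero(is_c)
    non_cpg_c = non_cpg_c[~np.isin(non_cpg_c, site_pos)]

    alphabet = np.array(list("ACGT"))
    reads = []
    for k in range(cfg.bisulfite_n_reads):
        bases = seq.copy()
        # CpG cytosines: protected (C) with the site probability, else T
        meth = rng.random(len(site_pos)) < probs
        bases[site_pos[~meth]] = "T"
        # non-CpG cytosines: converted to T with the efficiency
        conv = rng.random(non_cpg_c.size) < cfg.conversion_efficiency
        bases[non_cpg_c[conv]] = "T"
        # independent substitution errors
        if cfg.sequencing_error_rate > 0:
            err = np.flatnonzero(rng.random(bases.size) < cfg.sequencing_error_rate)
            for i in err:
                choices = alphabet[alphabet != bases[i]]
                bases[i] = choices[rng.integers(3)]
        if cfg.read_fragmentation and cfg.fragment_length < bases.size:
            lo = int(rng.integers(0, bases.size - cfg.fragment_length + 1))
            bases = bases[lo : lo + cfg.fragment_length]
        reads.append(BisulfiteRead(read_id=f"read_{k:05d}", bases="".join(bases)))
    return reads


# ---------------------------------------------------------------------------
# one-call dataset


def generate_dataset(
    cohort_cfg: CohortConfig | None = None,
    assay_cfg: AssaySimConfig | None = None,
    site_probs=None,
) -> dict:
    """Generate every pipeline input in one call.

    Returns a dict with keys ``subjects`` (DataFrame), ``qmsp``
    (DataFrame), ``qpcr`` (DataFrame), ``array`` (DataFrame),
    ``reference`` (ReferenceSequence), ``reads`` (list of BisulfiteRead).
    The cohort's per-subject methylation values drive the qMSP simulator,
    so the two stages are mutually consistent.
    """
    cohort_cfg = cohort_cfg or study_cohort_config()
    assay_cfg = assay_cfg or AssaySimConfig(seed=cohort_cfg.seed)

    subjects = generate_cohort(cohort_cfg)
    qmsp = simulate_qmsp_triplets(
        subjects["methylation_pct"].to_numpy(), assay_cfg,
        sample_ids=subjects["subject_id"].tolist(),
    )
    qpcr = simulate_expression_cts(assay_cfg.expression_fold_change, assay_cfg)
    array = simulate_array(assay_cfg)
    ref = make_reference(STUDY_CPG_TSS_OFFSETS, seed=assay_cfg.seed)
    if site_probs is None:
        # promoter mostly methylated; the two mid-amplicon sites hypomethylated,
        # mirroring the screen's strongest signals
        site_probs = np.full(len(STUDY_CPG_TSS_OFFSETS), 0.9)
        site_probs[STUDY_CPG_TSS_OFFSETS.index(-374)] = 0.2
        site_probs[STUDY_CPG_TSS_OFFSETS.index(-341)] = 0.25
    reads = simulate_bisulfite_reads(ref, site_probs, assay_cfg)
    return {
        "subjects": subjects,
        "qmsp": qmsp,
        "qpcr": qpcr,
        "array": array,
        "reference": ref,
        "reads": reads,
    }
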