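"""Synthetic case-control cohort generator.

Produces cohorts with the joint biomarker / physiology / activity / survival
structure the downstream analysis assumes, together with planted ground truth
for recovery tests.

Generative model
----------------
A latent unitless "severity" score couples all blocks.  Three correlated
physiological factors (function/activity, systolic, diastolic) each load on
severity; the 92 log-scale biomarkers form three correlation blocks whose
block factors are tied to the physiological factors, so markers acquire
calibrated within-block, between-block and marker-physiology correlations.
Marker abundances are log-normal: normal on the log2 scale, exponentiated to
strictly positive arbitrary units, with a per-marker multiplicative
case/control ratio applied on the log scale so the expected linear-scale
group-mean ratio equals the configured effect profile exactly.

Event times follow a Weibull proportional-hazards law with a per-subject
log-hazard proportional to severity, censored administratively with uniform
staggered entry.  Accelerometer traces are day-structured (sleep gap, wear
block, geometric activity bouts) with per-subject active fraction and wear
time tied to the same latent structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "InfeasibleTargetError",
    "PHYSIO_VARIABLES",
    "PHYSIO_NAMES",
    "CATEGORY_MAP",
    "TABLE2_RATIOS",
    "default_effect_profile",
    "calibrate_block_correlations",
    "block_correlation_matrix",
    "simulate_severities",
    "simulate_markers",
    "simulate_physiology",
    "simulate_survival",
    "simulate_accel_trace",
    "simulate_accel_traces",
    "simulate_cohort",
    "recovery_scenario_config",
]


class InfeasibleTargetError(ValueError):
    """Raised when requested correlation/variance targets cannot coexist."""


# ---------------------------------------------------------------------------
# physiological variable metadata
# ---------------------------------------------------------------------------

#: (name, factor index, severity sign, HF (med, q1, q3), control (med, q1, q3))
#: sign +1 means the variable increases as latent severity worsens.
PHYSIO_VARIABLES: list[tuple[str, int, int, tuple, tuple]] = [
    ("vo2peak",      0, -1, (13.4, 12.0, 16.1),   (23.8, 17.7, 25.4)),
    ("map",          0, -1, (89.0, 82.0, 97.0),   (107.0, 100.0, 113.0)),
    ("heart_rate",   0, +1, (72.5, 64.8, 80.0),   (72.0, 67.0, 76.0)),
    ("pct_active",   0, -1, (22.0, 17.0, 30.0),   (38.0, 31.0, 44.0)),
    ("skewness_cpm", 0, +1, (1.6, 0.8, 2.5),      (1.0, 0.8, 1.5)),
    ("lvef",         1, -1, (25.0, 20.0, 32.0),   (57.75, 55.0, 60.0)),
    ("psv",          1, -1, (0.04, 0.03, 0.05),   (0.07, 0.06, 0.08)),
    ("lvedd",        1, +1, (64.0, 59.0, 71.2),   (46.0, 42.0, 52.0)),
    ("tapse",        1, -1, (15.0, 11.5, 18.0),   (23.0, 18.0, 25.0)),
    ("septal_e",     2, -1, (0.04, 0.035, 0.05),  (0.07, 0.06, 0.08)),
    ("lateral_e",    2, -1, (0.05, 0.04, 0.08),   (0.08, 0.07, 0.11)),
    ("e_over_e",     2, +1, (16.4, 12.7, 24.0),   (9.5, 7.6, 11.8)),
    ("la_area",      2, +1, (31.0, 26.0, 36.0),   (19.0, 15.2, 20.8)),
    ("pa_pressure",  2, +1, (47.0, 40.0, 52.9),   (30.0, 30.0, 40.0)),
]

PHYSIO_NAMES = [v[0] for v in PHYSIO_VARIABLES]

#: analysis categories over the physiology block (category -> variable names)
CATEGORY_MAP: dict[str, list[str]] = {
    "capacity": ["vo2peak", "map", "heart_rate"],
    "activity": ["pct_active", "pct_inactive", "skewness_cpm"],
    "myocardial": [
        "lvef", "psv", "lvedd", "tapse", "septal_e", "lateral_e",
        "e_over_e", "la_area", "pa_pressure",
    ],
}

#: latent factor driving each category (activity and capacity share factor 0)
CATEGORY_FACTORS: dict[str, tuple[int, ...]] = {
    "capacity": (0,),
    "activity": (0,),
    "myocardial": (1, 2),
}

# communality and factor/severity coupling calibrated so that the 14-variable
# physiology block shows ~75% variance in its first three PCs and a mean
# pairwise |r| of ~0.25:  14*h2 + 3*(1-h2) = 0.75*14  and
# (26*h2 + 65*h2*phi) / 91 = 0.25
_PHYSIO_H2 = 7.5 / 11.0
_PHYSIO_PHI = (0.25 * 91 - 26 * _PHYSIO_H2) / (65 * _PHYSIO_H2)
_FACTOR_SEV_CORR = float(np.sqrt(_PHYSIO_PHI))


def default_severity_link() -> dict[str, float]:
    """Signed default loading of each physiological variable on its factor."""
    loading = float(np.sqrt(_PHYSIO_H2))
    return {name: sign * loading for name, _, sign, _, _ in PHYSIO_VARIABLES}


# ---------------------------------------------------------------------------
# case/control effect profile (linear-scale group-mean ratios)
# ---------------------------------------------------------------------------

#: 39 differentially abundant panel factors and their HF/control ratios
TABLE2_RATIOS: dict[str, float] = {
    "EGFR": 0.3, "NT-proBNP": 5.69, "PON3": 0.1, "TLT-2": 0.2, "TFPI": 0.3,
    "GDF-15": 10.3, "PAI": 0.1, "U-PAR": 3.2, "MMP-3": 4.0, "SELP": 0.2,
    "FABP4": 10.2, "CNTN1": 0.5, "TR-AP": 0.4, "PDGF-A": 0.1, "SPON1": 2.6,
    "DLK-1": 0.3, "ITGB2": 0.4, "PI3": 4.2, "LDL-R": 0.3, "Gal-4": 2.5,
    "ST2": 3.3, "COL1A1": 0.4, "CASP-3": 0.1, "OPN": 2.9,
    "BLM-hydrolase": 0.5, "TFF3": 3.1, "TfR": 3.3, "PLC": 2.1, "CSTB": 3.2,
    "IGFBP-7": 3.2, "TNF-R1": 2.7, "PECAM-1": 0.3, "TNF-R2": 2.4,
    "FAS": 0.6, "MPO": 0.5, "PSP-D": 2.8, "Ep-CAM": 0.3, "CCL24": 0.3,
    "RARRES2": 0.6,
}


def default_effect_profile(p_markers: int = 92) -> np.ndarray:
    """Per-marker HF/control linear-scale ratio vector.

    The 39 tabulated ratios are planted at every other marker index
    (spreading them across the three correlation blocks); all remaining
    markers get ratio 1.0.
    """
    profile = np.ones(p_markers)
    ratios = list(TABLE2_RATIOS.values())
    for i, ratio in enumerate(ratios):
        idx = 2 * i
        if idx >= p_markers:
            break
        profile[idx] = ratio
    return profile


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic cohort generator.

    The defaults are calibrated against the printed cohort statistics:
    mean pairwise marker correlation 0.25 with ~48% of marker variance in
    three PCs, ~75% of physiology variance in three PCs, HF median VO2peak
    13.4 mL/kg/min, HF median 950 active min/week (controls 2182), and
    ~42/66 HF deaths with median event time ~1.8 years.
    """

    n_hf: int = 66
    n_ctrl: int = 28
    p_markers: int = 92
    cluster_sizes: tuple[int, int, int] = (31, 31, 30)
    within_corr: float = 0.46247191011235955
    between_corr: float = 0.14719101123595508
    effect_profile: np.ndarray | None = None
    severity_link: dict[str, float] | None = None
    marker_sev_loading: np.ndarray | None = None
    block_link: float = 1.0          # coupling of marker blocks to factors
    factor_sev_corr: float = _FACTOR_SEV_CORR
    marker_log2_sd: float = 1.0
    marker_log2_mean: float = 5.0
    baseline_hazard: float = 0.3738  # events/year (Weibull scale rate)
    hazard_shape: float = 2.489      # Weibull shape; 1.0 -> exponential
    severity_log_hazard: float = 0.7
    control_hazard_scale: float = 0.15
    censor_time: float = 5.0
    entry_span: float = 4.0          # staggered-entry censoring width (years)
    wear_base: tuple[float, float] = (840.0, 900.0)   # HF/control min/day
    wear_sd: float = 45.0
    target_weekly_active: tuple[float, float] = (950.0, 2182.0)  # min/week
    low_compliance_rate: float = 0.04  # subjects worn < 3 days (excluded)
    active_bout_mean: float = 8.0    # minutes
    active_cpm_shape: float = 1.2
    active_cpm_scale: float = 350.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.cluster_sizes) != self.p_markers:
            raise ValueError(
                f"cluster_sizes {self.cluster_sizes} must sum to "
                f"p_markers={self.p_markers}"
            )
        if not (0.0 <= self.between_corr < 1.0 and 0.0 <= self.within_corr < 1.0):
            raise ValueError("correlations must lie in [0, 1)")
        if self.between_corr > self.within_corr:
            raise ValueError(
                f"between_corr ({self.between_corr}) must not exceed "
                f"within_corr ({self.within_corr})"
            )
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0")
        if self.entry_span < 0 or self.entry_span >= self.censor_time:
            raise ValueError("entry_span must lie in [0, censor_time)")
        if self.effect_profile is not None and len(self.effect_profile) != self.p_markers:
            raise ValueError("effect_profile length must equal p_markers")
        if self.marker_sev_loading is not None and len(self.marker_sev_loading) != self.p_markers:
            raise ValueError("marker_sev_loading length must equal p_markers")

    # resolved defaults -----------------------------------------------------

    def resolved_effect_profile(self) -> np.ndarray:
        if self.effect_profile is not None:
            return np.asarray(self.effect_profile, dtype=float)
        return default_effect_profile(self.p_markers)

    def resolved_severity_link(self) -> dict[str, float]:
        if self.severity_link is not None:
            return dict(self.severity_link)
        return default_severity_link()

    def marker_mixture(self) -> tuple[np.ndarray, float, np.ndarray]:
        """Return ``(lambda_j, c, d_j)`` of the marker latent decomposition.

        ``z_j = lambda_j*sev + c*u_block + d_j*eps`` where the block factors
        ``u_block`` are standardized, mutually independent and orthogonal to
        severity (but aligned with the severity-orthogonal part of the
        physiological factors through ``block_link``).  This reproduces the
        within/between block correlation targets exactly:
        between = lambda^2, within = lambda^2 + c^2.
        """
        w, b = self.within_corr, self.between_corr
        if self.marker_sev_loading is not None:
            lam = np.asarray(self.marker_sev_loading, dtype=float)
        else:
            lam = np.full(self.p_markers, np.sqrt(b))
        c = float(np.sqrt(w - b))
        d2 = 1.0 - lam ** 2 - c * c
        if np.any(d2 < -1e-12):
            raise InfeasibleTargetError(
                "marker severity loadings exceed the unit-variance budget "
                f"given within_corr={w}, between_corr={b}"
            )
        return lam, c, np.sqrt(np.maximum(d2, 0.0))


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort.

    Attributes
    ----------
    marker_category_corr : DataFrame (marker x category)
        Population correlation between each log-scale marker and the latent
        factor(s) behind each analysis category (max |corr| over a
        category's factors, signed).
    planted_edges : list of (marker_name, category)
        Marker-category dependencies with |population correlation| >= 0.2.
    true_ratio : Series
        Per-marker linear-scale HF/control mean ratio.
    true_log_hazard : Series
        Population log-hazard slope per 1-SD increase of each log2 marker.
    severities : Series
        Latent severity per subject id.
    """

    marker_category_corr: pd.DataFrame
    planted_edges: list[tuple[str, str]]
    true_ratio: pd.Series
    true_log_hazard: pd.Series
    severities: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "planted_edges": [list(e) for e in self.planted_edges],
            "true_ratio": self.true_ratio.to_dict(),
            "true_log_hazard": self.true_log_hazard.to_dict(),
            "marker_category_corr": {
                c: self.marker_category_corr[c].to_dict()
                for c in self.marker_category_corr.columns
            },
        }


# ---------------------------------------------------------------------------
# correlation calibration
# ---------------------------------------------------------------------------


def block_correlation_matrix(
    cluster_sizes: Sequence[int], w: float, b: float
) -> np.ndarray:
    """Population 3-block equicorrelation matrix (within ``w``, between ``b``)."""
    p = sum(cluster_sizes)
    mat = np.full((p, p), b)
    start = 0
    for s in cluster_sizes:
        mat[start:start + s, start:start + s] = w
        start += s
    np.fill_diagonal(mat, 1.0)
    return mat


def _top3_share(cluster_sizes: Sequence[int], w: float, b: float) -> float:
    """Exact top-3 eigenvalue share of the block equicorrelation matrix.

    Eigenvalues split into the spectrum of the reduced k x k matrix
    ``M[k,l] = delta_kl*(1+(s_k-1)w) + (1-delta_kl)*b*sqrt(s_k s_l)`` and the
    bulk value ``1-w`` with multiplicity ``p-k``.
    """
    sizes = np.asarray(cluster_sizes, dtype=float)
    p = sizes.sum()
    m = b * np.sqrt(np.outer(sizes, sizes))
    np.fill_diagonal(m, 1.0 + (sizes - 1.0) * w)
    reduced = np.linalg.eigvalsh(m)
    eigs = np.sort(np.concatenate([reduced, np.full(int(p) - len(sizes), 1.0 - w)]))
    return float(eigs[-3:].sum() / p)


def calibrate_block_correlations(
    p_markers: int,
    cluster_sizes: Sequence[int],
    target_mean_r: float,
    target_top3_var: float,
    tol: float = 0.03,
) -> tuple[float, float]:
    """Find ``(w, b)`` matching a mean-correlation and top-3-variance target.

    Bisects over the within-block correlation ``w``; for each trial ``w`` the
    between-block correlation is pinned by the mean-correlation constraint
    and the top-3 eigenvalue share is evaluated in closed form.

    Raises
    ------
    InfeasibleTargetError
        If no ``(w, b)`` with ``0 <= b <= w < 1`` achieves the top-3 target
        within ``tol`` while holding the mean correlation.
    """
    if not (0.0 < target_mean_r < 1.0):
        raise InfeasibleTargetError("target_mean_r must lie in (0, 1)")
    if sum(cluster_sizes) != p_markers:
        raise ValueError("cluster_sizes must sum to p_markers")
    sizes = list(cluster_sizes)
    within_pairs = sum(s * (s - 1) // 2 for s in sizes)
    total_pairs = p_markers * (p_markers - 1) // 2
    between_pairs = total_pairs - within_pairs

    def b_of(w: float) -> float:
        if between_pairs == 0:
            return 0.0
        return (target_mean_r * total_pairs - within_pairs * w) / between_pairs

    def feasible(w: float) -> bool:
        b = b_of(w)
        return 0.0 <= b <= w

    # admissible w range: b(w) in [0, w]
    grid = np.linspace(target_mean_r, 1.0 - 1e-9, 4001)
    ok = [w for w in grid if feasible(w)]
    if not ok:
        raise InfeasibleTargetError(
            f"no within/between correlations satisfy mean r = {target_mean_r}"
        )
    lo, hi = min(ok), max(ok)
    share_lo = _top3_share(sizes, lo, b_of(lo))
    share_hi = _top3_share(sizes, hi, b_of(hi))
    if not (min(share_lo, share_hi) - tol <= target_top3_var <= max(share_lo, share_hi) + tol):
        raise InfeasibleTargetError(
            f"top-3 variance target {target_top3_var} unreachable: attainable "
            f"range is [{min(share_lo, share_hi):.3f}, {max(share_lo, share_hi):.3f}] "
            f"at mean r = {target_mean_r}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        share = _top3_share(sizes, mid, b_of(mid))
        if (share < target_top3_var) == (share_lo < target_top3_var):
            lo = mid
        else:
            hi = mid
    w = 0.5 * (lo + hi)
    b = b_of(w)
    achieved = _top3_share(sizes, w, b)
    if abs(achieved - target_top3_var) > tol:
        raise InfeasibleTargetError(
            f"calibration converged to top-3 share {achieved:.3f}, more than "
            f"{tol} away from target {target_top3_var}"
        )
    return float(w), float(b)


# ---------------------------------------------------------------------------
# latent draws
# ---------------------------------------------------------------------------


def simulate_severities(config: CohortConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Latent severity scores, standard normal within each group."""
    return rng.standard_normal(n)


def _draw_factors(
    config: CohortConfig, severities: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Three physiological factors, each correlated ``rho`` with severity."""
    n = len(severities)
    rho = config.factor_sev_corr
    eta = rng.standard_normal((n, 3))
    return rho * severities[:, None] + np.sqrt(1.0 - rho * rho) * eta


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


def marker_names(p_markers: int) -> list[str]:
    return [f"marker_{j + 1:03d}" for j in range(p_markers)]


def simulate_markers(
    config: CohortConfig,
    severities: np.ndarray,
    groups: np.ndarray,
    rng: np.random.Generator | None = None,
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate the positive-abundance biomarker panel.

    Parameters
    ----------
    severities : (n,) latent severity scores.
    groups : (n,) array of "HF"/"control" labels.
    factors : optional (n, 3) physiological factor draws to couple marker
        blocks to; drawn internally when omitted.

    Returns
    -------
    DataFrame of shape (n, p_markers), strictly positive linear-scale values.
    """
    if rng is None:
        rng = child_rng(config.seed, "markers")
    severities = np.asarray(severities, dtype=float)
    n = len(severities)
    if factors is None:
        factors = _draw_factors(config, severities, rng)

    corr = block_correlation_matrix(
        config.cluster_sizes, config.within_corr, config.between_corr
    )
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise InfeasibleTargetError(
            f"block correlation (w={config.within_corr}, b={config.between_corr}) "
            "is not positive definite"
        )

    lam, c, d = config.marker_mixture()
    psi = config.block_link
    rho = config.factor_sev_corr
    nu = rng.standard_normal((n, 3))
    # block factors: standard normal, orthogonal to severity, independent
    # across blocks, aligned with the severity-orthogonal factor parts
    u_raw = psi * (factors - rho * severities[:, None]) + np.sqrt(1.0 - psi * psi) * nu
    denom = np.sqrt(max(1.0 - psi * psi * rho * rho, 1e-12))
    u = u_raw / denom

    block_of = np.repeat(np.arange(3), config.cluster_sizes)
    eps = rng.standard_normal((n, config.p_markers))
    z = lam[None, :] * severities[:, None] + c * u[:, block_of] + d[None, :] * eps

    ratios = config.resolved_effect_profile()
    if np.any(ratios <= 0):
        raise ValueError("effect_profile ratios must be strictly positive")
    is_hf = (np.asarray(groups) == "HF").astype(float)
    log2m = (
        config.marker_log2_mean
        + np.log2(ratios)[None, :] * is_hf[:, None]
        + config.marker_log2_sd * z
    )
    values = np.exp2(log2m)
    return pd.DataFrame(values, columns=marker_names(config.p_markers))


def marker_category_correlations(config: CohortConfig) -> pd.DataFrame:
    """Population correlation of each log-marker with each category factor.

    ``corr(z_j, f_m) = lam_j*rho + c*psi*(Phi[k(j),m] - rho^2)/sqrt(1-psi^2 rho^2)``
    with factor correlation ``Phi = rho^2`` off-diagonal; a category column
    is zeroed when none of its variables carries a severity-link loading
    (its summary scores are then pure noise).
    """
    lam, c, _ = config.marker_mixture()
    psi = config.block_link
    rho = config.factor_sev_corr
    phi = rho * rho
    denom = np.sqrt(max(1.0 - psi * psi * phi, 1e-12))
    block_of = np.repeat(np.arange(3), config.cluster_sizes)
    fac_corr = np.full((3, 3), phi)
    np.fill_diagonal(fac_corr, 1.0)
    corr_fm = lam[:, None] * rho + c * psi * (fac_corr[block_of, :] - phi) / denom
    link = config.resolved_severity_link()
    out = pd.DataFrame(index=marker_names(config.p_markers))
    for cat, fids in CATEGORY_FACTORS.items():
        cat_vars = [v for v in CATEGORY_MAP[cat] if v != "pct_inactive"]
        if all(abs(link.get(v, 0.0)) < 1e-12 for v in cat_vars):
            out[cat] = 0.0
            continue
        sub = corr_fm[:, list(fids)]
        best = sub[np.arange(len(sub)), np.abs(sub).argmax(axis=1)]
        out[cat] = best
    return out


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------


def simulate_physiology(
    config: CohortConfig,
    severities: np.ndarray,
    groups: np.ndarray,
    rng: np.random.Generator | None = None,
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate the 14-variable physiological block in clinical units.

    Each variable is a group-specific location (cohort medians as defaults)
    plus a signed loading on its latent factor and independent noise, scaled
    by the group IQR.  Medians of generated HF variables match the defaults
    within sampling error because severity has median zero within groups.
    """
    if rng is None:
        rng = child_rng(config.seed, "physiology")
    severities = np.asarray(severities, dtype=float)
    n = len(severities)
    if factors is None:
        factors = _draw_factors(config, severities, rng)
    link = config.resolved_severity_link()
    unknown = set(link) - set(PHYSIO_NAMES)
    if unknown:
        raise ValueError(f"unknown physiology variable(s) in severity_link: {sorted(unknown)}")

    is_hf = np.asarray(groups) == "HF"
    data = {}
    for name, fac_idx, _sign, hf_stats, ctrl_stats in PHYSIO_VARIABLES:
        loading = link.get(name, 0.0)
        resid_sd = float(np.sqrt(max(1.0 - loading * loading, 0.0025)))
        z = loading * factors[:, fac_idx] + resid_sd * rng.standard_normal(n)
        med = np.where(is_hf, hf_stats[0], ctrl_stats[0])
        scale = np.where(
            is_hf,
            (hf_stats[2] - hf_stats[1]) / 1.349,
            (ctrl_stats[2] - ctrl_stats[1]) / 1.349,
        )
        data[name] = med + scale * z
    df = pd.DataFrame(data)
    # physical range guards (affect far tails only)
    df["vo2peak"] = df["vo2peak"].clip(lower=3.0)
    df["pct_active"] = df["pct_active"].clip(0.5, 99.5)
    df["lvef"] = df["lvef"].clip(5.0, 80.0)
    for col in ("psv", "septal_e", "lateral_e", "e_over_e", "la_area",
                "pa_pressure", "tapse", "lvedd", "heart_rate", "map"):
        df[col] = df[col].clip(lower=0.01)
    return df


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def simulate_survival(
    config: CohortConfig,
    severities: np.ndarray,
    rng: np.random.Generator | None = None,
    groups: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate (time, event) per subject.

    Event times follow a Weibull proportional-hazards model with cumulative
    hazard ``H(t) = (h0*t)^k * exp(gamma*severity) * group_scale`` and are
    censored at ``censor_time - U(0, entry_span)`` (staggered entry).  The
    default shape ``k~2.5`` is calibrated jointly with ``h0`` so the HF group
    shows ~63.6% events with a median event time of ~1.8 years; a shape of
    1 recovers the exponential model.
    """
    if rng is None:
        rng = child_rng(config.seed, "survival")
    severities = np.asarray(severities, dtype=float)
    n = len(severities)
    scale = np.ones(n)
    if groups is not None:
        scale = np.where(np.asarray(groups) == "HF", 1.0, config.control_hazard_scale)
    g = config.severity_log_hazard
    k = config.hazard_shape
    u = rng.uniform(size=n)
    t_event = (-np.log(u) * np.exp(-g * severities) / scale) ** (1.0 / k) / config.baseline_hazard
    c = config.censor_time - rng.uniform(0.0, config.entry_span, size=n) if config.entry_span > 0 \
        else np.full(n, config.censor_time)
    event = (t_event < c).astype(int)
    time = np.minimum(t_event, c)
    time = np.maximum(time, 1e-6)
    return time, event


# ---------------------------------------------------------------------------
# accelerometry traces
# ---------------------------------------------------------------------------

EPOCHS_PER_DAY = 1440
TRACE_DAYS = 7


def _one_trace(
    config: CohortConfig,
    p_active: float,
    wear_minutes_per_day: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one week of per-minute cpm plus the true wear mask."""
    n_epochs = EPOCHS_PER_DAY * TRACE_DAYS
    cpm = np.zeros(n_epochs, dtype=np.int64)
    wear = np.zeros(n_epochs, dtype=bool)
    p_active = float(np.clip(p_active, 0.005, 0.995))
    mean_a = config.active_bout_mean
    mean_i = mean_a * (1.0 - p_active) / p_active
    for day in range(TRACE_DAYS):
        dur = int(np.clip(wear_minutes_per_day[day], 120, 1020))
        start = day * EPOCHS_PER_DAY + 360 + int(rng.normal(0, 20))
        start = max(day * EPOCHS_PER_DAY, start)
        end = min((day + 1) * EPOCHS_PER_DAY, start + dur)
        dur = end - start
        if dur <= 0:
            continue
        wear[start:end] = True
        # alternating geometric activity/rest bouts
        n_bouts = max(4, int(2.5 * dur / (mean_a + mean_i)) + 8)
        len_a = rng.geometric(min(1.0 / mean_a, 1.0), size=n_bouts)
        len_i = rng.geometric(min(1.0 / mean_i, 1.0), size=n_bouts)
        states = np.empty(2 * n_bouts, dtype=bool)
        states[0::2] = rng.uniform() < p_active
        states[1::2] = ~states[0]
        lengths = np.empty(2 * n_bouts, dtype=np.int64)
        lengths[0::2] = len_a if states[0] else len_i
        lengths[1::2] = len_i if states[0] else len_a
        seq = np.repeat(states, lengths)[:dur]
        while len(seq) < dur:  # pragma: no cover - n_bouts oversized
            seq = np.concatenate([seq, np.repeat(states, lengths)])[:dur]
        n_act = int(seq.sum())
        vals = np.zeros(dur, dtype=np.int64)
        if n_act:
            vals[seq] = 100 + rng.gamma(
                config.active_cpm_shape, config.active_cpm_scale, size=n_act
            ).astype(np.int64)
        n_inact = dur - n_act
        if n_inact:
            low = rng.integers(1, 100, size=n_inact)
            low[rng.uniform(size=n_inact) < 0.35] = 0
            vals[~seq] = low
        cpm[start:end] = vals
    return cpm, wear


def simulate_accel_trace(
    config: CohortConfig,
    severity: float,
    group: str,
    rng: np.random.Generator,
    pct_active: float | None = None,
    return_truth: bool = False,
):
    """Simulate a 7-day, 60-s-epoch cpm trace for one subject.

    Weekly active minutes scale inversely with severity through both the
    active fraction and the daily wear duration.  The sleep gap (device off
    overnight) provides known non-wear intervals for detector tests.
    """
    gi = 0 if group == "HF" else 1
    base = config.wear_base[gi]
    link = config.resolved_severity_link()
    hf, ctrl = dict((v[0], (v[3], v[4])) for v in PHYSIO_VARIABLES)["pct_active"]
    med_pct = hf[0] if group == "HF" else ctrl[0]
    if pct_active is None:
        q1, q3 = (hf[1], hf[2]) if group == "HF" else (ctrl[1], ctrl[2])
        z = link.get("pct_active", 0.0) * severity
        pct_active = float(np.clip(med_pct + (q3 - q1) / 1.349 * z, 0.5, 99.5))
    # active fraction scaled from the planted percentage so the group median
    # weekly active minutes lands on the configured target
    frac_med = config.target_weekly_active[gi] / (TRACE_DAYS * base)
    frac = frac_med * pct_active / med_pct
    # wear tied to the same latent direction (comonotone keeps the median)
    z_act = (pct_active - med_pct) / 10.0
    wear_per_day = base + config.wear_sd * z_act + rng.normal(0, 15, size=TRACE_DAYS)
    if rng.uniform() < config.low_compliance_rate:
        wear_per_day = wear_per_day * rng.uniform(0.3, 0.55)
    cpm, wear = _one_trace(config, frac, wear_per_day, rng)
    ts = np.arange(len(cpm)) * 60
    df = pd.DataFrame({"timestamp": ts, "cpm": cpm})
    if return_truth:
        return df, wear
    return df


def simulate_accel_traces(
    config: CohortConfig,
    severities: np.ndarray,
    groups: np.ndarray,
    rng: np.random.Generator | None = None,
    pct_active: np.ndarray | None = None,
) -> list[pd.DataFrame]:
    """Simulate traces for a vector of subjects (loop over `_one_trace`)."""
    if rng is None:
        rng = child_rng(config.seed, "accel")
    out = []
    for i, (sev, grp) in enumerate(zip(severities, groups)):
        pa = None if pct_active is None else float(pct_active[i])
        out.append(simulate_accel_trace(config, float(sev), str(grp), rng, pct_active=pa))
    return out


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    config: CohortConfig,
    include_traces: bool = False,
):
    """Simulate a complete joined cohort.

    Returns
    -------
    table : DataFrame
        One row per subject: id, group, demographics, severity, marker
        columns, physiology columns, activity summary (derived from the
        simulated traces through the accelerometry module), time, event.
    truth : GroundTruth
    traces : list of DataFrame, only when ``include_traces`` is True.
    """
    from . import accelerometry  # local import to avoid cycle at import time

    n = config.n_hf + config.n_ctrl
    groups = np.array(["HF"] * config.n_hf + ["control"] * config.n_ctrl)
    ids = np.array([f"S{i + 1:03d}" for i in range(n)])

    rng_sev = child_rng(config.seed, "severity")
    severities = simulate_severities(config, n, rng_sev)
    factors = _draw_factors(config, severities, child_rng(config.seed, "factors"))

    markers = simulate_markers(
        config, severities, groups, child_rng(config.seed, "markers"), factors=factors
    )
    physio = simulate_physiology(
        config, severities, groups, child_rng(config.seed, "physiology"), factors=factors
    )
    time, event = simulate_survival(
        config, severities, child_rng(config.seed, "survival"), groups=groups
    )

    traces = simulate_accel_traces(
        config, severities, groups, child_rng(config.seed, "accel"),
        pct_active=physio["pct_active"].to_numpy(),
    )
    summaries = []
    for tr in traces:
        trace = accelerometry.EpochTrace(
            timestamps=tr["timestamp"].to_numpy(), cpm=tr["cpm"].to_numpy()
        )
        mask = accelerometry.detect_nonwear(trace)
        summaries.append(accelerometry.summarize_activity(trace, mask))

    rng_demo = child_rng(config.seed, "demographics")
    is_hf = groups == "HF"
    age = np.where(is_hf, 70.0, 70.5) + rng_demo.normal(0, 6.5, n)
    female = rng_demo.uniform(size=n) < np.where(is_hf, 0.20, 0.71)
    weight = np.where(is_hf, 85.0, 70.0) + rng_demo.normal(0, 12.0, n)
    creatinine = np.exp(
        np.log(np.where(is_hf, 1.25, 0.9)) + 0.25 * rng_demo.normal(size=n)
        + 0.1 * severities * is_hf
    )

    table = pd.DataFrame({
        "id": ids,
        "group": groups,
        "age": np.round(age, 1),
        "sex": np.where(female, "female", "male"),
        "weight": np.round(np.clip(weight, 40, 160), 1),
        "creatinine": np.round(creatinine, 3),
        "severity": severities,
    })
    table = pd.concat([table, markers, physio.drop(columns=["pct_active", "skewness_cpm"])],
                      axis=1)
    table["wear_days"] = [s.wear_days for s in summaries]
    table["pct_active"] = [s.pct_active for s in summaries]
    table["pct_inactive"] = [s.pct_inactive for s in summaries]
    table["skewness_cpm"] = [s.skewness for s in summaries]
    table["activity_valid"] = [s.valid for s in summaries]
    table["time"] = time
    table["event"] = event

    cat_corr = marker_category_correlations(config)
    edges = [
        (marker, cat)
        for marker in cat_corr.index
        for cat in cat_corr.columns
        if abs(cat_corr.loc[marker, cat]) >= 0.2
    ]
    lam, _, _ = config.marker_mixture()
    sev_corr = lam  # block factors are severity-orthogonal
    truth = GroundTruth(
        marker_category_corr=cat_corr,
        planted_edges=edges,
        true_ratio=pd.Series(config.resolved_effect_profile(), index=cat_corr.index),
        true_log_hazard=pd.Series(
            config.severity_log_hazard * sev_corr, index=cat_corr.index
        ),
        severities=pd.Series(severities, index=ids),
    )
    if include_traces:
        return table, truth, traces
    return table, truth


def recovery_scenario_config(
    n_subjects: int = 500,
    n_true: int = 20,
    p_markers: int = 40,
    loading: float = 0.5,
    seed: int = 0,
) -> tuple[CohortConfig, list[tuple[str, str]]]:
    """Planted-edge scenario for network recovery tests.

    Only the capacity variables are severity-linked; ``n_true`` markers
    carry an explicit severity loading with block structure and block-factor
    coupling switched (almost) off, so exactly the ``n_true``
    (marker, capacity) dependencies are planted.  Marker-marker correlations
    stay well below the marker-capacity correlations, so DPI prunes the
    indirect marker-marker edges rather than the planted ones (a hub with
    near-duplicate category nodes would instead be pruned by the DPI rule).

    Returns the config plus the list of true (marker, category) edges.
    """
    sizes = (p_markers // 3, p_markers // 3, p_markers - 2 * (p_markers // 3))
    lam = np.zeros(p_markers)
    lam[:n_true] = loading
    cfg = CohortConfig(
        n_hf=n_subjects, n_ctrl=0, p_markers=p_markers, cluster_sizes=sizes,
        within_corr=0.05, between_corr=0.0, block_link=0.0,
        factor_sev_corr=0.9, marker_sev_loading=lam,
        effect_profile=np.ones(p_markers),
        severity_link={
            **{k: 0.0 for k in PHYSIO_NAMES},
            "vo2peak": -0.85, "map": -0.85, "heart_rate": 0.85,
        },
        seed=seed,
    )
    names = marker_names(p_markers)
    true_edges = [(names[j], "capacity") for j in range(n_true)]
    return cfg, true_edges
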