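"""Cox proportional-hazards modeling and survival summaries.

From-scratch Newton-Raphson maximization of the Efron-tie partial
likelihood with step-halving, per-quartile hazard-ratio tables (crude and
covariate-adjusted, BH-FDR across markers), Kaplan-Meier product-limit
curves with Greenwood variance, and PC-score/quadrant risk contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import bh_fdr

__all__ = [
    "CoxFit",
    "fit_cox",
    "quartile_encode",
    "hr_table",
    "kaplan_meier",
    "pc_risk",
]


@dataclass
class CoxFit:
    """Fitted Cox model: coefficients, SEs, HRs with 95% CIs, diagnostics."""

    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    hr_low: np.ndarray
    hr_high: np.ndarray
    p: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    warnings: list[str] = field(default_factory=list)
    names: list[str] | None = None

    def summary(self) -> pd.DataFrame:
        idx = self.names or [f"x{j}" for j in range(len(self.beta))]
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se,
                "hr": self.hr,
                "hr_low": self.hr_low,
                "hr_high": self.hr_high,
                "p": self.p,
            },
            index=idx,
        )


def _efron_loglik_grad_hess(
    beta: np.ndarray, x: np.ndarray, time: np.ndarray, event: np.ndarray
):
    """Efron-tie partial log-likelihood with gradient and Hessian.

    Subjects are processed in decreasing-time order, accumulating risk-set
    sums; ties at each event time use the Efron correction.
    """
    n, p = x.shape
    order = np.argsort(-time, kind="stable")
    xs, ts, es = x[order], time[order], event[order]
    eta = xs @ beta
    # guard against overflow in degenerate (monotone-likelihood) directions
    w = np.exp(np.clip(eta, -500, 500))
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t_cur = ts[i]
        j = i
        while j < n and ts[j] == t_cur:
            j += 1
        # add the whole tied block to the risk set
        for idx in range(i, j):
            wi = w[idx]
            s0 += wi
            s1 += wi * xs[idx]
            s2 += wi * np.outer(xs[idx], xs[idx])
        deaths = [idx for idx in range(i, j) if es[idx] == 1]
        d = len(deaths)
        if d:
            d0 = sum(w[idx] for idx in deaths)
            d1 = np.sum([w[idx] * xs[idx] for idx in deaths], axis=0)
            d2 = np.sum(
                [w[idx] * np.outer(xs[idx], xs[idx]) for idx in deaths], axis=0
            )
            for r in range(d):
                f = r / d
                z0 = s0 - f * d0
                z1 = s1 - f * d1
                z2 = s2 - f * d2
                ll += float(eta[deaths[r]]) - np.log(z0)
                grad += xs[deaths[r]] - z1 / z0
                hess -= z2 / z0 - np.outer(z1, z1) / (z0 * z0)
        i = j
    return ll, grad, hess


def fit_cox(
    time,
    event,
    covariates,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-9,
    names: list[str] | None = None,
) -> CoxFit:
    """Newton-Raphson Cox fit with Efron tie handling and step-halving.

    Convergence when ``max|delta beta| < tol``; standard errors from the
    inverse observed information.  Monotone (perfectly separating) or flat
    likelihoods are flagged in ``warnings`` rather than returned silently.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is implemented")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if isinstance(covariates, pd.DataFrame):
        names = names or list(covariates.columns)
        x = covariates.to_numpy(dtype=float)
    else:
        x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates must be finite")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    sds = x.std(axis=0)
    if np.any(sds == 0):
        bad = [
            (names[j] if names else f"x{j}") for j in np.flatnonzero(sds == 0)
        ]
        raise ValueError(f"constant covariate(s): {', '.join(bad)}")

    p = x.shape[1]
    beta = np.zeros(p)
    warnings: list[str] = []
    ll, grad, hess = _efron_loglik_grad_hess(beta, x, time, event)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            warnings.append("flat likelihood: singular information matrix")
            break
        # step-halving on log-likelihood decrease
        factor = 1.0
        for _ in range(30):
            beta_new = beta + factor * step
            ll_new, grad_new, hess_new = _efron_loglik_grad_hess(
                beta_new, x, time, event
            )
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        delta = np.max(np.abs(beta_new - beta))
        beta, ll, grad, hess = beta_new, ll_new, grad_new, hess_new
        if delta < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 20:
        warnings.append(
            "monotone likelihood suspected: |beta| diverging (possible "
            "perfect separation in risk sets)"
        )
        converged = False
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        warnings.append("information matrix not invertible")
    z = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pval = 2.0 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        return CoxFit(
            beta=beta,
            se=se,
            hr=np.exp(beta),
            hr_low=np.exp(beta - 1.96 * se),
            hr_high=np.exp(beta + 1.96 * se),
            p=pval,
            loglik=float(ll),
            iterations=it,
            converged=converged,
            warnings=warnings,
            names=names,
        )


def quartile_encode(values, log_transform: bool = True) -> np.ndarray:
    """Ordinal quartile code 1..4 per subject (type-7 quantiles, ties down).

    Values are log2-transformed before quantiling by default (rank-
    invariant, so codes are unchanged; retained for interface parity with
    the analysis scale).
    """
    v = np.asarray(values, dtype=float)
    if len(np.unique(v)) < 4:
        raise ValueError("quartile coding needs at least 4 distinct values")
    if log_transform:
        if np.any(v <= 0):
            raise ValueError("log2 quartile coding needs positive values")
        v = np.log2(v)
    q25, q50, q75 = np.quantile(v, [0.25, 0.5, 0.75])
    return (1 + (v > q25).astype(int) + (v > q50) + (v > q75)).astype(int)


DEFAULT_ADJUSTMENT = ("age", "egfr", "vo2peak", "lvef")
ALTERNATE_ADJUSTMENT = ("age", "sex_male", "log2_ntprobnp")


def hr_table(
    markers: pd.DataFrame,
    time,
    event,
    adjust: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-marker crude and adjusted per-quartile hazard ratios.

    Markers are log2-transformed and quartile-coded (ordinal 1..4, entered
    linearly).  The crude model has the quartile code alone; the adjusted
    model adds the supplied covariate frame.  BH-FDR is applied across
    markers separately within each model family.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if adjust is not None:
        missing = [c for c in adjust.columns if adjust[c].isna().any()]
        if missing:
            raise ValueError(f"adjustment covariate(s) with missing values: {missing}")
    rows = []
    for m in markers.columns:
        q = quartile_encode(markers[m].to_numpy()).astype(float)
        crude = fit_cox(time, event, q[:, None], names=["quartile"])
        row = {
            "marker": m,
            "crude_hr": crude.hr[0],
            "crude_p": crude.p[0],
        }
        if adjust is not None:
            xmat = np.column_stack([q, adjust.to_numpy(dtype=float)])
            adj = fit_cox(
                time, event, xmat, names=["quartile", *adjust.columns]
            )
            row["adj_hr"] = adj.hr[0]
            row["adj_p"] = adj.p[0]
        rows.append(row)
    out = pd.DataFrame(rows).set_index("marker")
    out["crude_q"] = bh_fdr(out["crude_p"].to_numpy())
    if "adj_p" in out:
        out["adj_q"] = bh_fdr(out["adj_p"].to_numpy())
    out["crude_significant"] = out["crude_q"] < alpha
    return out


def kaplan_meier(time, event, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group with Greenwood 95% CIs.

    Returns a frame per group with columns time, n_at_risk, n_events,
    survival, ci_low, ci_high, including censoring-mark rows (n_events=0).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if groups is None:
        groups = np.repeat("all", len(time))
    groups = np.asarray(groups)
    out = {}
    for g in pd.unique(groups):
        sel = groups == g
        t, e = time[sel], event[sel]
        if len(t) == 0:
            raise ValueError(f"empty group {g!r}")
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        uniq = np.unique(t)
        rows = []
        surv = 1.0
        greenwood = 0.0
        for ut in uniq:
            at_risk = int(np.sum(t >= ut))
            d = int(np.sum((t == ut) & (e == 1)))
            if d > 0:
                surv *= 1.0 - d / at_risk
                if at_risk > d:
                    greenwood += d / (at_risk * (at_risk - d))
            se = surv * np.sqrt(greenwood)
            rows.append(
                (ut, at_risk, d, surv, max(surv - 1.96 * se, 0.0),
                 min(surv + 1.96 * se, 1.0))
            )
        out[str(g)] = pd.DataFrame(
            rows,
            columns=["time", "n_at_risk", "n_events", "survival", "ci_low", "ci_high"],
        )
    return out


def km_median(km: pd.DataFrame) -> float:
    """Median survival time from a Kaplan-Meier frame (NaN if not reached)."""
    below = km[km["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("nan")


def pc_risk(
    scores: pd.DataFrame,
    time,
    event,
    pc1_col: str = "PC1",
    pc2_col: str = "PC2",
) -> pd.DataFrame:
    """HRs for low-vs-high median splits of PC1/PC2 and quadrant contrasts.

    Scores are oriented so higher = better function; indicators are coded 1
    for the low (worse) side, so HRs > 1 mean excess risk.  Quadrant
    contrasts use the best-function quadrant (UR) as reference; empty or
    event-free contrasts are dropped with a warning row.
    """
    from .pca_summary import quadrant_groups

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    pc1 = scores[pc1_col].to_numpy(dtype=float)
    pc2 = scores[pc2_col].to_numpy(dtype=float)
    quads = quadrant_groups(pc1, pc2)
    rows = []
    for label, indicator in (
        ("PC1_low_vs_high", (~quads["pc1_high"]).astype(float).to_numpy()),
        ("PC2_low_vs_high", (~quads["pc2_high"]).astype(float).to_numpy()),
    ):
        fit = fit_cox(time, event, indicator[:, None], names=[label])
        rows.append(
            {
                "contrast": label, "hr": fit.hr[0], "hr_low": fit.hr_low[0],
                "hr_high": fit.hr_high[0], "p": fit.p[0], "note": "",
            }
        )
    quad = quads["quadrant"].to_numpy()
    for q in ("LL", "LR", "UL"):
        sel = (quad == q) | (quad == "UR")
        if not np.any(quad == q) or event[quad == q].sum() + event[quad == "UR"].sum() == 0:
            rows.append(
                {
                    "contrast": f"{q}_vs_UR", "hr": np.nan, "hr_low": np.nan,
                    "hr_high": np.nan, "p": np.nan,
                    "note": "dropped: empty or event-free contrast",
                }
            )
            continue
        indicator = (quad[sel] == q).astype(float)
        fit = fit_cox(time[sel], event[sel], indicator[:, None], names=[q])
        rows.append(
            {
                "contrast": f"{q}_vs_UR", "hr": fit.hr[0], "hr_low": fit.hr_low[0],
                "hr_high": fit.hr_high[0], "p": fit.p[0],
                "note": "; ".join(fit.warnings),
            }
        )
    return pd.DataFrame(rows).set_index("contrast")
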