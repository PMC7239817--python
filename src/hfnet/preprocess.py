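"""Shared statistics and data preparation.

Scaling, the Cockcroft-Gault renal formula, Bland-Altman method agreement,
univariate case/control screening on log2 marker values with
Benjamini-Hochberg FDR, pairwise correlation structure with a 3-cluster
average-linkage cut, and Table-1-style cohort description.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "scale_unit_variance",
    "cockcroft_gault",
    "bland_altman",
    "AgreementResult",
    "univariate_screen",
    "bh_fdr",
    "correlation_structure",
    "CorrelationStructure",
    "describe_cohort",
]


def scale_unit_variance(matrix) -> np.ndarray | pd.DataFrame:
    """Center each column to mean 0 and scale to sample SD 1 (ddof=1).

    Raises
    ------
    ValueError
        Naming the offending column if any column has zero variance.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    x = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    sd = x.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sd > 0))
    if bad.size:
        names = (
            [str(matrix.columns[i]) for i in bad] if is_df else [str(i) for i in bad]
        )
        raise ValueError(f"zero-variance column(s): {', '.join(names)}")
    out = (x - x.mean(axis=0)) / sd
    if is_df:
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def cockcroft_gault(
    age_y: float, weight_kg: float, sex: str, creatinine_mg_dl: float
) -> float:
    """Creatinine clearance (mL/min): ((140-age)*weight)/(72*crea), x0.85 if female."""
    if creatinine_mg_dl <= 0:
        raise ValueError("creatinine must be positive")
    if age_y >= 140:
        raise ValueError("age must be below 140 for the formula to be positive")
    crcl = (140.0 - age_y) * weight_kg / (72.0 * creatinine_mg_dl)
    if str(sex).lower().startswith("f"):
        crcl *= 0.85
    return float(crcl)


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement between two measurement methods."""

    bias: float
    loa_low: float
    loa_high: float
    r2: float
    max_abs_diff_sd: float
    n: int


def bland_altman(x, y, standardize: bool = False) -> AgreementResult:
    """Bland-Altman bias and 1.96-SD limits of agreement for paired values.

    With ``standardize=True`` both vectors are unit-scaled first so the bias
    and limits are in SD units of the respective methods.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("Bland-Altman requires n >= 3 pairs")
    if standardize:
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    pooled_sd = float(np.concatenate([x, y]).std(ddof=1))
    r = np.corrcoef(x, y)[0, 1] if x.std() > 0 and y.std() > 0 else np.nan
    max_ratio = float(np.abs(diff).max() / pooled_sd) if pooled_sd > 0 else 0.0
    return AgreementResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        r2=float(r ** 2),
        max_abs_diff_sd=max_ratio,
        n=len(x),
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def univariate_screen(
    markers: pd.DataFrame, groups, alpha: float = 0.05, equal_var: bool = False
) -> pd.DataFrame:
    """Per-marker two-sided t test of HF vs control on log2 values.

    Returns a frame indexed by marker with the linear-scale group-mean ratio,
    t statistic, raw p, BH q and a ``significant`` flag at ``q < alpha``.
    Welch's unequal-variance t test is the default.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {list(labels)}")
    # HF (or first label) is the numerator of the ratio
    g1 = "HF" if "HF" in labels else labels[0]
    g2 = [l for l in labels if l != g1][0]
    a = markers.loc[groups == g1]
    b = markers.loc[groups == g2]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    la, lb = np.log2(a.to_numpy(dtype=float)), np.log2(b.to_numpy(dtype=float))
    t, p = sps.ttest_ind(la, lb, axis=0, equal_var=equal_var)
    ratio = a.mean(axis=0) / b.mean(axis=0)
    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "ratio": ratio.to_numpy(),
            "t": t,
            "p": p,
            "q": q,
            "significant": q < alpha,
        },
        index=markers.columns,
    )
    return out


@dataclass(frozen=True)
class CorrelationStructure:
    """Pairwise correlation matrix with a k=3 hierarchical clustering cut."""

    corr: pd.DataFrame
    labels: pd.Series       # cluster id (1..3) per variable
    leaf_order: list[str]   # dendrogram leaf ordering for heatmaps
    mean_offdiag_r: float
    mean_offdiag_abs_r: float


def correlation_structure(markers: pd.DataFrame, k: int = 3) -> CorrelationStructure:
    """Pearson correlation matrix + average-linkage clustering on 1 - r."""
    x = markers.to_numpy(dtype=float)
    if x.shape[1] < 3 or x.shape[0] < 3:
        raise ValueError("need at least 3 variables and 3 observations")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [str(markers.columns[i]) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant marker(s): {', '.join(bad)}")
    corr = np.corrcoef(x, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.average(squareform(dist, checks=False))
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    leaves = hierarchy.leaves_list(linkage)
    off = corr[~np.eye(len(corr), dtype=bool)]
    return CorrelationStructure(
        corr=pd.DataFrame(corr, index=markers.columns, columns=markers.columns),
        labels=pd.Series(labels, index=markers.columns),
        leaf_order=[str(markers.columns[i]) for i in leaves],
        mean_offdiag_r=float(off.mean()),
        mean_offdiag_abs_r=float(np.abs(off).mean()),
    )


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    # type-7 (linear interpolation) quantiles
    return tuple(np.quantile(x, [0.5, 0.25, 0.75]))


def describe_cohort(
    table: pd.DataFrame,
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Table-1-style summary: median (Q1; Q3) per group plus a group test.

    Continuous variables get a Welch t test, categorical variables a
    Chi-square test of the group x level contingency table.
    """
    if group_col not in table.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = pd.unique(table[group_col])
    if continuous is None:
        continuous = [
            c for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    if categorical is None:
        categorical = []
    rows = []
    for var in continuous:
        entry = {"variable": var, "kind": "continuous"}
        samples = []
        for g in groups:
            x = table.loc[table[group_col] == g, var].dropna().to_numpy(dtype=float)
            med, q1, q3 = _quartiles(x) if len(x) else (np.nan,) * 3
            entry[str(g)] = f"{med:.6g} ({q1:.6g}; {q3:.6g})"
            samples.append(x)
        if len(groups) == 2 and all(len(s) > 1 for s in samples):
            entry["p"] = float(sps.ttest_ind(samples[0], samples[1], equal_var=False).pvalue)
        else:
            entry["p"] = np.nan
        rows.append(entry)
    for var in categorical:
        entry = {"variable": var, "kind": "categorical"}
        ct = pd.crosstab(table[group_col], table[var])
        for g in groups:
            counts = ct.loc[g] if g in ct.index else None
            if counts is not None:
                total = counts.sum()
                entry[str(g)] = "; ".join(
                    f"{lvl}: {c} ({100 * c / total:.0f}%)" for lvl, c in counts.items()
                )
        try:
            entry["p"] = float(sps.chi2_contingency(ct.to_numpy())[1])
        except ValueError:
            entry["p"] = np.nan
        rows.append(entry)
    return pd.DataFrame(rows).set_index("variable")
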