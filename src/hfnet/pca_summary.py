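"""Principal-component summary scores for clinical variable blocks.

PCA is performed on the correlation matrix (variables scaled to unit
variance and mean-centered).  Each analysis category (physical capacity,
daily physical activity, myocardial function) is summarized by its first
two component scores, oriented so that a higher PC1 means better function;
the combined scores feed median-split quadrant risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import scale_unit_variance

__all__ = [
    "PcaSummary",
    "fit_pca",
    "category_scores",
    "quadrant_groups",
    "DEFAULT_CATEGORY_MAP",
    "ORIENTATION_ANCHORS",
]

#: variables whose loading sign anchors the "higher = better function"
#: orientation of each category's PC1
ORIENTATION_ANCHORS = {
    "capacity": "vo2peak",
    "activity": "pct_active",
    "myocardial": "lvef",
}

DEFAULT_CATEGORY_MAP: dict[str, list[str]] = {
    "capacity": ["vo2peak", "map", "heart_rate"],
    "activity": ["pct_active", "pct_inactive", "skewness_cpm"],
    "myocardial": [
        "lvef", "psv", "lvedd", "tapse", "septal_e", "lateral_e",
        "e_over_e", "la_area", "pa_pressure",
    ],
}


@dataclass(frozen=True)
class PcaSummary:
    """PCA of a (scaled) variable block.

    ``loadings`` columns are orthonormal eigenvectors of the correlation
    matrix; ``scores = scaled_data @ loadings``; ``var_ratio`` is the
    non-increasing per-component explained-variance fraction summing to 1.
    """

    loadings: pd.DataFrame   # variable x component
    scores: pd.DataFrame     # subject x component
    var_ratio: np.ndarray
    category: str = "combined"

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pca(x: pd.DataFrame, category: str = "combined") -> PcaSummary:
    """Eigen-decomposition of the correlation matrix of ``x``.

    Sign convention: within each component, the largest-|loading| element is
    made positive, so results are deterministic across solvers.
    """
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    xs = scale_unit_variance(x)  # raises on constant columns
    arr = xs.to_numpy(dtype=float)
    n = arr.shape[0]
    # SVD of the scaled data == eigendecomposition of the correlation matrix
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    eigvals = s ** 2 / (n - 1)
    loadings = vt.T
    for j in range(loadings.shape[1]):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
    scores = arr @ loadings
    comps = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    return PcaSummary(
        loadings=pd.DataFrame(loadings, index=x.columns, columns=comps),
        scores=pd.DataFrame(scores, index=x.index, columns=comps),
        var_ratio=eigvals / eigvals.sum(),
        category=category,
    )


def category_scores(
    table: pd.DataFrame,
    category_map: dict[str, list[str]] | None = None,
    n_components: int = 2,
) -> tuple[pd.DataFrame, dict[str, PcaSummary]]:
    """Per-subject PC1/PC2 summary scores for each analysis category.

    Each category's PCA is fit on its own variable block; PC1 is oriented so
    a higher score means better function (positive loading on the category's
    anchor variable: VO2peak, % active, LVEF).

    Returns
    -------
    scores : DataFrame with columns ``<category>_PC1`` .. ``_PC{n}``.
    models : the fitted per-category :class:`PcaSummary` objects.
    """
    if category_map is None:
        category_map = DEFAULT_CATEGORY_MAP
    for cat, cols in category_map.items():
        if len(cols) < 2:
            raise ValueError(f"category {cat!r} needs at least 2 variables")
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"category {cat!r}: missing variable(s) {missing}")
    seen: dict[str, str] = {}
    for cat, cols in category_map.items():
        for c in cols:
            if c in seen:
                raise ValueError(f"variable {c!r} assigned to both {seen[c]!r} and {cat!r}")
            seen[c] = cat

    out = {}
    models = {}
    for cat, cols in category_map.items():
        fit = fit_pca(table[cols], category=cat)
        anchor = ORIENTATION_ANCHORS.get(cat)
        load = fit.loadings.copy()
        scores = fit.scores.copy()
        if anchor in load.index and load.loc[anchor, "PC1"] < 0:
            load["PC1"] *= -1.0
            scores["PC1"] *= -1.0
            fit = PcaSummary(load, scores, fit.var_ratio, cat)
        models[cat] = fit
        for i in range(min(n_components, fit.n_components)):
            out[f"{cat}_PC{i + 1}"] = fit.scores[f"PC{i + 1}"].to_numpy()
    return pd.DataFrame(out, index=table.index), models


def quadrant_groups(pc1_scores, pc2_scores) -> pd.DataFrame:
    """Median-split quadrant labels from two score vectors.

    Quadrants are labeled LL/LR/UL/UR (left/right = PC1 below/above its
    median, lower/upper = PC2).  With scores oriented so higher = better
    function, LL is the highest-risk and UR the lowest-risk group.
    """
    pc1 = np.asarray(pc1_scores, dtype=float)
    pc2 = np.asarray(pc2_scores, dtype=float)
    if pc1.shape != pc2.shape:
        raise ValueError("score vectors must have equal length")
    hi1 = pc1 > np.median(pc1)
    hi2 = pc2 > np.median(pc2)
    labels = np.where(
        hi1, np.where(hi2, "UR", "LR"), np.where(hi2, "UL", "LL")
    )
    return pd.DataFrame(
        {"pc1_high": hi1, "pc2_high": hi2, "quadrant": labels}
    )
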