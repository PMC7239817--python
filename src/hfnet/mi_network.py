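"""Mutual-information association network with DPI pruning.

Pipeline: plug-in MI on rank (empirical-copula) transformed, equal-frequency
binned variable pairs; per-pair permutation significance with seeded
streams; BH-FDR across pairs; data-processing-inequality triangle pruning;
bootstrap Pearson-correlation filtering (|r| > 0.2 and FDR < 5%); and a
factor-connectivity summary over the category summary-score nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_seed
from .preprocess import bh_fdr

__all__ = [
    "mutual_info",
    "permutation_test",
    "infer_candidate_edges",
    "apply_dpi",
    "bootstrap_corr_filter",
    "MiNetwork",
    "build_network",
    "connectivity_summary",
    "ConnectivityReport",
    "export_graph",
    "CATEGORY_SCORE_NODES",
]

CATEGORY_SCORE_NODES = {
    "capacity": ("capacity_PC1", "capacity_PC2"),
    "activity": ("activity_PC1", "activity_PC2"),
    "myocardial": ("myocardial_PC1", "myocardial_PC2"),
}


def _n_bins(n: int) -> int:
    return int(np.clip(round(n ** (1.0 / 3.0)), 3, 10))


def _bin_codes(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin index per observation via stable rank transform."""
    n = len(x)
    ranks = np.argsort(np.argsort(x, kind="stable"), kind="stable")
    return (ranks * bins) // n


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray, bins: int) -> float:
    joint = np.bincount(cx * bins + cy, minlength=bins * bins).astype(float)
    joint /= joint.sum()
    px = joint.reshape(bins, bins).sum(axis=1)
    py = joint.reshape(bins, bins).sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py).ravel()
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def _perm_pvalue(
    cx: np.ndarray, cy: np.ndarray, bins: int, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Vectorized permutation p for MI of pre-binned codes.

    Marginals are invariant under permutation, so only the joint histogram
    is recomputed per replicate (all replicates batched).
    """
    n = len(cx)
    mi_obs = _mi_from_codes(cx, cy, bins)
    perm_cy = rng.permuted(np.broadcast_to(cy, (n_perm, n)), axis=1)
    flat = cx[None, :] * bins + perm_cy  # (B, n)
    joint = np.zeros((n_perm, bins * bins))
    np.add.at(joint, (np.repeat(np.arange(n_perm), n), flat.ravel()), 1.0)
    joint /= n
    px = np.bincount(cx, minlength=bins) / n
    py = np.bincount(cy, minlength=bins) / n
    outer = np.outer(px, py).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / outer[None, :])
    mi_perm = np.nansum(np.where(joint > 0, terms, 0.0), axis=1)
    exceed = int(np.sum(mi_perm >= mi_obs - 1e-15))
    return mi_obs, (1.0 + exceed) / (n_perm + 1.0)


def mutual_info(x, y, bins: int | None = None) -> float:
    """Plug-in mutual information (nats) of two variables.

    Both variables are rank-transformed and discretized into
    ``clamp(round(n^(1/3)), 3, 10)`` equal-frequency bins (ties broken by
    stable rank order), making the estimate exactly invariant under strictly
    increasing transforms of either variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 20:
        raise ValueError("mutual information needs n >= 20")
    b = bins if bins is not None else _n_bins(n)
    return _mi_from_codes(_bin_codes(x, b), _bin_codes(y, b), b)


def permutation_test(
    x, y, n_perm: int = 1000, seed: int = 0, bins: int | None = None
) -> tuple[float, float]:
    """Permutation p-value for MI(x, y): ``p = (1 + #{MI_perm >= MI_obs}) / (B + 1)``.

    Returns ``(mi_observed, p)``.  Permutations only reshuffle the bin codes
    of ``y`` (marginals are permutation-invariant), with a seeded generator.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    b = bins if bins is not None else _n_bins(n)
    cx = _bin_codes(x, b)
    cy = _bin_codes(y, b)
    rng = np.random.default_rng(seed)
    return _perm_pvalue(cx, cy, b, n_perm, rng)


def infer_candidate_edges(
    data: pd.DataFrame,
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Test all variable pairs; BH across pairs; candidate iff ``q < fdr``.

    Each pair gets its own seeded permutation stream (stable under pair
    reordering), so a fixed cohort and seed give an identical edge list.
    """
    cols = list(data.columns)
    if len(cols) < 3:
        raise ValueError("need at least 3 nodes")
    arr = data.to_numpy(dtype=float)
    n = arr.shape[0]
    b = _n_bins(n)
    codes = np.column_stack([_bin_codes(arr[:, j], b) for j in range(arr.shape[1])])
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            pair_seed = child_seed(seed, f"mi:{cols[i]}|{cols[j]}")
            rng = np.random.default_rng(pair_seed)
            mi_obs, p = _perm_pvalue(codes[:, i], codes[:, j], b, n_perm, rng)
            rows.append((cols[i], cols[j], mi_obs, p))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "mi", "perm_p"])
    edges["bh_q"] = bh_fdr(edges["perm_p"].to_numpy())
    edges["candidate"] = edges["bh_q"] < fdr
    return edges


def apply_dpi(edges: pd.DataFrame, tolerance: float = 0.15) -> pd.DataFrame:
    """Data-processing-inequality pruning of candidate edges.

    For every fully connected candidate triangle the weakest edge is marked
    removed if ``MI_weak < min(other two) * (1 - tolerance)``.  Removal is
    simultaneous: all triangles are evaluated on the original MI values.
    """
    edges = edges.copy()
    cand = edges[edges["candidate"]]
    mi_map = {
        frozenset((a, b)): m
        for a, b, m in zip(cand["node_a"], cand["node_b"], cand["mi"])
    }
    neighbors: dict[str, set[str]] = {}
    for a, b in zip(cand["node_a"], cand["node_b"]):
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    removed: set[frozenset] = set()
    nodes = sorted(neighbors)
    for a in nodes:
        for b in (x for x in neighbors[a] if x > a):
            common = neighbors[a] & neighbors[b]
            for c in (x for x in common if x > b):
                trio = [
                    (mi_map[frozenset((a, b))], frozenset((a, b))),
                    (mi_map[frozenset((a, c))], frozenset((a, c))),
                    (mi_map[frozenset((b, c))], frozenset((b, c))),
                ]
                trio.sort()
                if trio[0][0] < trio[1][0] * (1.0 - tolerance):
                    removed.add(trio[0][1])
    key = [frozenset((a, b)) for a, b in zip(edges["node_a"], edges["node_b"])]
    edges["dpi_removed"] = [k in removed for k in key]
    edges["dpi_pass"] = edges["candidate"] & ~edges["dpi_removed"]
    return edges


def bootstrap_corr_filter(
    edges: pd.DataFrame,
    data: pd.DataFrame,
    n_boot: int = 1000,
    r_threshold: float = 0.2,
    fdr: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Final retention: Pearson |r| > threshold and correlation-test FDR < 5%.

    Per surviving edge: Pearson r, subject-bootstrap percentile 95% CI for
    r, two-sided correlation-test p, BH across the surviving edges.
    """
    from scipy import stats as sps

    edges = edges.copy()
    n = len(data)
    arr = data.to_numpy(dtype=float)
    col = {c: i for i, c in enumerate(data.columns)}
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))

    r_vals = np.full(len(edges), np.nan)
    r_lo = np.full(len(edges), np.nan)
    r_hi = np.full(len(edges), np.nan)
    p_vals = np.full(len(edges), np.nan)
    surviving = edges.index[edges["dpi_pass"]]
    for i in surviving:
        xa = arr[:, col[edges.at[i, "node_a"]]]
        xb = arr[:, col[edges.at[i, "node_b"]]]
        res = sps.pearsonr(xa, xb)
        r_vals[edges.index.get_loc(i)] = res.statistic
        p_vals[edges.index.get_loc(i)] = res.pvalue
        rb = np.array([
            np.corrcoef(xa[idx], xb[idx])[0, 1] for idx in boot_idx
        ])
        r_lo[edges.index.get_loc(i)] = np.nanpercentile(rb, 2.5)
        r_hi[edges.index.get_loc(i)] = np.nanpercentile(rb, 97.5)
    edges["pearson_r"] = r_vals
    edges["r_lo"] = r_lo
    edges["r_hi"] = r_hi
    edges["corr_p"] = p_vals
    q = np.full(len(edges), np.nan)
    mask = edges["dpi_pass"].to_numpy()
    if mask.any():
        q[mask] = bh_fdr(p_vals[mask])
    edges["corr_q"] = q
    edges["retained"] = mask & (np.abs(r_vals) > r_threshold) & (q < fdr)
    reason = np.where(
        ~edges["candidate"], "fdr",
        np.where(edges["dpi_removed"], "dpi",
                 np.where(~edges["retained"], "corr_filter", "none")),
    )
    edges["removal_reason"] = reason
    return edges


@dataclass
class MiNetwork:
    """Node table + undirected edge table of the inferred network."""

    nodes: pd.DataFrame  # index: node name; column: type (marker|category_score)
    edges: pd.DataFrame  # full per-pair table with retention flags

    @property
    def retained_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["retained"].astype(bool)]


def build_network(
    markers: pd.DataFrame,
    category_scores: pd.DataFrame,
    n_perm: int = 1000,
    n_boot: int = 1000,
    fdr: float = 0.05,
    r_threshold: float = 0.2,
    dpi_tolerance: float = 0.15,
    seed: int = 0,
    log_markers: bool = True,
) -> MiNetwork:
    """Run the full inference chain on markers + category summary scores."""
    mk = np.log2(markers) if log_markers else markers
    data = pd.concat([mk, category_scores], axis=1)
    edges = infer_candidate_edges(data, n_perm=n_perm, fdr=fdr, seed=seed)
    edges = apply_dpi(edges, tolerance=dpi_tolerance)
    edges = bootstrap_corr_filter(
        edges, data, n_boot=n_boot, r_threshold=r_threshold, fdr=fdr, seed=seed
    )
    nodes = pd.DataFrame(
        {
            "type": ["marker"] * markers.shape[1]
            + ["category_score"] * category_scores.shape[1]
        },
        index=list(markers.columns) + list(category_scores.columns),
    )
    return MiNetwork(nodes=nodes, edges=edges)


@dataclass
class ConnectivityReport:
    """Per-factor degree and category linkage; key factors link all three."""

    per_factor: pd.DataFrame           # degree + one bool column per category
    key_factors: list[str]
    category_edge_counts: dict[str, int]


def connectivity_summary(network: MiNetwork) -> ConnectivityReport:
    """Category linkage of each marker in the final network.

    A marker links to a category iff it retains an edge to either of that
    category's two PC score nodes.  Edges among category score nodes are
    excluded from marker degrees and counts.
    """
    markers = [n for n, t in network.nodes["type"].items() if t == "marker"]
    score_to_cat = {
        node: cat for cat, nodes in CATEGORY_SCORE_NODES.items() for node in nodes
    }
    ret = network.retained_edges
    per = pd.DataFrame(
        {"degree": 0, **{c: False for c in CATEGORY_SCORE_NODES}},
        index=pd.Index(markers, name="factor"),
    )
    cat_counts = {c: 0 for c in CATEGORY_SCORE_NODES}
    for a, b in zip(ret["node_a"], ret["node_b"]):
        a_is_marker, b_is_marker = a in per.index, b in per.index
        if a_is_marker and b_is_marker:
            per.at[a, "degree"] += 1
            per.at[b, "degree"] += 1
        elif a_is_marker or b_is_marker:
            marker, other = (a, b) if a_is_marker else (b, a)
            per.at[marker, "degree"] += 1
            cat = score_to_cat.get(other)
            if cat:
                per.at[marker, cat] = True
                cat_counts[cat] += 1
    cats = list(CATEGORY_SCORE_NODES)
    per["n_categories"] = per[cats].sum(axis=1)
    key = sorted(per.index[per["n_categories"] == len(cats)])
    return ConnectivityReport(
        per_factor=per, key_factors=key, category_edge_counts=cat_counts
    )


def export_graph(network: MiNetwork, graphml_path, tsv_path=None) -> None:
    """Write the network as GraphML (nodes typed, edges attributed) + TSV."""
    import networkx as nx

    g = nx.Graph()
    for node, row in network.nodes.iterrows():
        g.add_node(node, type=row["type"])
    for _, e in network.edges[network.edges["candidate"]].iterrows():
        g.add_edge(
            e["node_a"], e["node_b"],
            mi=float(e["mi"]),
            perm_p=float(e["perm_p"]),
            bh_q=float(e["bh_q"]),
            r=float(e["pearson_r"]) if np.isfinite(e["pearson_r"]) else 0.0,
            retained=bool(e["retained"]),
            removal_reason=str(e["removal_reason"]),
        )
    nx.write_graphml(g, graphml_path)
    if tsv_path is not None:
        cols = [
            "node_a", "node_b", "mi", "perm_p", "bh_q", "pearson_r",
            "r_lo", "r_hi", "retained", "removal_reason",
        ]
        network.edges[cols].to_csv(tsv_path, sep="\t", index=False)
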