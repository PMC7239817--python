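"""End-to-end orchestration of the analysis stages.

simulate -> validate -> screen -> OPLS-DA -> category PCA -> MI network ->
survival, with a provenance manifest (input hashes, child seeds, stage
outputs) and full determinism under a fixed master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_seed
from . import cohortsim, oplsda, pca_summary, preprocess, mi_network, survival

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "load_cohort"]

MARKER_PREFIX = "marker_"


@dataclass
class RunConfig:
    """Pipeline configuration; all analysis thresholds are surfaced here."""

    out_dir: str = "hfnet_out"
    cohort_path: str | None = None     # TSV to load; None -> simulate
    simulate: bool = True
    master_seed: int = 0
    stages: tuple[str, ...] = (
        "simulate", "validate", "screen", "opls", "pca", "network", "survival",
    )
    fdr: float = 0.05
    r_threshold: float = 0.2
    vip_threshold: float = 0.8
    active_cpm: int = 100
    min_wear_days: float = 3.0
    dpi_tolerance: float = 0.15
    n_perm: int = 200
    n_boot: int = 200
    cv_folds: int = 7
    n_hf: int = 66
    n_ctrl: int = 28

    def __post_init__(self) -> None:
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if not (0 <= self.r_threshold < 1):
            raise ValueError("r_threshold must lie in [0, 1)")
        if self.min_wear_days < 0 or self.dpi_tolerance < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def marker_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith(MARKER_PREFIX)]


def validate_inputs(table: pd.DataFrame, p_markers: int | None = None) -> pd.DataFrame:
    """Structural validation of a cohort table.

    Returns a frame of findings (row number, column, message); raises on a
    malformed header (missing required columns).
    """
    required = {"id", "group", "time", "event"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"malformed cohort header: missing column(s) {sorted(missing)}")
    mcols = marker_columns(table)
    if p_markers is not None and len(mcols) != p_markers:
        raise ValueError(
            f"expected {p_markers} marker columns, found {len(mcols)}"
        )
    findings = []
    for i, row in table.iterrows():
        if row["group"] not in ("HF", "control"):
            findings.append((i, "group", f"unknown group label {row['group']!r}"))
        if not (row["time"] > 0):
            findings.append((i, "time", f"non-positive follow-up time {row['time']}"))
        if row["event"] not in (0, 1):
            findings.append((i, "event", f"event flag {row['event']!r} not in {{0,1}}"))
    vals = table[mcols].to_numpy(dtype=float) if mcols else np.empty((len(table), 0))
    bad = np.argwhere(~(vals > 0))
    for r, c in bad:
        findings.append((table.index[r], mcols[c], "non-positive marker abundance"))
    return pd.DataFrame(findings, columns=["row", "column", "finding"])


def load_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Every output file is recorded in ``manifest.json`` with its SHA-256, the
    stage's child seed, and stage-level counts; a failing stage halts the
    run with partial outputs retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": config.master_seed,
        "config": asdict(config),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path), "sha256": _sha256(path), "stage": stage,
        }

    def stage_info(stage: str, **kw) -> None:
        manifest["stages"][stage] = {
            "seed": child_seed(config.master_seed, stage), **kw,
        }

    table: pd.DataFrame | None = None
    truth = None

    if "simulate" in config.stages and config.simulate and config.cohort_path is None:
        sim_cfg = cohortsim.CohortConfig(
            n_hf=config.n_hf, n_ctrl=config.n_ctrl,
            seed=child_seed(config.master_seed, "simulate"),
        )
        table, truth = cohortsim.simulate_cohort(sim_cfg)
        path = out / "cohort.tsv"
        _write_tsv(table, path, index=False)
        record("simulate", "cohort", path)
        tpath = out / "ground_truth.json"
        with open(tpath, "w") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        record("simulate", "ground_truth", tpath)
        stage_info("simulate", n_subjects=len(table))
    elif config.cohort_path is not None:
        table = load_cohort(config.cohort_path)
        manifest["inputs"] = {
            "cohort": {"path": config.cohort_path, "sha256": _sha256(Path(config.cohort_path))}
        }
    if table is None:
        raise ValueError("no cohort: enable simulation or provide cohort_path")

    if "validate" in config.stages:
        findings = validate_inputs(table)
        vpath = out / "validation.tsv"
        _write_tsv(findings, vpath, index=False)
        record("validate", "validation", vpath)
        stage_info("validate", n_findings=len(findings))

    # activity-validity exclusion mirrors the < 3 wear-day rule
    if "activity_valid" in table.columns:
        analysis = table[table["activity_valid"].astype(bool)].reset_index(drop=True)
    else:
        analysis = table
    mcols = marker_columns(analysis)
    markers = analysis[mcols]
    groups = analysis["group"].to_numpy()
    is_hf = groups == "HF"

    screen = None
    if "screen" in config.stages:
        screen = preprocess.univariate_screen(markers, groups, alpha=config.fdr)
        spath = out / "screen.tsv"
        _write_tsv(screen, spath)
        record("screen", "screen", spath)
        stage_info("screen", n_significant=int(screen["significant"].sum()))

    opls_table = None
    if "opls" in config.stages:
        if is_hf.all() or not is_hf.any():
            raise ValueError("OPLS-DA requires both groups present")
        seed = child_seed(config.master_seed, "opls")
        q2, n_orth = oplsda.cross_validate(
            np.log2(markers), groups, folds=config.cv_folds, seed=seed
        )
        boot = oplsda.bootstrap_significance(
            np.log2(markers), groups, n_boot=max(config.n_boot, 200),
            n_orth=max(n_orth, 1), seed=seed,
        )
        model = oplsda.fit_opls(np.log2(markers), groups, n_orth=max(n_orth, 1))
        boot.index = mcols
        boot["vip_flag"] = boot["vip"] >= config.vip_threshold
        opath = out / "opls_variables.tsv"
        _write_tsv(boot, opath)
        record("opls", "opls_variables", opath)
        scores = pd.DataFrame(
            {"id": analysis["id"], "group": groups, "t": model.t}
        )
        spath2 = out / "opls_scores.tsv"
        _write_tsv(scores, spath2, index=False)
        record("opls", "opls_scores", spath2)
        stage_info(
            "opls", r2y=model.r2y, q2=q2, n_orth=n_orth,
            accuracy=model.accuracy,
            n_significant=int(boot["significant"].sum()),
        )
        opls_table = boot

    scores6 = None
    if "pca" in config.stages:
        hf_tab = analysis[is_hf]
        scores6, models = pca_summary.category_scores(hf_tab)
        ppath = out / "category_scores.tsv"
        _write_tsv(scores6.assign(id=hf_tab["id"].to_numpy()), ppath, index=False)
        record("pca", "category_scores", ppath)
        stage_info(
            "pca",
            var_ratio={c: [float(v) for v in m.var_ratio[:3]] for c, m in models.items()},
        )

    network = None
    if "network" in config.stages:
        if scores6 is None:
            raise ValueError("network stage requires the pca stage")
        hf_tab = analysis[is_hf]
        net = mi_network.build_network(
            hf_tab[mcols], scores6,
            n_perm=config.n_perm, n_boot=config.n_boot,
            fdr=config.fdr, r_threshold=config.r_threshold,
            dpi_tolerance=config.dpi_tolerance,
            seed=child_seed(config.master_seed, "network"),
        )
        conn = mi_network.connectivity_summary(net)
        gpath = out / "network.graphml"
        tpath = out / "network_edges.tsv"
        mi_network.export_graph(net, gpath, tpath)
        record("network", "network_graphml", gpath)
        record("network", "network_edges", tpath)
        cpath = out / "connectivity.tsv"
        _write_tsv(conn.per_factor, cpath)
        record("network", "connectivity", cpath)
        stage_info(
            "network",
            n_candidate=int(net.edges["candidate"].sum()),
            n_dpi_pass=int(net.edges["dpi_pass"].sum()),
            n_retained=int(net.edges["retained"].sum()),
            key_factors=conn.key_factors,
        )
        network = net

    if "survival" in config.stages:
        hf_tab = analysis[is_hf].reset_index(drop=True)
        adjust = pd.DataFrame(
            {
                "age": hf_tab["age"],
                "egfr": [
                    preprocess.cockcroft_gault(a, w, s, c)
                    for a, w, s, c in zip(
                        hf_tab["age"], hf_tab["weight"], hf_tab["sex"],
                        hf_tab["creatinine"],
                    )
                ],
                "vo2peak": hf_tab["vo2peak"],
                "lvef": hf_tab["lvef"],
            }
        )
        hrt = survival.hr_table(
            hf_tab[mcols], hf_tab["time"], hf_tab["event"], adjust=adjust,
            alpha=config.fdr,
        )
        hpath = out / "hr_table.tsv"
        _write_tsv(hrt, hpath)
        record("survival", "hr_table", hpath)
        km = survival.kaplan_meier(hf_tab["time"], hf_tab["event"])
        kpath = out / "km_hf.tsv"
        _write_tsv(km["all"], kpath, index=False)
        record("survival", "km_hf", kpath)
        info = {"n_events": int(hf_tab["event"].sum())}
        if scores6 is not None:
            risk = survival.pc_risk(
                scores6.rename(
                    columns={"capacity_PC1": "PC1", "capacity_PC2": "PC2"}
                ),
                hf_tab["time"], hf_tab["event"],
            )
            rpath = out / "pc_risk.tsv"
            _write_tsv(risk, rpath)
            record("survival", "pc_risk", rpath)
        stage_info("survival", **info)

    # qualitative funnel: discriminating >= key network >= prognostic factors
    if opls_table is not None and network is not None and "survival" in config.stages:
        discriminating = set(opls_table.index[opls_table["significant"]])
        conn = mi_network.connectivity_summary(network)
        key = set(conn.key_factors) & discriminating
        hf_tab = analysis[is_hf].reset_index(drop=True)
        prognostic = set()
        if key:
            sub = survival.hr_table(
                hf_tab[sorted(key)], hf_tab["time"], hf_tab["event"],
                alpha=config.fdr,
            )
            prognostic = set(sub.index[sub["crude_significant"]])
        manifest["funnel"] = {
            "discriminating": sorted(discriminating),
            "key_discriminating": sorted(key),
            "prognostic": sorted(prognostic),
        }

    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest
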