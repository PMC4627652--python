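"""End-to-end study orchestration.

`run_study` drives the whole analysis from a subject manifest (or an
in-memory synthetic cohort): connectivity construction, the sparsity sweep,
global/nodal metrics with optional degree-preserving null normalization,
AUC summarization, covariate-adjusted permutation inference with FDR,
betweenness hub detection, module decomposition and clinical correlation.

Reproducibility: a single master seed is fanned out to per-subject null
streams and per-test permutation streams via name-keyed seed sequences, so
results are bit-identical across runs and independent of evaluation order
(disabling one analysis never shifts another's stream).
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .graph_metrics import (
    GlobalMetrics,
    betweenness,
    local_efficiency,
    modularity_q,
    newman_partition,
    nodal_degree,
    nodal_efficiency,
)
from .group_inference import (
    auc,
    clinical_correlation,
    fdr_correct,
    hub_sign_test,
    mean_group_network,
    per_threshold_ttest,
    permutation_test,
    residualize,
)
from .net_build import SparsityGrid, binarize_at_sparsity, check_min_sparsity, compute_connectivity, sweep
from .null_models import normalize, null_efficiencies
from .synthetic_data import Cohort

__all__ = ["RunConfig", "StudyResult", "run_study", "load_cohort"]

logger = logging.getLogger("fcnet")

GLOBAL_METRICS = ("e_glob", "e_loc", "modularity")
NORM_METRICS = ("e_glob_norm", "e_loc_norm")
NODAL_METRICS = ("degree", "efficiency", "betweenness")


@dataclass
class RunConfig:
    """Resolved study parameters; defaults reproduce the standard protocol."""

    s_min: float = 0.11
    s_max: float = 0.34
    s_step: float = 0.01
    n_random: int = 100
    swap_factor: int = 10
    master_seed: int = 0
    n_perm: int = 10000
    fdr_q: float = 0.05
    hub_alpha: float = 0.002
    modularity_sparsity: float = 0.15
    skip_nulls: bool = False
    nodal_metrics: tuple[str, ...] = NODAL_METRICS
    write_metrics: bool = True

    @property
    def grid(self) -> SparsityGrid:
        return SparsityGrid(self.s_min, self.s_max, self.s_step)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config with optional nested sections grid/null/inference."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        # a bare `null:` section key parses as Python None
        raw = {("null" if k is None else k): v for k, v in raw.items()}
        flat: dict = {}
        nested = {
            "grid": {"s_min": "s_min", "s_max": "s_max", "step": "s_step"},
            "null": {
                "n_random": "n_random",
                "swap_factor": "swap_factor",
                "master_seed": "master_seed",
            },
            "inference": {
                "n_perm": "n_perm",
                "fdr_q": "fdr_q",
                "hub_alpha": "hub_alpha",
                "modularity_sparsity": "modularity_sparsity",
            },
        }
        for section, mapping in nested.items():
            for key, attr in mapping.items():
                if section in raw and key in raw[section]:
                    flat[attr] = raw[section][key]
        for key in (
            "skip_nulls",
            "nodal_metrics",
            "master_seed",
            "n_perm",
            "write_metrics",
        ):
            if key in raw:
                flat[key] = raw[key]
        if "nodal_metrics" in flat:
            flat["nodal_metrics"] = tuple(flat["nodal_metrics"])
        return cls(**flat)


@dataclass
class StudyResult:
    global_aucs: pd.DataFrame
    nodal_aucs: dict[str, pd.DataFrame]
    global_comparisons: pd.DataFrame
    nodal_comparisons: pd.DataFrame
    per_level_ttests: pd.DataFrame
    hubs: dict[str, pd.DataFrame]
    modules: dict
    module_counts: pd.DataFrame
    clinical: pd.DataFrame
    summary: dict
    metrics_long: pd.DataFrame | None = None


def _seed_for(master_seed: int, tag: str) -> np.random.SeedSequence:
    """Name-keyed child seed: stable under re-ordering or ablation of stages."""
    return np.random.SeedSequence([master_seed, zlib.crc32(tag.encode())])


def load_cohort(manifest_path: str | Path, regions_path: str | Path | None = None) -> Cohort:
    """Read a cohort from disk into the in-memory form run_study consumes."""
    manifest_path = Path(manifest_path)
    manifest = fio.read_manifest(manifest_path)
    labels = None
    if regions_path is not None:
        labels = list(fio.read_regions(regions_path)["name"].astype(str))
    subjects = {}
    for _, row in manifest.iterrows():
        fpath = manifest_path.parent / row["file"]
        try:
            ts = fio.read_timeseries(fpath, subject_id=row["subject_id"], region_labels=labels)
        except ValueError as exc:
            raise ValueError(f"subject {row['subject_id']}: {exc}") from exc
        subjects[row["subject_id"]] = ts
    n_regions = {s.n_regions for s in subjects.values()}
    if len(n_regions) > 1:
        raise ValueError(f"subjects disagree on region count: {sorted(n_regions)}")
    first = subjects[manifest["subject_id"].iloc[0]]
    return Cohort(
        manifest=manifest, subjects=subjects, ground_truth={}, region_labels=first.region_labels
    )


def _group_order(labels: list[str]) -> tuple[str, str]:
    if {"patient", "control"} <= set(labels):
        return "patient", "control"
    a, b = sorted(labels)
    return a, b


def run_study(cohort: Cohort, config: RunConfig | None = None, out_dir: str | Path | None = None) -> StudyResult:
    """Run the full analysis on a cohort; optionally write result tables."""
    config = config or RunConfig()
    grid = config.grid
    svals = grid.values
    n_levels = len(svals)
    manifest = cohort.manifest
    sids = list(manifest["subject_id"])
    labels = cohort.region_labels
    n_regions = len(labels)
    t0 = time.perf_counter()
    logger.info("run_study: %d subjects, %d levels, master_seed=%d", len(sids), n_levels, config.master_seed)

    global_names = list(GLOBAL_METRICS) + ([] if config.skip_nulls else list(NORM_METRICS))
    g_curves = {m: np.full((len(sids), n_levels), np.nan) for m in global_names}
    n_curves = {m: np.full((len(sids), n_levels, n_regions), np.nan) for m in config.nodal_metrics}
    conns = {}
    rep_nets = {}

    for si, sid in enumerate(sids):
        conn = compute_connectivity(cohort.subjects[sid])
        conns[sid] = conn
        nets = sweep(conn, grid)
        if not check_min_sparsity(nets[0]):
            logger.warning("subject %s: mean degree at S=%.3f below 2 ln N", sid, svals[0])
        for k, net in enumerate(nets):
            e_i = nodal_efficiency(net)
            e_glob = float(e_i.mean())
            e_loc = local_efficiency(net)
            part = newman_partition(net)
            g_curves["e_glob"][si, k] = e_glob
            g_curves["e_loc"][si, k] = e_loc
            g_curves["modularity"][si, k] = part.q
            if "degree" in n_curves:
                n_curves["degree"][si, k] = nodal_degree(net)
            if "efficiency" in n_curves:
                n_curves["efficiency"][si, k] = e_i
            if "betweenness" in n_curves:
                n_curves["betweenness"][si, k] = betweenness(net)
            if not config.skip_nulls:
                ens = null_efficiencies(
                    net,
                    n_random=config.n_random,
                    seed=_seed_for(config.master_seed, f"null:{sid}:{k}"),
                    swap_factor=config.swap_factor,
                )
                gm = normalize(GlobalMetrics(e_glob=e_glob, e_loc=e_loc), ens)
                g_curves["e_glob_norm"][si, k] = gm.e_glob_norm
                g_curves["e_loc_norm"][si, k] = gm.e_loc_norm
        rep_nets[sid] = binarize_at_sparsity(conn, config.modularity_sparsity)
    logger.info("subject metrics done in %.1fs", time.perf_counter() - t0)

    # AUC summaries
    global_aucs = pd.DataFrame(
        {m: [auc(g_curves[m][i], grid) for i in range(len(sids))] for m in global_names},
        index=sids,
    )
    nodal_aucs = {
        m: pd.DataFrame(
            np.stack([[auc(n_curves[m][i, :, r], grid) for r in range(n_regions)] for i in range(len(sids))]),
            index=sids,
            columns=labels,
        )
        for m in config.nodal_metrics
    }

    # group split and covariates
    grp_a, grp_b = _group_order(list(manifest["group"].unique()))
    is_a = (manifest["group"] == grp_a).to_numpy()
    age = manifest["age"].to_numpy(dtype=float)
    sex = manifest["sex"].to_numpy()

    # covariate-adjusted permutation inference on AUCs
    def compare(values: np.ndarray, tag: str) -> tuple[float, float]:
        resid = residualize(values, age, sex)
        seed = _seed_for(config.master_seed, f"perm:{tag}")
        return permutation_test(resid[is_a], resid[~is_a], n_perm=config.n_perm, seed=seed)

    g_rows = []
    for m in global_names:
        diff, p = compare(global_aucs[m].to_numpy(), m)
        g_rows.append({"metric": m, "region": "", "observed_diff": diff, "p_perm": p, "n_perm": config.n_perm})
    global_comparisons = pd.DataFrame(g_rows)

    n_rows = []
    for m in config.nodal_metrics:
        mat = nodal_aucs[m].to_numpy()
        stats_m = [compare(mat[:, r], f"{m}:{labels[r]}") for r in range(n_regions)]
        pvals = np.array([p for _, p in stats_m])
        flags = fdr_correct(pvals, q=config.fdr_q)
        for r in range(n_regions):
            n_rows.append(
                {
                    "metric": m,
                    "region": labels[r],
                    "observed_diff": stats_m[r][0],
                    "p_perm": stats_m[r][1],
                    "n_perm": config.n_perm,
                    "fdr_significant": bool(flags[r]),
                }
            )
    nodal_comparisons = pd.DataFrame(n_rows)
    logger.info("permutation inference done in %.1fs", time.perf_counter() - t0)

    # per-level t profiles for global metrics
    t_rows = []
    for m in global_names:
        for k, s in enumerate(svals):
            try:
                t, p = per_threshold_ttest(g_curves[m][is_a, k], g_curves[m][~is_a, k])
            except ValueError:
                t, p = np.nan, np.nan
            t_rows.append({"metric": m, "sparsity": float(s), "t": t, "p": p})
    per_level_ttests = pd.DataFrame(t_rows)

    # hubs from group-mean betweenness curves
    hubs = {}
    if "betweenness" in n_curves:
        for grp, mask in ((grp_a, is_a), (grp_b, ~is_a)):
            curves = n_curves["betweenness"][mask].mean(axis=0).reshape(n_levels, n_regions)
            hubs[grp] = hub_sign_test(curves, grid, alpha=config.hub_alpha, region_labels=labels)

    # module decomposition of the group-mean networks + per-subject counts
    modules: dict = {}
    for grp, mask in ((grp_a, is_a), (grp_b, ~is_a)):
        mean_conn = mean_group_network([conns[s] for s, m in zip(sids, mask) if m])
        net = binarize_at_sparsity(mean_conn, config.modularity_sparsity)
        part = newman_partition(net)
        modules[grp] = {
            "n_modules": part.n_modules,
            "q": part.q,
            "assignment": part.assignment.tolist(),
        }
    counts = np.array([newman_partition(rep_nets[s]).n_modules for s in sids], dtype=float)
    try:
        t_mod, p_mod = per_threshold_ttest(counts[is_a], counts[~is_a])
    except ValueError:
        # all subjects share one module count; comparison is undefined
        logger.warning("module counts identical across subjects; t-test undefined")
        t_mod, p_mod = float("nan"), float("nan")
    module_counts = pd.DataFrame({"subject_id": sids, "group": manifest["group"], "n_modules": counts.astype(int)})
    modules["count_ttest"] = {"t": t_mod, "p": p_mod,
                              f"mean_{grp_a}": float(counts[is_a].mean()),
                              f"mean_{grp_b}": float(counts[~is_a].mean()),
                              f"sd_{grp_a}": float(counts[is_a].std(ddof=1)),
                              f"sd_{grp_b}": float(counts[~is_a].std(ddof=1))}

    # clinical correlation, gated on FDR-surviving nodal findings
    c_rows = []
    scores = manifest["updrs_motor"].to_numpy(dtype=float)
    has_score = np.isfinite(scores)
    if has_score.sum() >= 4 and len(nodal_comparisons):
        sig = nodal_comparisons[nodal_comparisons["fdr_significant"]]
        for _, row in sig.iterrows():
            vals = nodal_aucs[row["metric"]][row["region"]].to_numpy()[has_score]
            try:
                assoc = clinical_correlation(vals, scores[has_score], metric=row["metric"], region=row["region"])
            except ValueError:
                continue
            c_rows.append({"metric": assoc.metric, "region": assoc.region, "r": assoc.r, "p": assoc.p})
    clinical = pd.DataFrame(c_rows, columns=["metric", "region", "r", "p"])

    summary = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "groups": {grp_a: int(is_a.sum()), grp_b: int((~is_a).sum())},
        "grid": [float(s) for s in svals],
        "significant_global": global_comparisons[global_comparisons["p_perm"] < 0.05]["metric"].tolist(),
        "n_significant_nodal": int(nodal_comparisons["fdr_significant"].sum()) if len(nodal_comparisons) else 0,
        "hubs": {g: h[h["is_hub"]]["region"].tolist() for g, h in hubs.items()},
        "modules": {g: modules[g]["n_modules"] for g in (grp_a, grp_b)},
        "module_count_ttest": modules["count_ttest"],
    }

    metrics_long = None
    if config.write_metrics:
        rows = []
        for si, sid in enumerate(sids):
            for k, s in enumerate(svals):
                for m in global_names:
                    rows.append((sid, float(s), m, "", g_curves[m][si, k]))
                for m in config.nodal_metrics:
                    for r in range(n_regions):
                        rows.append((sid, float(s), m, labels[r], n_curves[m][si, k, r]))
        metrics_long = pd.DataFrame(rows, columns=["subject_id", "sparsity", "metric", "region", "value"])

    result = StudyResult(
        global_aucs=global_aucs,
        nodal_aucs=nodal_aucs,
        global_comparisons=global_comparisons,
        nodal_comparisons=nodal_comparisons,
        per_level_ttests=per_level_ttests,
        hubs=hubs,
        modules=modules,
        module_counts=module_counts,
        clinical=clinical,
        summary=summary,
        metrics_long=metrics_long,
    )
    if out_dir is not None:
        _write_results(result, Path(out_dir))
    logger.info("run_study complete in %.1fs", time.perf_counter() - t0)
    return result


def _write_results(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    fmt = "%.6g"
    result.global_aucs.to_csv(out_dir / "global_aucs.tsv", sep="\t", float_format=fmt, index_label="subject_id")
    for m, df in result.nodal_aucs.items():
        df.to_csv(out_dir / f"nodal_aucs_{m}.tsv", sep="\t", float_format=fmt, index_label="subject_id")
    result.global_comparisons.to_csv(out_dir / "global_comparisons.tsv", sep="\t", float_format=fmt, index=False)
    result.nodal_comparisons.to_csv(out_dir / "nodal_comparisons.tsv", sep="\t", float_format=fmt, index=False)
    result.per_level_ttests.to_csv(out_dir / "per_level_ttests.tsv", sep="\t", float_format=fmt, index=False)
    for grp, df in result.hubs.items():
        df.to_csv(out_dir / f"hubs_{grp}.tsv", sep="\t", float_format=fmt, index=False)
    result.module_counts.to_csv(out_dir / "module_counts.tsv", sep="\t", index=False)
    result.clinical.to_csv(out_dir / "clinical.tsv", sep="\t", float_format=fmt, index=False)
    if result.metrics_long is not None:
        result.metrics_long.to_csv(out_dir / "metrics.tsv", sep="\t", float_format=fmt, index=False)
    payload = dict(result.summary)
    payload["module_partitions"] = {
        g: result.modules[g] for g in result.modules if g != "count_ttest"
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
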