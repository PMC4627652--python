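"""Synthetic two-group ROI time-series cohorts with known ground truth.

The generator emulates the study design the pipeline targets: two groups
(26 patients, 30 controls) of 90-region, 230-time-point cleaned BOLD series
at TR = 2 s.  Regional signals are multivariate Gaussian draws with a
block-modular correlation matrix — 5 modules in controls, 4 in patients
(two control modules merged), r = 0.4 within modules and 0.10 between, with
designated hub regions boosted and a planted long-range deficit (patients'
between-module correlation reduced by delta) — then band-passed to the
0.01–0.08 Hz band at the sampling rate 1/TR.

Ages, sexes and clinical scores mirror the target demographics: age ~
N(55, 11) truncated to [30, 80], balanced sexes, patient motor scores
centered near 19 with SD near 9 and a planted (negative by default) slope
against the designated hub region's nodal connectivity strength.  Because the
pipeline consumes only correlations, temporal realism beyond band-limiting is
deliberately not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .net_build import RoiTimeSeries

__all__ = ["CohortSpec", "Cohort", "build_covariance", "sample_timeseries", "generate_cohort"]


def _default_control_modules() -> list[int]:
    return [18, 18, 18, 18, 18]


def _default_patient_modules() -> list[int]:
    # controls' last two modules merged: the patient network loses one module
    return [18, 18, 18, 36]


def _default_hubs() -> list[int]:
    return [0, 18, 36, 54, 72]


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_patients: int = 26
    n_controls: int = 30
    n_regions: int = 90
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    module_sizes_control: list[int] = field(default_factory=_default_control_modules)
    module_sizes_patient: list[int] = field(default_factory=_default_patient_modules)
    r_within: float = 0.4
    r_between: float = 0.10
    delta_between: float = 0.05
    hub_regions: list[int] = field(default_factory=_default_hubs)
    hub_boost: float = 0.1
    band: tuple[float, float] = (0.01, 0.08)
    effect_updrs: float = -4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, sizes in (
            ("control", self.module_sizes_control),
            ("patient", self.module_sizes_patient),
        ):
            if sum(sizes) != self.n_regions:
                raise ValueError(f"{name} module sizes must sum to n_regions")
        if not (0 <= self.r_between < self.r_within < 1):
            raise ValueError("need 0 <= r_between < r_within < 1")
        if self.r_between - self.delta_between < 0:
            raise ValueError("delta_between makes patient between-module correlation negative")

    def module_sizes(self, group: str) -> list[int]:
        return self.module_sizes_patient if group == "patient" else self.module_sizes_control


@dataclass
class Cohort:
    """In-memory cohort: manifest, per-subject series and ground truth."""

    manifest: pd.DataFrame
    subjects: dict[str, RoiTimeSeries]
    ground_truth: dict
    region_labels: list[str]

    def to_directory(self, path: str | Path) -> Path:
        """Write manifest.tsv, regions.tsv, per-subject TSVs, ground_truth.json."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.copy()
        files = []
        for sid in manifest["subject_id"]:
            fname = f"{sid}.tsv"
            ts = self.subjects[sid]
            pd.DataFrame(ts.values, columns=ts.region_labels).to_csv(
                path / fname, sep="\t", index=False, float_format="%.6g"
            )
            files.append(fname)
        manifest["file"] = files
        manifest.to_csv(path / "manifest.tsv", sep="\t", index=False, float_format="%.6g")
        regions = pd.DataFrame(
            {"index": np.arange(1, len(self.region_labels) + 1), "name": self.region_labels}
        )
        regions.to_csv(path / "regions.tsv", sep="\t", index=False)
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2)
        return path


def _nearest_pd(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at eps and re-normalize to unit diagonal."""
    w, v = np.linalg.eigh(corr)
    if w.min() >= eps:
        return corr
    w = np.clip(w, eps, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def build_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Block-modular correlation matrix for one group.

    r_within inside modules, r_between (minus delta_between for patients)
    between modules; rows/columns of hub regions get +hub_boost (applied once
    per pair, capped at 0.95); repaired to the nearest positive-definite
    correlation matrix if needed.
    """
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group {group!r}")
    n = spec.n_regions
    r_b = spec.r_between - (spec.delta_between if group == "patient" else 0.0)
    corr = np.full((n, n), r_b)
    start = 0
    module_of = np.empty(n, dtype=int)
    for m, size in enumerate(spec.module_sizes(group)):
        corr[start : start + size, start : start + size] = spec.r_within
        module_of[start : start + size] = m
        start += size
    if spec.hub_regions:
        is_hub = np.zeros(n, dtype=bool)
        is_hub[list(spec.hub_regions)] = True
        boost = is_hub[:, None] | is_hub[None, :]
        corr = np.where(boost, np.minimum(corr + spec.hub_boost, 0.95), corr)
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    if np.any(np.abs(corr[~np.eye(n, dtype=bool)]) >= 1.0):
        raise ValueError("infeasible correlation values (|r| >= 1 off-diagonal)")
    return _nearest_pd(corr)


def _band_pass(x: np.ndarray, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Keep only Fourier components inside the band (per column)."""
    t = x.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(x, axis=0)
    spec[~mask, :] = 0.0
    return np.fft.irfft(spec, n=t, axis=0)


def sample_timeseries(
    cov: np.ndarray,
    spec: CohortSpec,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    subject_id: str = "synthetic",
) -> RoiTimeSeries:
    """Draw T correlated Gaussian rows and band-pass each column.

    The filter is the same linear operator on every column, so cross-column
    correlations converge to the target as T grows (band-passing reduces the
    effective degrees of freedom, inflating sampling variance at finite T).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.linalg.eigvalsh(cov)
    if w.min() <= 0:
        raise ValueError("covariance must be positive definite")
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((spec.n_timepoints, cov.shape[0])) @ chol.T
    x = _band_pass(x, spec.tr_seconds, spec.band)
    return RoiTimeSeries(subject_id=subject_id, values=x, tr_seconds=spec.tr_seconds)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(spec: CohortSpec, out_dir: str | Path | None = None) -> Cohort:
    """Generate the full two-group cohort with covariates and clinical scores.

    Patient motor scores are built as clip(19 + 9*latent + effect_updrs *
    standardized nodal strength, >= 0), where the nodal strength is the
    subject's empirical mean |r| of the designated hub region — so a negative
    effect_updrs plants a negative score-vs-centrality correlation the
    pipeline should recover.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_cov, ss_demo, ss_updrs = root.spawn(3)
    cov = {g: build_covariance(spec, g) for g in ("patient", "control")}

    groups = ["patient"] * spec.n_patients + ["control"] * spec.n_controls
    sids = [f"sub-P{i + 1:02d}" for i in range(spec.n_patients)] + [
        f"sub-C{i + 1:02d}" for i in range(spec.n_controls)
    ]
    subj_seeds = ss_cov.spawn(len(sids))
    subjects: dict[str, RoiTimeSeries] = {}
    strengths = {}
    target_region = spec.hub_regions[0] if spec.hub_regions else 0
    for sid, grp, sseed in zip(sids, groups, subj_seeds):
        ts = sample_timeseries(cov[grp], spec, seed=sseed, subject_id=sid)
        subjects[sid] = ts
        r = np.corrcoef(ts.values, rowvar=False)
        row = np.abs(r[target_region])
        strengths[sid] = (row.sum() - 1.0) / (spec.n_regions - 1)

    rng_demo = np.random.default_rng(ss_demo)
    ages = _truncated_normal(rng_demo, 55.0, 11.0, 30.0, 80.0, len(sids))
    sexes = []
    for n_grp in (spec.n_patients, spec.n_controls):
        s = np.array(["M"] * (n_grp // 2) + ["F"] * (n_grp - n_grp // 2))
        rng_demo.shuffle(s)
        sexes.append(s)
    sex = np.concatenate(sexes)

    rng_updrs = np.random.default_rng(ss_updrs)
    pat_strength = np.array([strengths[s] for s in sids[: spec.n_patients]])
    sd = pat_strength.std()
    z_strength = (pat_strength - pat_strength.mean()) / sd if sd > 0 else np.zeros_like(pat_strength)
    latent = rng_updrs.standard_normal(spec.n_patients)
    updrs = np.clip(19.0 + 9.0 * latent + spec.effect_updrs * z_strength, 0.0, None)

    manifest = pd.DataFrame(
        {
            "subject_id": sids,
            "file": [f"{s}.tsv" for s in sids],
            "group": groups,
            "age": np.round(ages, 2),
            "sex": sex,
            "updrs_motor": np.concatenate(
                [np.round(updrs, 2), np.full(spec.n_controls, np.nan)]
            ),
        }
    )
    labels = subjects[sids[0]].region_labels
    ground_truth = {
        "spec": {
            k: (list(v) if isinstance(v, (list, tuple)) else v)
            for k, v in asdict(spec).items()
        },
        "hub_regions": list(spec.hub_regions),
        "delta_between": spec.delta_between,
        "target_region": int(target_region),
        "true_covariance_patient": np.round(cov["patient"], 6).tolist(),
        "true_covariance_control": np.round(cov["control"], 6).tolist(),
    }
    cohort = Cohort(
        manifest=manifest, subjects=subjects, ground_truth=ground_truth, region_labels=labels
    )
    if out_dir is not None:
        cohort.to_directory(out_dir)
    return cohort
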