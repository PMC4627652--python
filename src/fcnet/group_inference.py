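"""Group-level statistics: AUC summaries, covariate-adjusted permutation
tests, FDR correction, betweenness hub detection and clinical correlation.

Each metric's per-sparsity curve is collapsed to a threshold-free scalar by
trapezoidal integration (AUC).  Age and sex effects are regressed out of the
AUCs once, before inference; group differences are then tested by permuting
group labels (difference of group means, two-tailed, +1 smoothing).  Nodal
results are corrected with Benjamini–Hochberg FDR.  Hubs are regions whose
group-mean betweenness exceeds the network mean + SD consistently across
thresholds (one-tailed sign test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .net_build import SparsityGrid, ZConnectivity

__all__ = [
    "GroupComparison",
    "ClinicalAssoc",
    "auc",
    "residualize",
    "permutation_test",
    "per_threshold_ttest",
    "fdr_correct",
    "hub_sign_test",
    "mean_group_network",
    "clinical_correlation",
    "count_modules_per_subject",
]


@dataclass
class GroupComparison:
    metric: str
    region: str
    observed_diff: float
    p_perm: float
    n_perm: int
    fdr_significant: bool | None = None


@dataclass
class ClinicalAssoc:
    metric: str
    region: str
    r: float
    p: float


def auc(curve: np.ndarray, grid: SparsityGrid) -> float:
    """Trapezoidal area under a metric curve over the sparsity sweep:
    sum_k [Y(S_k) + Y(S_{k+1})] * dS / 2."""
    curve = np.asarray(curve, dtype=float)
    s = grid.values
    if curve.shape[0] != s.shape[0]:
        raise ValueError(
            f"curve length {curve.shape[0]} does not match grid length {s.shape[0]}"
        )
    if curve.shape[0] < 2:
        raise ValueError("AUC needs at least 2 grid levels")
    return float(np.trapezoid(curve, s))


def residualize(values: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """OLS residuals of values on [intercept, age, sex(0/1)].

    Sex may be given as any two-level coding (strings accepted).
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if not np.issubdtype(sex.dtype, np.number):
        levels = np.unique(sex)
        if levels.size > 2:
            raise ValueError(f"sex must be dichotomous, got levels {levels}")
        sex = (sex == levels[-1]).astype(float)
    sex = sex.astype(float)
    n = values.shape[0]
    if n < 3:
        raise ValueError("residualization needs at least 3 subjects")
    x = np.column_stack([np.ones(n), age, sex])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        for col, name in ((1, "age"), (2, "sex")):
            reduced = np.delete(x, col, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"covariate matrix rank-deficient: {name} is collinear")
        raise ValueError("covariate matrix rank-deficient")
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[float, float]:
    """Two-tailed label-permutation test of the difference of group means.

    Returns (observed a-minus-b difference, p value).  p uses the +1
    smoothing (1 + #{|null| >= |obs|}) / (n_perm + 1) so it is never 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a, n_tot = a.size, a.size + b.size
    rng = np.random.default_rng(seed)
    # vectorized label shuffles: argsort of uniform noise gives permutations
    keys = rng.random((n_perm, n_tot))
    order = np.argsort(keys, axis=1)
    perm_vals = pooled[order]
    null = perm_vals[:, :n_a].mean(axis=1) - perm_vals[:, n_a:].mean(axis=1)
    p = (1.0 + np.count_nonzero(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return observed, float(p)


def per_threshold_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pooled-variance two-sample two-tailed t-test (per-sparsity profile)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up significance flags at level q."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def hub_sign_test(
    group_b_curves: np.ndarray,
    grid: SparsityGrid,
    alpha: float = 0.002,
    region_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Detect hubs from group-mean betweenness curves.

    ``group_b_curves`` is (n_levels, n_regions): the group-mean betweenness of
    each region at each sparsity level.  A region counts as exceeding at a
    level when its value is above the across-region mean + SD at that level.
    The one-tailed sign test p is P[Binomial(n_levels, 1/2) >= n_exceed];
    BH-FDR is applied across regions and hubs are flagged at ``alpha``.
    """
    curves = np.asarray(group_b_curves, dtype=float)
    n_levels = len(grid)
    if curves.shape[0] != n_levels:
        raise ValueError("curve rows must match grid length")
    if n_levels < 2:
        raise ValueError("hub sign test needs at least 2 grid levels")
    n_regions = curves.shape[1]
    thresh = curves.mean(axis=1, keepdims=True) + curves.std(axis=1, ddof=1, keepdims=True)
    n_exceed = (curves > thresh).sum(axis=0)
    p_sign = stats.binom.sf(n_exceed - 1, n_levels, 0.5)
    reject = fdr_correct(p_sign, q=alpha)
    labels = region_labels or [f"ROI{i + 1:03d}" for i in range(n_regions)]
    return pd.DataFrame(
        {
            "region": labels,
            "n_exceed": n_exceed.astype(int),
            "p_sign": p_sign,
            "is_hub": reject,
        }
    )


def mean_group_network(conns: list[ZConnectivity]) -> ZConnectivity:
    """Element-wise mean of a group's Fisher-z connectivity matrices."""
    if not conns:
        raise ValueError("need at least one subject")
    labels = conns[0].region_labels
    for c in conns[1:]:
        if c.region_labels != labels:
            raise ValueError("subjects have mismatched region sets")
    z = np.mean([c.z for c in conns], axis=0)
    return ZConnectivity(z=z, region_labels=list(labels))


def clinical_correlation(
    nodal_aucs: np.ndarray, scores: np.ndarray, metric: str = "", region: str = ""
) -> ClinicalAssoc:
    """Pearson correlation between a nodal AUC and a clinical score."""
    x = np.asarray(nodal_aucs, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    res = stats.pearsonr(x, y)
    return ClinicalAssoc(metric=metric, region=region, r=float(res.statistic), p=float(res.pvalue))


def count_modules_per_subject(
    nets_a: list, nets_b: list
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-subject module counts at a representative sparsity, compared by t-test.

    Returns (counts_a, counts_b, t, p).  A zero-variance situation (all
    subjects yield identical counts) surfaces as an error from the t-test.
    """
    from .graph_metrics import newman_partition

    counts_a = np.array([newman_partition(n).n_modules for n in nets_a], dtype=float)
    counts_b = np.array([newman_partition(n).n_modules for n in nets_b], dtype=float)
    t, p = per_threshold_ttest(counts_a, counts_b)
    return counts_a, counts_b, t, p
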