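# fcnet

Graph-theoretical analysis of resting-state functional connectomes, for
researchers comparing brain-network topology between a clinical group and
controls from regional BOLD time series (e.g., AAL-parcellated
resting-state fMRI).

Given per-subject ROI time series, `fcnet` builds Fisher-z connectivity
matrices, binarizes them over a sparsity sweep so all subjects' networks
have identical edge counts, and quantifies topology with the efficiency
formalism:

- global efficiency  E_glob = (1/(N(N−1))) Σ_{i≠j} 1/L_ij
- local efficiency   E_loc = (1/N) Σ_i E_glob(G_i), G_i the neighbor
  subgraph of node i
- nodal degree K_i, nodal efficiency E_i, betweenness centrality
  B_i = Σ_{j<k} δ_jk(i)/δ_jk
- Newman–Girvan modularity Q via leading-eigenvector spectral bisection

Small-worldness is judged against 100 degree-preserving double-edge-swap
random networks per graph: E_loc(real)/E_loc(random) > 1 with
E_glob(real)/E_glob(random) ≈ 1. Each metric's curve over the sweep
S = 0.11…0.34 collapses to a threshold-free AUC; group differences are
tested by a 10 000-permutation test on age/sex-residualized AUCs, nodal
results are FDR-corrected (Benjamini–Hochberg), hubs are detected by a
one-tailed sign test on betweenness exceeding mean+SD across thresholds,
and surviving nodal metrics are correlated with clinical scores (Pearson).

A synthetic cohort generator produces two-group study data (default: 26
patients vs 30 controls, 90 regions, 230 time points at TR = 2 s) with
block-modular covariance, designated hubs, a planted long-range
connectivity deficit in patients, covariates and clinical scores — so
every stage of the pipeline can be validated against known ground truth.
See `docs/methods.md` for the model details and assumptions.

## Worked example

Simulate a cohort and run the full study from the command line:

```sh
fcnet simulate --out cohort/ --seed 1
fcnet run --manifest cohort/manifest.tsv --regions cohort/regions.tsv \
          --out results/ --seed 1 --n-random 20 --n-perm 5000
```

or equivalently from Python:

```python
from fcnet import CohortSpec, RunConfig, generate_cohort, run_study

cohort = generate_cohort(CohortSpec(seed=1))
result = run_study(cohort, RunConfig(n_random=20, n_perm=5000, master_seed=1))
print(result.summary["significant_global"])
print(result.modules["patient"]["n_modules"],
      result.modules["control"]["n_modules"])
```

On this cohort the pipeline reports (values printed by
`scripts/acceptance.py --seed 1`):

| quantity | patients | controls | meaning |
|---|---|---|---|
| E_glob AUC | 0.1120 | 0.1290 | patients' networks integrate information less efficiently; permutation p = 0.0002 |
| E_loc AUC | 0.1934 | 0.1846 | local clustering is higher in patients (the flip side of losing long-range edges at fixed edge count) |
| modularity Q AUC | 0.1237 | 0.1224 | no group difference (p = 0.51) |
| mean-network modules | 4 | 5 | the generator's merged module is recovered exactly |
| detected hubs | 5 | 5 | exactly the 5 planted hub regions |

Mean normalized efficiencies are E_loc_norm = 1.61 > 1 and
E_glob_norm = 0.87 ≈ 1: both groups show the small-world signature. The
planted clinical effect is recovered as r = −0.51 (p = 0.008) between
patients' motor scores and the target region's degree AUC.

## Layout

- `fcnet.net_build` — time series → Fisher-z connectivity → binarized
  networks (exact edge counts, nested sweeps, deterministic tie-breaking)
- `fcnet.graph_metrics` — efficiencies, degree, betweenness, spectral
  modularity
- `fcnet.null_models` — degree-preserving rewiring and normalization
- `fcnet.group_inference` — AUC, residualization, permutation tests, FDR,
  hub sign test, clinical correlation
- `fcnet.synthetic_data` — ground-truth cohort generator
- `fcnet.pipeline` / `fcnet.cli` — orchestration, config, `fcnet` console
  entry point (`simulate`, `run`, `metrics`, `null-check`)
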