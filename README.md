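# connectokit

Individual-level functional connectomics for resting-state fMRI: personalized
large-scale network mapping by spatially regularized non-negative matrix
factorization (NMF), node- and edge-centric functional network connectivity,
co-fluctuation amplitude analysis, graph-theoretic network attributes,
edge-community detection, and the group-comparison statistics layer used to
contrast clinical groups (e.g. typically developing children vs. ASD and ADHD
subtypes).

The package is aimed at researchers who analyse masked voxel × time BOLD
matrices at the single-subject level and want the whole chain — from numerical
preprocessing to FDR-corrected group statistics — as tested, scriptable
library code. A synthetic multi-subject cohort generator with full ground
truth makes every stage testable end-to-end without any imaging data.

## The model

Each subject's normalized time × voxel matrix `X` (all entries shifted and
scaled into [0, 1] per voxel) is factorized as

    X ≈ W H,   minimizing  ‖X − WH‖²_F + β·tr(H L Hᵀ) + α·‖H − H₀‖²_F

with `W` (T × K) the non-negative network time courses, `H` (K × V) the
non-negative spatial loadings, `L` the graph Laplacian of the voxel adjacency
(spatial smoothness), and `H₀` a consensus **group atlas** used as a prior
when decomposing an individual (K = 17 networks by default). The group atlas
itself comes from repeated decompositions of a time-concatenated multi-subject
matrix, fused by spectral clustering of the repeat atlases' rows.

Downstream, with `x_i` the z-scored time course of network *i*:

* **FNC**: the K × K matrix of Pearson correlations r(x_i, x_j);
* **edge time series**: e_ij(t) = x_i(t)·x_j(t) for all E = K(K−1)/2 pairs —
  with population-variance z-scoring, (1/T)Σ_t e_ij(t) = r(i, j) exactly;
* **eFC**: the E × E correlation matrix between edge time series;
* **RSS**: the per-frame co-fluctuation amplitude √(Σ_e e(t)²), its top/bottom
  5 % frame tails, and the 3 × 3 matrix of transitions between
  bottom/normal/top amplitude levels;
* **graph attributes** of the significance-thresholded (p < 0.05) FNC and eFC
  graphs: Cp, Lp, Eglob, Eloc, assortativity, modularity Q, betweenness,
  degree, and the small-world indices γ = Cp/⟨Cp_null⟩, λ = Lp/⟨Lp_null⟩,
  σ = γ/λ against degree-preserving rewired nulls;
* **edge communities**: module count by recursive signed spectral modularity
  optimization of the eFC matrix, partition by correlation-distance k-means,
  community↔network incidence counts and community-level FC;
* **statistics**: per-feature ANCOVA (group factor, mean framewise
  displacement as covariate), post-hoc two-sample t-tests gated at p < 0.05,
  Benjamini–Hochberg FDR, plus one-way ANOVA, chi-square and Pearson
  correlation utilities for demographics and brain–behaviour associations.

## Worked example

```python
import numpy as np
import connectokit as ck
from connectokit.netmap import NmfConfig

# a cohort with a planted +0.4 covariance shift on one network pair in ASD
design = ck.CohortDesign(
    groups=[("TD", 6), ("ASD", 6)], n_voxels=300, k=5, t_raw=120,
    fnc_effects=[("ASD", (1, 2), 0.4)], seed=42,
)
scans, pheno, truth = ck.simulate_cohort(design)
proc = [ck.preprocess_subject(s, n_drop=10)[0] for s in scans]

cfg = NmfConfig(k=5, repeats=3, init_seed=42)
consensus = ck.consensus_atlas(ck.group_initialize(proc, cfg), 5, seed=42)
pers = [ck.personalize(s, consensus, cfg) for s in proc]
tcs, atlases = [p[0] for p in pers], [p[1] for p in pers]

labels = ck.assign_voxels(consensus)
acc = ck.reconstruction_accuracy(proc, tcs, atlases, labels)
print("reconstruction accuracy per network:", np.round(acc, 3))

ets = ck.edge_time_series(tcs[0])
prof = ck.rss_profile(ets, frac=0.05)
print("top-5% mean RSS:", round(ck.tail_amplitude(prof, "top"), 2),
      " bottom-5%:", round(ck.tail_amplitude(prof, "bottom"), 2))

g = ck.threshold_significant(ck.edge_fnc(ets).values, t_samples=110)
gamma, lam, sigma, crit = ck.small_world(g, n_null=50, seed=42)
print(f"edge-wise small-world: gamma={gamma:.2f} lambda={lam:.2f} "
      f"sigma={sigma:.2f}")

feats = np.array([ck.node_fnc(tc).upper_triangle() for tc in tcs])
res = ck.feature_screen(feats, pheno["group"].to_numpy(),
                        pheno["mean_fd"].to_numpy(),
                        feature_names=[f"fnc_{i}_{j}" for i, j in ets.edges])
for r in res:
    if r.gated:
        print(r.feature, f"F={r.f:.2f} p={r.p:.4f}",
              [(pr.pair, round(pr.p_fdr, 3)) for pr in r.pairs])
```

Output:

```
reconstruction accuracy per network: [0.889 0.913 0.904 0.893 0.905]
top-5% mean RSS: 8.2  bottom-5%: 0.2
edge-wise small-world: gamma=1.14 lambda=1.00 sigma=1.14
fnc_0_4 F=9.51 p=0.0131 [(('ASD', 'TD'), 0.016)]
fnc_1_3 F=9.97 p=0.0116 [(('ASD', 'TD'), 0.016)]
```

Reading the numbers: every network is reconstructed at r ≈ 0.9, so the
5-network decomposition explains the voxel signals well. The top 5 % of
frames carry ~40× the co-fluctuation amplitude of the bottom 5 % — the
familiar picture that a few high-amplitude frames drive functional
connectivity. The edge-wise graph is (weakly) small-world (σ > 1, λ ≈ 1).
The ANCOVA + FDR screen flags two FNC pairs as differing between ASD and TD;
network indices are in consensus-atlas space, so the planted truth pair
(1, 2) appears under the matched consensus row indices.

The same pipeline is scriptable end-to-end from the shell:

```bash
connectokit run-all --config my_design.yaml --out results/ --seed 7
```

which writes per-stage artifacts (`simulate/`, `preprocess/`,
`map-networks/`, `connectivity/`, `graph/`, `communities/`, `stats/`) and a
`manifest.json` with per-stage seeds and output checksums; re-running the
same config and seed reproduces identical checksums.

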