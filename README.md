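# nodedce

Pixel-wise analysis of dynamic contrast-enhanced MRI (DCE-MRI) of lymph
nodes. Normal lymph nodes show a heterogeneous enhancement pattern: a
strongly and rapidly enhancing inner region (medulla/hilum) and a more
weakly enhancing outer rim (cortex). `nodedce` turns that observation into a
reproducible, operator-independent pipeline for one slice of interest:

1. **Motion correction** — translation-only registration of every frame to
   the 2nd post-injection frame (cross-correlation with subpixel
   refinement); series whose residual displacement exceeds a threshold are
   flagged and excluded.
2. **Normalized differential enhancement (NDE)** — per node pixel,

   `NDE(t) = (SI(t) − SI_pre) / DEmax_muscle`

   where `SI_pre` is the pixel's mean pre-contrast signal and
   `DEmax_muscle` the maximal differential enhancement of a muscle ROI,
   which makes curves invariant to global scaling and partially compensates
   dose differences.
3. **PCA screen + k-means** — the per-pixel NDE curves are clustered with
   k-means (k = 2, squared Euclidean distance on the raw curves, no spatial
   term); a PCA variance screen on the same curves reports how much variance
   the first components explain. The cluster with the larger
   post-injection AUC is labeled *inner*, the other *outer*.
4. **Semiquantitative parameters** per cluster-averaged curve — AUC
   (trapezoidal, post-injection window), wash-in rate (maximum
   consecutive-frame slope between the last baseline point and the
   enhancement peak) and wash-out rate (least-squares slope of the last 40
   frames), the rates normalized by the node's maximal enhancement — plus
   cluster volume (%).
5. **Statistics** — mixed two-way ANOVA (cluster as a within-node factor,
   contrast agent as a between-node factor) with Bonferroni-adjusted
   within-agent inner-vs-outer contrasts.

A digital phantom (`nodedce.phantom`) synthesizes 70-frame dynamic series —
3 pre-contrast baselines, bolus between scans 3 and 4, two concentric node
compartments with distinct uptake/washout kinetics, a muscle strip, optional
noise and rigid motion — with full ground truth, so every stage is testable
without animal data. A transcription of the published per-node parameter
table (15 nodes: 9 Gd-DTPA, 6 Gd-BOPTA) ships with the package for the
statistics stage.

## Worked example

```python
from nodedce import (PhantomSpec, generate_phantom, RoiMask, compute_nde,
                     pca_screen, kmeans_segment, assign_cluster_roles, extract_all)

spec = PhantomSpec(seed=4)                      # 70 frames, 46/70 min apart
series, truth = generate_phantom(spec)
nde = compute_nde(series, RoiMask(truth.node_mask, "node"),
                  RoiMask(truth.muscle_mask, "muscle"))
print(f"two PCs explain {pca_screen(nde).cumulative_pct[1]:.1f}% of variance")
result = assign_cluster_roles(kmeans_segment(nde, seed=4),
                              series.frame_interval, series.n_baseline)
print(extract_all(result, nde.mean_curve(), series.frame_interval,
                  series.n_baseline).to_string(index=False))
```

prints

```
two PCs explain 96.6% of variance
 node   agent cluster        auc  wash_in  wash_out  volume_pct
    1 Gd-DTPA   inner 124.330922 1.719234 -0.024493   29.680365
    1 Gd-DTPA   outer  78.863825 0.354101 -0.009297   70.319635
```

— the inner cluster occupies ~30% of the node, enhances more (higher AUC
and wash-in) and washes out faster (more negative wash-out), matching the
pattern seen in vivo. The same run is available from the shell:

```
nodedce simulate --out phantom --seed 4
nodedce run --config run.yaml          # or: register / enhance / cluster / params
nodedce stats --parameter wash_out     # ANOVA on the packaged node table
```

`nodedce stats` reports, per parameter, the cluster and agent main effects
and the Bonferroni-adjusted within-agent inner-vs-outer contrasts with
significance annotations at p < 0.05 (*) and p < 0.01 (**).

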