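# tcdeeg

Resting-state EEG source-spectral analysis of **thalamocortical dysrhythmia
(TCD)**, packaged as a tested, reproducible pipeline with a synthetic
two-group cohort generator for verification.

In TCD syndromes, altered thalamic firing drags the dominant cortical alpha
rhythm toward the theta band and produces secondary, spatially localized
gamma elevation (the "edge effect").  This package implements the analysis
chain used to characterize that signature in clinical populations such as
Fragile X Syndrome:

1. **Forward/inverse modeling** — an analytic current-dipole lead field in a
   homogeneous conducting sphere (toy cortical icosphere, Fibonacci-lattice
   montage) and a depth-weighted L2 minimum-norm inverse,
   `K = R Lᵀ (L R Lᵀ + λ²I)⁻¹` with `R = diag(‖lᵢ‖^(−2γ))`, identity noise
   covariance, and `λ² = mean diag(L R Lᵀ)/SNR²`.
2. **Spectral analysis** — 2-s epochs on a 0.5 Hz grid (Hann taper, linear
   detrend), Welch PSD for source series, seven bands
   (δ 2–3.5, θ 3.5–7.5, α1 8–10, α2 10–12.5, β 13–30, γ1 30–55,
   γ2 65–90 Hz), relative power per epoch then trial-averaged, geodesic
   Gaussian cortical smoothing, and **peak alpha frequency** (PAF) as the
   largest log-power peak in 6–14 Hz.
3. **Parcellation** — vertex → node → 14 anatomical regions and 6
   resting-state networks (DMN/DAN/SAN/AUD/VIS/Other); a Desikan–Killiany
   68-node classification table ships as editable CSV, and a clustered toy
   atlas keeps every code path runnable at desk scale.
4. **Cross-frequency coupling (CFC)** — Spearman rank correlation, across
   2-s epochs, between whole-brain low-band relative power (θ, α1, α2) and
   node-level γ1 relative power, Fisher Z-transformed.
5. **Group statistics** — pooled-t maps, cluster-based Monte-Carlo
   permutation testing (0.025 per tail, cluster mass, max-statistic null),
   Benjamini–Hochberg FDR over signals × bands, a 0.05/7 scalp Bonferroni
   rule, and age-controlled partial Spearman correlations.

Because the original group-level numbers come from a real cohort, the
package verifies itself on **synthetic cohorts with known ground truth**:
the generator builds per-node band-limited noise with a 1/f amplitude
profile, a dominant alpha bump centred on each subject's drawn PAF
(presets: control 9.2 Hz vs affected 7.8 Hz), focal gamma gains, and a
Gaussian-copula mechanism that sets the epoch-wise power–power rank
correlation exactly (`ρ_latent = 2 sin(πρ_s/6)`).

## Worked example

```python
from tcdeeg.pipeline import RunConfig, run_full

rep = run_full(RunConfig(master_seed=1), out_dir="results/run")
for name, d in rep.report["directions"].items():
    print(name, f"diff={d['diff']:+.3f}", f"t={d['t']:+.2f}")
print(rep.report["paf"]["group_mean"])
```

prints (10 + 10 subjects, 642-vertex mesh, 32 electrodes, 24 nodes):

```
paf_lower diff=-1.450 t=-4.20
theta_share_higher diff=+0.257 t=+5.42
alpha2_share_lower diff=-0.069 t=-2.11
gamma1_focus_higher diff=+0.006 t=+9.70
theta_gamma1_z_more_negative diff=-0.615 t=-10.15
{'control': 9.0, 'affected': 7.55}
```

i.e. the affected-like group shows the full dysrhythmia signature: PAF
slowed by ~1.45 Hz (true generative gap 1.42 Hz), elevated theta share,
depressed alpha2 share, gamma1 elevated specifically on the designated
temporal/parietal/occipital nodes, and inverse theta–gamma1 coupling —
each direction matching the generator's ground truth, with its test
statistic and FDR-adjusted p value in the report.

The numbered scripts under `analysis/` run the same stages as standalone
steps (simulate cohort, spectral tables, group statistics, estimator
validation), writing their tables under `results/`.  A thin CLI is also
installed: `tcdeeg run --seed 1 --out results/run`.

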