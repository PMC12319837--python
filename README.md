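# axisflux

Dense-sampling ("precision imaging") studies scan one or two individuals
daily for about a month, yielding ~30 functional connectomes per person
alongside day-by-day hormone panels and perceived-stress scores.  `axisflux`
implements the full analysis pipeline for asking how functional cortical
organization fluctuates within a person over such a study, and what covaries
with those fluctuations:

1. **Connectomes** — parcellated BOLD series are band-limited with a maximal
   overlap discrete wavelet transform (detail scales 3–6, ~0.01–0.17 Hz at
   TR = 0.72 s) and pairwise connectivity is magnitude-squared coherence
   `C_xy = |S_xy|² / (S_xx S_yy)` averaged over the passband, with
   Benjamini–Hochberg FDR over edges.
2. **The S-A axis** — each session's connectome is sparsified (top 10% per
   row), converted to a normalized-angle affinity, and embedded with
   anisotropic diffusion maps (α = 0.5, t = 0, 10 components).  Session
   embeddings are Procrustes-aligned to the embedding of the subject's mean
   connectome; the first aligned component is the session's
   sensorimotor-association (S-A) axis, oriented so association cortex
   (default-mode) loads above somatomotor cortex.
3. **Statistics** — per-parcel SD of loadings across sessions (intra-
   individual variability), Levene tests for between-subject variance
   differences, feature-map decoding, per-parcel session-grouped linear
   models of hormone/stress effects (FDR across parcels), and within- /
   between-network dispersion along the axis
   (`D_w(n) = Σ_p (g_p − median_n)²`, `D_b(n,m) = |median_n − median_m|`)
   with Bonferroni families 0.025/7 and 0.025/21.  All spatial inference
   uses hemisphere-aware spherical spin permutations.

A first-class synthetic-data module (`axisflux.synth`) generates
parcellations, menstrual-cycle-like or diurnal covariate trajectories, and
session time series from a planted latent axis with known local and
dispersion effects, so every stage of the pipeline is testable with full
ground truth and no data downloads.

## Worked example

Simulate a 20-session study at 100 parcels with a planted estradiol effect
on ten parcels' loadings and a planted progesterone effect on default-mode
dispersion, then run the pipeline:

```python
import numpy as np
from scipy.stats import spearmanr
from axisflux import *
from axisflux import synth

meta = synth.make_parcellation(100, 7, seed=7)
cov = synth.simulate_covariates(20, "cycle", seed=7)
beta = np.zeros(100); beta[:10] = 0.08
truth = synth.make_ground_truth(
    meta,
    beta_local={"estradiol": beta},
    gamma_dispersion={"progesterone": {"default_mode": 0.5}},
    noise_sd=0.05, seed=7,
)
meta, truth, cov, records = synth.simulate_study(
    n_parcels=100, n_sessions=20, n_timepoints=512, seed=7, truth=truth
)

fcs = [session_coherence_fc(r) for r in records]
axes = compute_sa_axes(fcs, meta)
print("mean-axis recovery r =",
      round(abs(spearmanr(axes.mean_axis, truth.g0).statistic), 3))

maps = fit_local_effects(axes, cov, ["estradiol", "progesterone"])
for m in maps:
    print(f"{m.covariate}: {int(m.significant.sum())} of 100 parcels "
          "significant (q<0.05)")

ser = dispersion_series(axes, meta)
eff = fit_dispersion_effects(ser, cov, ["progesterone"])
row = eff[(eff.kind == "within") & (eff.measure == "default_mode")].iloc[0]
print(f"default_mode within-dispersion: t = {row.t:.2f}, "
      f"significant at p<0.004: {row.bonferroni_significant}")

spins = generate_spins(meta, 200, seed=7)
print("label-spin specificity p =",
      spin_specificity(axes, meta, cov, "default_mode", "progesterone", spins))
```

prints

```
mean-axis recovery r = 0.943
estradiol: 8 of 100 parcels significant (q<0.05)
progesterone: 47 of 100 parcels significant (q<0.05)
default_mode within-dispersion: t = 7.78, significant at p<0.004: True
label-spin specificity p = 0.024875621890547265
```

The embedding recovers the planted axis from raw time series (r = 0.94);
the estradiol t-map flags planted parcels; the progesterone dispersion
effect is Bonferroni-significant for the planted network and survives the
network-label spin test (dispersion planting also shifts individual
default-mode loadings, which is why progesterone shows local effects too).

The same stages are available as a CLI for file-based workflows:

```bash
axisflux simulate --out study/ --seed 7 --n-parcels 100 --n-sessions 20
axisflux fc --in study/sessions --meta study/parcellation.csv --out fc.h5
axisflux gradients --fc fc.h5 --meta study/parcellation.csv --out axes.h5
axisflux effects --axes axes.h5 --cov study/covariates.csv \
    --model female_predominant --out effects/
```

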