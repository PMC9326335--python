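# tumorperf

Longitudinal analysis of tumor perfusion and angiogenesis under different
neoadjuvant chemotherapy schedules — maximum-tolerated-dose (MTD),
metronomic (MET) and saline control (CG) arms followed over six weekly
endoscopy visits in a preclinical colorectal model.

The package implements the full analysis chain for that study design:

- **optics** — calibration of endoscopic diffuse reflectance spectra
  against dark and 5%-standard measurements, artifact screening
  (saturation, low signal, high residual), and bounded least-squares
  inversion of a monotone forward model R(μₐ, μₛ′) — evaluated directly or
  through a lookup table — into tissue parameters θ = (tHb, StO₂, a, b)
  with μₐ(λ) = ln10 · (tHb/64500) · [StO₂·ε_HbO₂(λ) + (1−StO₂)·ε_Hb(λ)] and
  μₛ′(λ) = a·(λ/630 nm)⁻ᵇ; derived metrics HbO₂ = StO₂·tHb,
  HbO = (1−StO₂)·tHb and per-tumor week-1 fold changes.
- **qpcr** — 260/280 quality filtering, triplicate aggregation,
  standard-curve efficiency estimation E = 10^(−1/slope), and Pfaffl
  relative quantification ratio = E_t^ΔCt_t / E_ref^ΔCt_ref with *Gapdh*
  as housekeeping gene and the control group at week 1 as calibrator.
- **gam / inference** — the statistical core, in the statsmodels mold:
  `GroupSmoothModel` fits y = α_g + f_g(week) + ε with one penalized
  cubic P-spline trend f_g per treatment arm (second-order difference
  penalty, REML-selected smoothing, Bayesian coefficient covariance with a
  smoothing-uncertainty correction); its `GroupSmoothResults` provides
  `summary()`, pointwise 95% intervals, and pairwise trend differences
  with **95% simultaneous confidence bands** built from posterior
  coefficient simulation — time windows where a band excludes zero are the
  periods of significant treatment difference.
- **cohort** — nine-category endoscopic tumor-score proportions (missing
  visits excluded from denominators) and microvessel density
  (MVD = % Nestin-positive of tissue area in 3-class label masks) compared
  across arms with a Kruskal–Wallis test.
- **synthetic** — a generator that emulates the whole cohort (spectra with
  acquisition artifacts, triplicate Ct tables with standard curves, score
  tables, vessel masks) from known ground-truth trajectories, so every
  stage is testable end to end without any external data.
- **pipeline / cli** — `tumorperf run-all --config cfg.yml --seed 3 --out
  results` executes simulate → invert → qpcr → fit → compare → cohort →
  report with a hash-stable manifest.

## Worked example

Fit the group-smooth GAM to *Vegf* relative expression from a synthetic
cohort at the study's arm sizes (CG 14, MET 20, MTD 27) and compare CG
against MTD:

```python
from tumorperf import CohortConfig, simulate_trajectories, simulate_qpcr
from tumorperf.qpcr import efficiencies_from_curves, normalize_expression
from tumorperf.gam import GroupSmoothModel
from tumorperf.inference import significant_windows

cfg = CohortConfig(n_per_group={"CG": 14, "MET": 20, "MTD": 27}, seed=5)
trajs = simulate_trajectories(cfg)
ct, curves = simulate_qpcr(trajs, cfg)
expr = normalize_expression(ct, efficiencies_from_curves(curves))
vegf = expr[expr["gene"] == "Vegf"].rename(columns={"relative_expression": "value"})

res = GroupSmoothModel.from_dataframe(vegf).fit()
print(res.summary())
band = res.difference("CG", "MTD", seed=1)
print(f"m* = {band.m_star:.3f}")
print(significant_windows(band).to_records())
```

prints

```
Group-smooth GAM (Gaussian, identity link)
==========================================================
Observations:    366    Basis dim k: 6    Penalty order: 2
Scale (sigma^2): 0.0059999    Total EDF: 7.27
----------------------------------------------------------
group        intercept      lambda   EDF(smooth)
CG              0.9396   9.993e+05          1.00
MET             0.9247   9.999e+05          1.00
MTD             0.7733       1.715          2.27
==========================================================
m* = 2.579
[{'start': 1.0, 'end': 4.41, 'direction': 'positive', 'short': False},
 {'start': 5.07, 'end': 6.0, 'direction': 'negative', 'short': False}]
```

Reading: the CG and MET *Vegf* trends are effectively linear (smooth EDF
1.0, heavy smoothing), while the MTD arm needs real curvature (EDF 2.3) —
its expression starts ~50% suppressed and recovers.  The simultaneous
critical multiplier m* = 2.58 exceeds the pointwise 1.96 because the band
must hold across the whole six-week window at once.  CG exceeds MTD
significantly from week 1 until week ~4.4 (the suppression window) before
the recovering MTD trend crosses over.

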