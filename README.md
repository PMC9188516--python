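# thermomri

Brain temperature strongly affects quantitative MRI. In post mortem in situ
imaging (PMMRI) the brain cools passively toward ambient temperature
(algor mortis), so T1, T2, T2*, mean diffusivity (MD) and fractional
anisotropy (FA) measured in deceased subjects are not directly comparable
to in vivo values, nor between subjects at different post mortem
temperatures. `thermomri` implements a complete, tested analysis pipeline
for this problem, aimed at forensic-imaging and qMRI researchers who need
to correct post mortem quantitative parameters for temperature:

1. **Simulation** (`thermomri.synth`) — a labeled nested-compartment brain
   phantom (white matter, cortex, four deep-gray nuclei, CSF) with
   voxel-wise multi-contrast signals under Rician noise, and synthetic
   cohorts of 16 post mortem subjects (brain temperatures from a truncated
   normal, 12.7 ± 5.7 °C on [5.6, 28.1]) plus 4 in vivo subjects at
   36.5 °C.
2. **Relaxometry** (`thermomri.relaxfit`) — voxel-wise two-parameter
   mono-exponential fits S = S₀·exp(−TE/T2) for T2 and T2*, and the
   three-parameter inversion-recovery fit

       S = M₀ · exp(−TE/T2) · (1 − p·exp(−TI/T1) + exp(−TR/T1))

   where the factor *p* absorbs B1 errors from imperfect 180° inversion
   (p = 2 is perfect inversion). Magnitude IR data are polarity-restored
   by exhaustive prefix search.
3. **Diffusion** (`thermomri.dtifit`) — log-linear OLS tensor estimation
   from single-shell DWI (b = 2000 s/mm², 64 directions + 3 b=0), with
   MD = tr(D)/3 and FA = √(3/2)·‖λ − MD‖/‖λ‖.
4. **Region aggregation** (`thermomri.regions`) — exclusion of
   partial-volume voxels (fraction < 1), Otsu thresholding of parameter
   maps (maximizing between-class variance) to remove residual
   contamination, and per-subject region means.
5. **Temperature modelling** (`thermomri.thermal`) — linear models
   y = a + b·T per region × parameter, fitted once with and once without
   the in vivo subjects (OLS, t-based 95% CIs, adjusted R², Pearson p),
   the percentage-difference statistics Δ\* (in vivo mean vs
   post-mortem-only prediction at 36.5 °C) and Δ\*\* (4 °C vs 36.5 °C
   model values), and temperature correction
   value + b·(T_ref − T_meas). Published model coefficients for
   7 regions × 5 parameters × 2 fit variants ship as packaged data.

A discrepancy between the two fit variants at 36.5 °C flags physiological
post mortem effects beyond temperature — most prominently the ~50% MD drop
attributed to cessation of perfusion and active diffusion.

## Worked example

```python
import numpy as np
from thermomri import (default_protocol, synth, fit_t1_ir,
                       model_from_coefficients, correct_to_temperature,
                       delta_double_star)

proto = default_protocol()
ti = np.asarray(proto.ti_list)                      # 30 ... 1200 ms

# simulate a magnitude IR-SE curve and refit it
s = synth.simulate_ir_se_signal(1000, 2.0, 600, 80, ti, proto.ir_te, proto.ir_tr)
fit = fit_t1_ir(np.abs(s), ti, proto.ir_te, proto.ir_tr, t2_voxel=80.0)
print(fit.params)
# {'m0': 1000.0000000000639, 'p': 1.99999999999992, 't1': 600.0000000000435}

# temperature-correct a white-matter T2 of 100 ms measured at 10 °C
m = model_from_coefficients("white_matter", "T2", "without_invivo")
print(correct_to_temperature(100.0, 10.0, 36.5, m))   # 84.1 ms
print(delta_double_star(m))                           # 23.35 (% change 4 vs 36.5 °C)
```

The corrected value 84.1 ms is what this white-matter T2 would read at in
vivo temperature: the post-mortem-only slope is −0.6 ms/°C, so warming by
26.5 °C lowers T2 by 15.9 ms.

The full synthetic study is driven by the numbered scripts under
`analysis/` (simulate → fit maps → summarize regions → fit temperature
models → validate coefficients → correct), each writing its tables to
`results/`. A 20³ phantom at 5.6 °C with 0.5% noise recovers T2 with
0.72% median voxel error, and region means land within ~1% of the
generating model values for the large regions; the cohort stage recovers
the generating slope inside the fitted 95% CI for 34/35 region × parameter
fits. The same pipeline is available as a CLI
(`thermomri simulate|fit|summarize|thermal-fit|correct|validate|run-all`).

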