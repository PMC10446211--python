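# delaypop

Population coding under axonal conduction delays.

Postsynaptic neurons integrate spikes from presynaptic populations that
cover space: signals from the near edge of a receptive field arrive
earlier than from the far edge, and the spread of arrival times grows
with population size, cell density and axonal conduction velocity.
`delaypop` provides the full analysis chain for asking how population
size, response heterogeneity and conduction-delay spread shape the
stimulus information carried by a converging population — developed for
the p-type electroreceptor afferents (P-units) of the weakly electric
fish *Apteronotus leptorhynchus*, but applicable to any converging
sensory array.

The package contains

- **spike-train metrics** — Gaussian-kernel firing rates, vector
  strength ρ = |Σⱼ exp(−i 2π tⱼ/Tⱼ)| / n, CV of interspike intervals,
  burst fraction, response modulation σ_mod and across-trial
  variability σ_psth, spike-triggered averages and STA delays;
- **spectral information estimates** — Welch cross-spectra, transfer
  function H(f) = P_sr/P_ss, squared coherence
  γ²(f) = |P_sr|²/(P_ss P_rr), and the coherence-based lower bound on
  the mutual information rate, MI = −∫ log₂(1 − γ²(f)) df (bit/s);
- **population assembly** — homogeneous populations (repeated trials of
  one cell) and heterogeneous populations (single trials of distinct
  cells, aligned to the stimulus via their STA delays), rigid
  per-member Gaussian delay injection (sd σ_delay), MI-vs-size curves,
  matched-modulation comparisons, and the σ_delay × σ_kernel filter
  grid that contrasts conduction delays with synaptic low-pass
  filtering;
- **localization & velocity** — receptor-position estimation from
  dipole-scan response powers (Gaussian fit), K-means phase clustering
  with 2π unwrapping, and conduction-velocity estimation as the inverse
  slope of the delay-vs-position regression;
- **a delayed LIF population simulator** — dimensionless leaky
  integrate-and-fire neurons, τ_m dV/dt = −V + I_offset + I_stim +
  √(2D) ξ(t), arranged on a 1-D array with finite conduction velocity,
  for mapping MI against population size, velocity and stimulus band;
- **a synthetic P-unit generator** — surrogate encoders driven by the
  rectified carrier scaled by the amplitude-modulation envelope, with
  calibrated heterogeneity and known ground-truth receptor positions
  and conduction velocity, so every analysis stage is testable without
  electrophysiological recordings.

## Worked example

```python
import numpy as np
import delaypop as dp
from delaypop import population as pop

# a synthetic 20-cell study: frozen 0-300 Hz AM noise at 10 % contrast,
# 8 repetitions per cell, ground-truth conduction velocity 47.2 m/s
study = dp.generate_study(
    n_cells=20, velocity=47.2, seed=11, n_trials=8,
    stimulus=dp.StimulusSpec(10.0, 20000.0, 0.0, 300.0, 1.0, 42),
)

# single-cell information
cell = study.cells[0]
avg = dp.average_rate(cell.driven_trials, kernel_sigma=1e-3)
coh = dp.coherence(study.stimulus, [avg.rate], nperseg=2**14)
print(round(dp.lower_bound_mi(coh, 0.0, 300.0), 1))   # 616.5 bit/s

# delay filtering: 20-cell heterogeneous populations
cells = {c.cell_id: c.driven_trials for c in study.cells}
store = pop.trial_store(study)
align = pop.alignment_delays(study)
asm = pop.assemble_heterogeneous(cells, size=20, n_populations=1,
                                 seed=5, align=align)[0]
for sigma in (0.0, 2e-3):
    a = pop.inject_delays(asm, pop.DelaySpec(sigma, seed=900))
    rate = pop.population_response(a, store)
    c = dp.coherence(study.stimulus, [rate.rate], nperseg=2**14)
    print(round(sigma * 1e3, 1), round(dp.lower_bound_mi(c, 0.0, 300.0), 1))
# 0.0 909.0   <- delay-compensated population
# 2.0 355.9   <- 2 ms delay spread filters away most information
```

The first number is the lower-bound mutual information of one cell
about the amplitude-modulation stimulus; the following two lines show
the population MI without and with an injected 2 ms conduction-delay
spread — the delay spread acts as a low-pass information filter.

A command-line interface wraps the stages for file-based pipelines:

```bash
delaypop synth --config cfg.yaml --out study/
delaypop characterize --study study/ --out results/
delaypop velocity --study study/ --out results/
delaypop lifsweep --config lif.yaml --out results/sweep.csv
delaypop report --out results/
```

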