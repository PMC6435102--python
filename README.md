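# hpbrain

Quantitative analysis of dynamic hyperpolarized [1-¹³C]pyruvate brain MRI.

Hyperpolarized ¹³C MRI follows an injected bolus of [1-¹³C]pyruvate through
the brain and watches its enzymatic conversion to [1-¹³C]lactate (LDH) and
[¹³C]bicarbonate (PDH) in real time. The signal is transient — the
polarization decays with an effective T1 of tens of seconds — so the whole
measurement is a single 60-second dynamic acquisition, and quantification
must extract metabolic rate constants from roughly fifteen time points.

`hpbrain` implements the full quantitative chain used in clinical
neuroimaging studies of this kind, exercised end-to-end on a synthetic
digital brain phantom with known ground truth:

1. **Simulation** (`hpbrain.synth`) — three-pool exchange dynamics
   (pyruvate → lactate, pyruvate → bicarbonate) driven by a gamma-variate
   arterial input, integrated exactly with per-excitation matrix-exponential
   updates; a digital phantom mixing gray/white-matter kinetics into
   multi-echo complex image stacks with a B₀ map, RF depletion, and complex
   Gaussian noise.
2. **IDEAL reconstruction** (`hpbrain.ideal`) — chemical-shift decomposition
   of echo-shifted acquisitions into per-metabolite images by least squares,
   with per-voxel B₀ demodulation.
3. **Kinetic modelling** (`hpbrain.kinetics`) — apparent exchange rates kPL
   and kPB and the effective relaxation time T1eff by *linear*
   frequency-domain least squares (exponential-prefilter formulation with
   pyruvate-derived instrumental variables), an independent nonlinear
   time-domain oracle, and model-free AUC-ratio / time-to-peak metrics.
4. **Spatial analysis** (`hpbrain.spatial`) — chemical-shift displacement of
   each metabolite's excitation slab, displacement-aware projection of tissue
   probability maps, conservative binary masks (probability > 0.60 for *all*
   metabolites), peak-pyruvate-normalised metabolite maps, ratio maps, ROI
   statistics, and paired gray-vs-white Wilcoxon tests with Bonferroni
   correction.
5. **B₁ calibration** (`hpbrain.b1map`) — per-voxel flip-angle scale by
   fitting |S₀ sin(κθ)| to a variable-flip-angle series.
6. **Pipeline & CLI** (`hpbrain.pipeline`, `hpbrain.cli`) — a reproducible
   simulate → reconstruct → segment → fit → report chain with validated YAML
   configuration, provenance sidecars, and byte-deterministic outputs.

## Quick start

Run the whole chain on the default digital phantom:

```bash
hpbrain run-all --seed 42 --out run42
```

This writes echo stacks, metabolite images, masks, kPL/kPB maps, normalised
and ratio maps, time-course CSVs, `report.csv` (mean ± SD of kPL, kPB,
lac:pyr, bic:pyr, bic:lac per ROI), `gray_white_tests.csv`, figures, and a
structured `log.txt`. Re-running with the same config and seed reproduces
every CSV byte for byte.

## Worked example (Python API)

```python
import numpy as np
from hpbrain import (AcquisitionProtocol, AifParams, KineticParams,
                     simulate_dynamics, fit_kpl_freq)
from hpbrain.protocol import default_basis
from hpbrain.synth import default_phantom_spec, make_phantom_dataset
from hpbrain.ideal import decompose

# 1. Ground-truth dynamics: kPL = 0.012 s^-1, T1eff = 26 s
protocol = AcquisitionProtocol()          # TR 0.5 s, 15 frames @ 4 s, FA 15
params = KineticParams(k_pl=0.012, k_pb=0.002,
                       rho_p=1/26, rho_l=1/26, rho_b=1/26)
dyn = simulate_dynamics(params, protocol, AifParams())

# 2. Fit the frequency-domain linear estimator
fit = fit_kpl_freq(dyn.pyruvate, dyn.lactate, dyn.frame_times)
print(fit.rate, fit.t1_eff)               # ~0.012, ~26.0

# 3. Full phantom: multi-echo stacks -> IDEAL -> per-voxel maps
basis = default_basis()
spec = default_phantom_spec(noise_sigma=0.02)
ds = make_phantom_dataset(spec, protocol, basis, seed=7)
dmi, residual = decompose(ds.stacks[1], basis, use_b0=True)
lac = dmi.series("lactate")               # mean lactate time course
```

## Why a linear frequency-domain fit?

Differentiating 15 noisy samples is hopeless. Instead, convolving the rate
equation dL/dt = kPL·P − ρ·L with e^(−λt) turns it into an exact algebraic
relation between smoothed integrals of the data, linear in (kPL, ρ). Solving
its normal equations on the DFTs of the regressors — projected onto
pyruvate-derived instruments so lactate noise never appears on both sides —
gives an estimator that recovers noiseless rates to ~10⁻⁴ relative, matches
the nonlinear time-domain oracle to ~10⁻⁸, and keeps the median kPL error
near 2% at peak-pyruvate SNR 10. See `docs/methods.md` for the derivation.

## Testing

```bash
pytest                                  # full suite, ~10 s
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(noiseless kPL/kPB/T1eff recovery, regional contrast at SNR 20, B₁ ratio);
the remaining suites cover round-trip exactness, B₀ invariance, conservation
laws, estimator equivalence, mask semantics, statistics, and pipeline
determinism, including hypothesis property tests.
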