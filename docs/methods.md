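# Methods

This note records the quantitative conventions and derivations behind
`hpbrain`, in the order data flows through the pipeline.

## 1. Acquisition model

The default protocol is a dynamic slab-selective ¹³C acquisition at 3 T:
repetition time 0.5 s, one image frame every 4 s (eight excitations per
frame), 15° nominal flip angle, 15 frames over 60 s, 30 mm axial slabs, and
seven echo-shifted acquisitions spaced 1.1 ms apart. The metabolite basis
places pyruvate on resonance (171 ppm) with lactate at 183 ppm and
bicarbonate at 161 ppm; offsets convert to Hz via
f = (ppm − 171)·10⁻⁶·γ·B₀ with γ(¹³C) = 10.7084 MHz/T, giving ±385.5 Hz and
−321.3 Hz at 3 T.

## 2. Exchange dynamics and simulation

Label flux follows irreversible two-site exchange out of pyruvate:

    dP/dt = u(t) − (ρ_P + kPL + kPB)·P
    dL/dt = kPL·P − ρ_L·L
    dB/dt = kPB·P − ρ_B·B

Each ρ is an *effective* decay (1/T1eff) lumping spin–lattice relaxation,
back-conversion, and — when not simulated explicitly — RF losses. The
arterial input u(t) is a gamma-variate, a·((t−t₀)r/s)^s·e^(s−r(t−t₀)), with
onset 4 s, shape 3, rate 0.75 s⁻¹ (bolus mode 8 s after imaging starts).

The linear system is integrated exactly: with the input held constant over
each RF interval (zero-order hold), the augmented matrix exponential
exp([[A·dt, b·dt],[0,0]]) yields the exact state transition and input
response per excitation. With all ρ = 0 the totals conserve the input
integral to machine precision (a test asserts ≤1e-9). Optional RF depletion
multiplies all pools by cos(FA) per excitation; since the factor is common
to every pool it adds −ln(cos FA)/TR to the *fitted* decay without biasing
exchange rates (verified numerically to 0.07%).

## 3. IDEAL decomposition

Echo-shifted images follow s(t_e) = Σ_m ρ_m·exp(i2π(f_m + Δf₀)t_e). The
encoding matrix A[e,m] = exp(i2π·f_m·t_e) is inverted by pseudo-inverse;
static off-resonance Δf₀ is removed per voxel by demodulating the echoes
with exp(−i2π·Δf₀·t_e) before the (single, shared) inversion — algebraically
identical to folding Δf₀ into A. Rank-deficient configurations raise with
the condition number; condition numbers above 1e6 warn. Noiseless
round-trips are exact to ~1e-12 and decompositions are invariant to B₀
offsets within ±30 Hz to ≤1e-8 (tested). Optional exponential apodization
multiplies echoes by exp(−π·lb·t_e), adding lb Hz of absorption-mode
Lorentzian linewidth.

## 4. Kinetic rate estimation

### Frequency-domain linear fit (primary)

Convolving dL/dt = k·P − ρ·L with e^(−λt) (integration by parts) gives, for
any λ > 0, the exact relation

    L(t) − L(0)e^(−λt) = k·(Φ_λP)(t) + (λ − ρ)·(Φ_λL)(t),

where (Φ_λf)(t) = ∫₀ᵗ e^(−λ(t−s)) f(s) ds. The series are cubic-spline
oversampled (×64) and Φ_λ is evaluated by its exact first-order-hold
recursion (an IIR filter). Three refinements:

* **Instrumental variables.** Φ_λL shares the noise of the response L, which
  biases ordinary least squares toward zero. The normal equations are
  projected onto the pyruvate-derived instruments [Φ_λP, Φ_λ²P], which are
  uncorrelated with lactate noise.
* **Filter matching.** λ is iterated toward the fitted ρ̂ (three fixed-point
  rounds, clipped to [1/60, 0.5] s⁻¹), which minimises residual structure.
* **Frequency domain.** The system is solved on the DFTs of regressors and
  response. The DFT is unitary up to a common scale, so the solution equals
  the time-domain least squares exactly while making the weighting across
  temporal frequencies explicit.

Measured performance at the default protocol: noiseless recovery of
kPL = 0.012, kPB = 0.002 and T1eff = 26 s to ~5×10⁻⁵ relative; agreement
with the time-domain oracle to ~10⁻⁹ over a (k, ρ) grid; median kPL error
~2% at peak-pyruvate SNR 10 over 200 replicates.

### Time-domain oracle

An independent check fits L(t) = k·∫ e^(−ρ(t−s)) P(s) ds by bounded
trust-region nonlinear least squares from three decay starting points.

### Model-free metrics

The AUC ratio Σ|L| / Σ|P| tends to k/ρ as the window grows (for equal
relaxation); time-to-peak is the frame time of the magnitude maximum.

## 5. Spatial analysis

Slab selection maps frequency to position: a resonance offset Δf is excited
at a slab displaced by Δz = Δf/(γ·G_ss). With G_ss = 3.6 mT/m at 3 T the
lactate slab sits 10.0 mm above the pyruvate slab and bicarbonate 8.3 mm
below. Tissue probability maps on a thin-slice grid are therefore projected
(mean over covered slice centres, half-open interval) onto each metabolite's
*displaced* slab, and a voxel enters a tissue mask only when its probability
exceeds 0.60 (strict) for **all** metabolites — a conservative intersection
that guarantees every metabolite's signal in a masked voxel comes from the
nominal tissue.

Metabolite maps are summed over frames in the complex domain, magnitudes
taken, and normalised to the peak pyruvate voxel inside the brain mask.
Ratio maps (lac:pyr, bic:pyr, bic:lac) carry NaN where the denominator is
non-positive; NaNs are excluded from all summaries. ROI statistics pool
voxels across slabs/datasets and report mean ± SD in a fixed schema
(k_pl, k_pb, lac:pyr, bic:pyr, bic:lac). Gray-vs-white contrasts use the
Wilcoxon signed-rank test (exact null for ≤25 pairs without zeros/ties,
normal approximation otherwise) with Bonferroni adjustment
p_adj = min(1, p·n).

## 6. B₁ calibration

A variable-flip-angle series at angles 70–180° in 10° steps follows
S(θ) = S₀·sin(κθ). Because magnitude images cannot go negative and the sine
crosses zero within the ladder when κ > 1, the fitted model is
|S₀·sin(κθ)|, solved by bounded nonlinear least squares (κ ∈ (0, 2]) from
three starting points. κ is reported as a percentage of nominal flip angle;
all-zero voxels yield NaN.

## 7. Digital phantom

The default phantom is a three-slab disk: a white-matter core inside a
gray-matter rim on a (30, 24, 24) thin-slice grid (5 mm slices), constant
in-plane anatomy across slices, a smooth in-plane B₀ map (±20 Hz), Table-style
tissue kinetics (gray kPL 0.011, white 0.012, kPB 0.002, T1eff 26 s), RF
depletion on, and per-metabolite chemical-shift-displaced slab projections
feeding the forward IDEAL model. Noise is i.i.d. Gaussian with standard
deviation σ in the real and imaginary channel of every echo sample; SNR is
defined as peak noiseless pyruvate amplitude divided by σ. A two-compartment
variant (homogeneous rectangular blocks, constant along z) supports regional
recovery experiments where each compartment's ground truth is known exactly.

## 8. Reproducibility

All randomness flows from a single seed (numpy `default_rng`; replicate
seeds via `SeedSequence`). CSV output uses a fixed float format and line
terminator, making reruns byte-identical. Every pipeline output carries a
provenance sidecar (config hash, seed, software version), and each stage
logs structured lines with data hashes.
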