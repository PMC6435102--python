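"""Digital phantom generation for dynamic hyperpolarized pyruvate imaging.

The generator produces everything the analysis chain consumes, with known
ground truth: per-tissue metabolite time courses from a three-pool exchange
model driven by a gamma-variate arterial input, mixed into image space by
tissue probability, encoded into echo-shifted complex images through the
forward IDEAL model (with a B0 map), and corrupted by complex Gaussian noise.

Exchange model
--------------
Label flux follows irreversible two-site exchange out of the pyruvate pool::

    dP/dt = u(t) - (rho_p + k_pl + k_pb) P
    dL/dt = k_pl P - rho_l L
    dB/dt = k_pb P - rho_b B

where ``u`` is the arterial input rate and each ``rho`` is an effective decay
rate (1/T1eff) lumping spin-lattice relaxation, back conversion and -- unless
RF depletion is simulated explicitly -- RF losses.  The system is integrated
exactly with one matrix-exponential update per RF excitation (zero-order-hold
input), so conservation of total label holds to machine precision when all
decay rates are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
from scipy.linalg import expm
from scipy.ndimage import gaussian_filter

from hpbrain.protocol import AcquisitionProtocol, MetaboliteBasis, GAMMA_13C_HZ_PER_T, default_basis
from hpbrain.ideal import EchoImageStack, synthesize_echoes
from hpbrain.spatial import (
    TissueProbabilityVolume,
    chemical_shift_displacement,
    project_probability,
)


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth exchange and effective decay rates (all s^-1).

    ``rho_*`` are effective decay rates, the inverse of the corresponding
    T1eff; they lump spin-lattice relaxation, back conversion (kLP) and,
    when RF depletion is not simulated explicitly, RF losses.
    """

    k_pl: float = 0.012
    k_pb: float = 0.002
    rho_p: float = 1 / 26.0
    rho_l: float = 1 / 26.0
    rho_b: float = 1 / 10.0

    def __post_init__(self):
        for name in ("k_pl", "k_pb", "rho_p", "rho_l", "rho_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def t1_eff_lactate(self) -> float:
        return 1.0 / self.rho_l if self.rho_l > 0 else np.inf

    @property
    def t1_eff_bicarbonate(self) -> float:
        return 1.0 / self.rho_b if self.rho_b > 0 else np.inf


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate arterial input: ``u(t) = a ((t')r/s)^s exp(s - r t')``.

    with ``t' = t - delay`` (zero before arrival).  ``shape``/``rate`` are the
    gamma-variate exponent and decay rate, so the analytic mode sits at
    ``delay + shape/rate``; ``amplitude`` is the peak input rate.  Defaults
    put the bolus peak 8 s after the start of imaging, consistent with a
    pyruvate injection finishing ~10 s before acquisition.
    """

    delay: float = 4.0
    shape: float = 3.0
    rate: float = 0.75
    amplitude: float = 1.0

    def __post_init__(self):
        if self.shape < 0 or self.rate < 0 or self.amplitude < 0:
            raise ValueError("AIF shape, rate and amplitude must be >= 0")
        if self.delay < 0:
            raise ValueError("AIF delay must be >= 0")


def make_aif(aif_params: AifParams, time_axis: np.ndarray) -> np.ndarray:
    """Evaluate the gamma-variate input rate on a time axis (s).

    The series is zero before the arrival delay, non-negative, and peaks at
    ``amplitude`` at the analytic mode ``delay + shape/rate``.
    """
    t = np.asarray(time_axis, dtype=float)
    if t.ndim != 1 or len(t) == 0:
        raise ValueError("time_axis must be a non-empty 1-D array")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("time_axis must be strictly increasing")
    if t[0] < 0:
        raise ValueError("time_axis must start at >= 0")
    p = aif_params
    tt = t - p.delay
    out = np.zeros_like(t)
    pos = tt > 0
    if p.amplitude == 0 or p.shape == 0 and p.rate == 0:
        return out
    x = tt[pos] * p.rate / max(p.shape, np.finfo(float).tiny)
    out[pos] = p.amplitude * x ** p.shape * np.exp(p.shape - p.rate * tt[pos])
    return out


@dataclass
class DynamicsResult:
    """Sampled metabolite time courses from the exchange model."""

    pyruvate: np.ndarray
    lactate: np.ndarray
    bicarbonate: np.ndarray
    frame_times: np.ndarray
    cumulative_input: np.ndarray

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {"pyruvate": self.pyruvate, "lactate": self.lactate,
                "bicarbonate": self.bicarbonate}


AifLike = Union[AifParams, Callable[[np.ndarray], np.ndarray], np.ndarray]


def _aif_on_grid(aif: AifLike, fine_times: np.ndarray, protocol: AcquisitionProtocol,
                 substeps: int) -> np.ndarray:
    if isinstance(aif, AifParams):
        return make_aif(aif, fine_times)
    if callable(aif):
        return np.asarray(aif(fine_times), dtype=float)
    arr = np.asarray(aif, dtype=float)
    if arr.shape != (protocol.n_frames,):
        raise ValueError("array AIF must have one value per frame")
    return np.repeat(arr, substeps)[: len(fine_times)]


def simulate_dynamics(params: KineticParams, protocol: AcquisitionProtocol,
                      aif: AifLike, rf_depletion: bool = False,
                      substeps: Optional[int] = None) -> DynamicsResult:
    """Integrate the three-pool exchange model over the acquisition.

    The input is held constant over each integration substep (one substep per
    RF excitation by default) and the linear system is advanced with the exact
    matrix exponential, so the sampled frames are exact for the zero-order-hold
    input.  With ``rf_depletion`` every excitation multiplies all pools by
    ``cos(flip_angle)``; since the loss is common to all pools it lumps into
    the fitted effective decay without affecting exchange rates.

    Returns the frame-sampled longitudinal magnetizations (the constant
    receive scale ``sin(flip_angle)`` is omitted; rate estimates are scale
    invariant) together with the cumulative input integral at each frame.
    """
    if protocol.frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    n = protocol.n_frames
    substeps = substeps or protocol.excitations_per_frame
    dtf = protocol.frame_interval / substeps
    n_fine = (n - 1) * substeps
    fine_times = np.arange(n_fine) * dtf
    u = _aif_on_grid(aif, fine_times, protocol, substeps)
    if np.any(u < 0):
        raise ValueError("AIF rate series must be non-negative")

    A = np.array([
        [-(params.rho_p + params.k_pl + params.k_pb), 0.0, 0.0],
        [params.k_pl, -params.rho_l, 0.0],
        [params.k_pb, 0.0, -params.rho_b],
    ])
    # augmented exponential gives the exact zero-order-hold input response
    M = np.zeros((4, 4))
    M[:3, :3] = A * dtf
    M[:3, 3] = [dtf, 0.0, 0.0]
    E = expm(M)
    F, G = E[:3, :3], E[:3, 3]
    deplete = np.cos(np.deg2rad(protocol.flip_angle)) ** (
        protocol.excitations_per_frame / substeps) if rf_depletion else 1.0

    x = np.zeros(3)
    frames = np.zeros((n, 3))
    cum = np.zeros(n)
    total_in = 0.0
    for j in range(n_fine):
        x = F @ x + G * u[j]
        if rf_depletion:
            x = x * deplete
        total_in += u[j] * dtf
        if (j + 1) % substeps == 0:
            frames[(j + 1) // substeps] = x
            cum[(j + 1) // substeps] = total_in
    return DynamicsResult(pyruvate=frames[:, 0], lactate=frames[:, 1],
                          bicarbonate=frames[:, 2],
                          frame_times=protocol.frame_times,
                          cumulative_input=cum)


@dataclass
class PhantomSpec:
    """Geometry, tissue composition and ground truth of a digital phantom.

    ``tissue_probability`` maps tissue name to a ``(nz, ny, nx)`` probability
    volume on the thin-slice grid; ``tissue_kinetics`` gives the ground-truth
    kinetics of each named tissue.  An optional ``brain`` entry in the
    probability dict marks overall brain tissue (defaults to the clipped sum
    of the named tissues).  ``field_map`` is the per-voxel B0 offset in Hz,
    shared by all slabs (``(ny, nx)``) or per slab (``(n_slabs, ny, nx)``).
    """

    grid_shape: Tuple[int, int, int]
    thin_slice_thickness: float
    tissue_probability: Dict[str, np.ndarray]
    tissue_kinetics: Dict[str, KineticParams]
    slab_centers: Tuple[float, ...]
    field_map: Optional[np.ndarray] = None
    aif_params: AifParams = field(default_factory=AifParams)
    noise_sigma: float = 0.0

    def __post_init__(self):
        nz, ny, nx = self.grid_shape
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.thin_slice_thickness <= 0:
            raise ValueError("thin_slice_thickness must be > 0")
        total = np.zeros(self.grid_shape)
        for name, vol in self.tissue_probability.items():
            vol = np.asarray(vol, dtype=float)
            if vol.shape != self.grid_shape:
                raise ValueError(f"tissue volume {name!r} shape mismatch")
            if np.any(vol < 0) or np.any(vol > 1):
                raise ValueError(f"tissue probabilities {name!r} outside [0, 1]")
            self.tissue_probability[name] = vol
            if name != "brain":
                total += vol
        if np.any(total > 1 + 1e-9):
            raise ValueError("summed tissue probabilities exceed 1")
        for name in self.tissue_kinetics:
            if name not in self.tissue_probability:
                raise ValueError(f"kinetics given for unknown tissue {name!r}")
        if self.field_map is not None:
            fm = np.asarray(self.field_map, dtype=float)
            if fm.shape not in ((ny, nx), (len(self.slab_centers), ny, nx)):
                raise ValueError("field_map shape mismatch")
            self.field_map = fm

    @property
    def kinetic_tissues(self) -> List[str]:
        return list(self.tissue_kinetics)

    def to_volume(self) -> TissueProbabilityVolume:
        data = dict(self.tissue_probability)
        if "brain" not in data:
            total = sum(np.asarray(v) for n, v in data.items())
            data["brain"] = np.clip(total, 0.0, 1.0)
        return TissueProbabilityVolume(
            data=data, thin_slice_thickness=self.thin_slice_thickness)

    def field_map_for_slab(self, s: int) -> Optional[np.ndarray]:
        if self.field_map is None:
            return None
        return self.field_map if self.field_map.ndim == 2 else self.field_map[s]


@dataclass
class PhantomDataset:
    """A generated phantom: echo stacks per slab plus ground truth."""

    stacks: List[EchoImageStack]
    truth: Dict[str, object]
    protocol: AcquisitionProtocol
    basis: MetaboliteBasis
    seed: Optional[int]


def metabolite_displacements(protocol: AcquisitionProtocol,
                             basis: MetaboliteBasis) -> Dict[str, float]:
    """Chemical-shift displacement (m) of each basis species' excited slab."""
    return {
        name: chemical_shift_displacement(
            f, GAMMA_13C_HZ_PER_T, protocol.slice_select_gradient)
        for name, f in zip(basis.names, basis.frequencies_hz)
    }


def make_phantom_dataset(spec: PhantomSpec, protocol: AcquisitionProtocol,
                         basis: MetaboliteBasis, seed: Optional[int] = None,
                         rf_depletion: bool = True,
                         apply_csd: bool = True) -> PhantomDataset:
    """Generate echo-shifted complex image stacks with known ground truth.

    Per-tissue time courses are mixed by the tissue probabilities projected
    onto each metabolite's (displacement-offset, when ``apply_csd``) slab,
    encoded into echoes through the forward IDEAL model with the phantom's
    field map, and corrupted by i.i.d. Gaussian noise of standard deviation
    ``noise_sigma`` in the real and imaginary channels of every echo sample.
    """
    protocol.validate_basis(basis)
    rng = np.random.default_rng(seed)
    courses = {
        t: simulate_dynamics(kp, protocol, spec.aif_params,
                             rf_depletion=rf_depletion)
        for t, kp in spec.tissue_kinetics.items()
    }
    vol = spec.to_volume()
    displacements = (metabolite_displacements(protocol, basis)
                     if apply_csd else {name: 0.0 for name in basis.names})
    nz, ny, nx = spec.grid_shape
    n_frames = protocol.n_frames
    met_index = {name: i for i, name in enumerate(basis.names)}

    stacks, truth_slabs = [], []
    for s, z_center in enumerate(spec.slab_centers):
        met_images = np.zeros((len(basis), n_frames, ny, nx))
        weights = {}
        for name in basis.names:
            proj = project_probability(vol, z_center, protocol.slice_thickness,
                                       displacements[name])
            weights[name] = proj
            img = np.zeros((n_frames, ny, nx))
            for tissue in spec.kinetic_tissues:
                series = courses[tissue].as_dict().get(name)
                if series is None:
                    continue  # species not produced by the exchange model
                img += series[:, None, None] * proj[tissue][None]
            met_images[met_index[name]] = img
        fm = spec.field_map_for_slab(s)
        echoes = synthesize_echoes(met_images, basis,
                                   np.asarray(protocol.echo_shifts), fm)
        if spec.noise_sigma > 0:
            noise = rng.normal(scale=spec.noise_sigma, size=echoes.shape + (2,))
            echoes = echoes + noise[..., 0] + 1j * noise[..., 1]
        stacks.append(EchoImageStack(
            data=echoes, echo_shifts=np.asarray(protocol.echo_shifts),
            frame_times=protocol.frame_times, field_map=fm))
        truth_slabs.append({
            "metabolite_images": met_images,
            "tissue_weights": weights,
        })
    kpl_maps = [
        sum(slab["tissue_weights"]["pyruvate"][t] * spec.tissue_kinetics[t].k_pl
            for t in spec.kinetic_tissues)
        for slab in truth_slabs
    ]
    truth = {
        "tissue_kinetics": dict(spec.tissue_kinetics),
        "courses": courses,
        "slabs": truth_slabs,
        "kpl_maps": kpl_maps,
        "displacements": displacements,
    }
    return PhantomDataset(stacks=stacks, truth=truth, protocol=protocol,
                          basis=basis, seed=seed)


def two_compartment_spec(kinetics_a: KineticParams, kinetics_b: KineticParams,
                         noise_sigma: float = 0.0,
                         grid: Tuple[int, int, int] = (24, 16, 16),
                         thin_slice_thickness: float = 0.005) -> PhantomSpec:
    """Single-slab phantom with two homogeneous rectangular compartments.

    Compartment ``a`` occupies the upper block of the image plane and ``b``
    the lower one, both with probability 1 and constant along z, so tissue
    projections are unaffected by chemical-shift displacement and each
    compartment's recovered kinetics can be compared against its ground truth
    directly.  A smooth in-plane B0 gradient (+-15 Hz) is included.
    """
    nz, ny, nx = grid
    vol_a = np.zeros(grid)
    vol_b = np.zeros(grid)
    vol_a[:, 2:ny // 2 - 1, 2:nx - 2] = 1.0
    vol_b[:, ny // 2 + 1:ny - 2, 2:nx - 2] = 1.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    b0 = 15.0 * (xx - (nx - 1) / 2) / max((nx - 1) / 2, 1)
    return PhantomSpec(
        grid_shape=grid,
        thin_slice_thickness=thin_slice_thickness,
        tissue_probability={"a": vol_a, "b": vol_b},
        tissue_kinetics={"a": kinetics_a, "b": kinetics_b},
        slab_centers=(nz * thin_slice_thickness / 2,),
        field_map=b0,
        aif_params=AifParams(),
        noise_sigma=noise_sigma,
    )


def default_phantom_spec(noise_sigma: float = 0.0,
                         grid: Tuple[int, int, int] = (30, 24, 24),
                         thin_slice_thickness: float = 0.005,
                         b0_amplitude_hz: float = 20.0) -> PhantomSpec:
    """Three-slab brain-like phantom with Table-style gray/white kinetics.

    The in-plane anatomy is a smoothed disk: a white-matter core surrounded by
    a gray-matter rim inside a brain mask, constant across thin slices (the
    point is the analysis chain, not anatomy).  The B0 map is a smooth
    in-plane gradient scaled to ``±b0_amplitude_hz``.
    """
    nz, ny, nx = grid
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    r = np.hypot(yy - cy, xx - cx)
    r_brain = 0.42 * min(ny, nx)
    r_core = 0.24 * min(ny, nx)
    white = np.where(r <= r_core, 0.92, 0.0)
    gray = np.where((r > r_core) & (r <= r_brain), 0.88, 0.0)
    white = gaussian_filter(white, 0.8)
    gray = gaussian_filter(gray, 0.8)
    overlap = gray + white
    scale = np.where(overlap > 1.0, 1.0 / np.maximum(overlap, 1e-12), 1.0)
    gray, white = gray * scale, white * scale
    gray3 = np.broadcast_to(gray, grid).copy()
    white3 = np.broadcast_to(white, grid).copy()

    b0 = b0_amplitude_hz * ((xx - cx) / max(cx, 1) * 0.7
                            + ((yy - cy) / max(cy, 1)) ** 2 * 0.3)

    slab = 0.03
    centers = tuple(0.075 + slab * k for k in (-1, 0, 1))
    kinetics = {
        "gray": KineticParams(k_pl=0.011, k_pb=0.002,
                              rho_p=1 / 26, rho_l=1 / 26, rho_b=1 / 10),
        "white": KineticParams(k_pl=0.012, k_pb=0.002,
                               rho_p=1 / 26, rho_l=1 / 26, rho_b=1 / 10),
    }
    return PhantomSpec(
        grid_shape=grid,
        thin_slice_thickness=thin_slice_thickness,
        tissue_probability={"gray": gray3, "white": white3},
        tissue_kinetics=kinetics,
        slab_centers=centers,
        field_map=b0,
        aif_params=AifParams(),
        noise_sigma=noise_sigma,
    )
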