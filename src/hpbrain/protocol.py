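"""Acquisition protocol and metabolite basis definitions.

The default protocol mirrors a clinical dynamic IDEAL spiral acquisition for
hyperpolarized [1-13C]pyruvate at 3 T: TR 0.5 s, one frame every 4 s (eight
excitations per frame), 15 degree flip angle, 15 frames over 60 s, 30 mm axial
slabs.  The default metabolite basis holds the carbonyl resonances seen in the
brain after a pyruvate injection: pyruvate (171 ppm, on resonance), lactate
(183 ppm) and bicarbonate (161 ppm); pyruvate hydrate (177 ppm) can be added
when needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Gyromagnetic ratio of carbon-13 in Hz per tesla (10.7084 MHz/T).
GAMMA_13C_HZ_PER_T = 10.7084e6


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing, excitation and slab geometry of a dynamic 13C acquisition.

    Parameters
    ----------
    repetition_time : float
        Time between successive excitations (s).
    frame_interval : float
        Time resolution of the dynamic series, i.e. one image frame every
        ``frame_interval`` seconds.
    flip_angle : float
        Nominal excitation flip angle in degrees.
    n_frames : int
        Number of dynamic frames.
    echo_shifts : tuple of float
        Echo time offsets of the chemical-shift-encoded acquisitions (s),
        strictly increasing.
    field_strength : float
        Static field strength (T).
    slice_thickness : float
        Thickness of the excited axial slab (m).
    slice_select_gradient : float
        Slice-select gradient amplitude (T/m); sets the chemical-shift
        displacement of off-resonance metabolites.
    center_frequency_ppm : float
        Chemical shift of the transmit centre frequency (ppm).
    excitations_per_frame : int
        RF excitations contributing to one frame.  Defaults to
        ``frame_interval / repetition_time``.
    """

    repetition_time: float = 0.5
    frame_interval: float = 4.0
    flip_angle: float = 15.0
    n_frames: int = 15
    echo_shifts: tuple = tuple(np.arange(7) * 1.1e-3)
    field_strength: float = 3.0
    slice_thickness: float = 0.03
    slice_select_gradient: float = 3.6e-3
    center_frequency_ppm: float = 171.0
    excitations_per_frame: int = 0  # 0 -> derived from frame_interval / TR

    def __post_init__(self):
        for name in ("repetition_time", "frame_interval", "flip_angle",
                     "field_strength", "slice_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        shifts = np.asarray(self.echo_shifts, dtype=float)
        if shifts.ndim != 1 or len(shifts) < 1:
            raise ValueError("echo_shifts must be a non-empty 1-D sequence")
        if len(shifts) > 1 and not np.all(np.diff(shifts) > 0):
            raise ValueError("echo_shifts must be strictly increasing")
        if self.excitations_per_frame == 0:
            n_exc = self.frame_interval / self.repetition_time
            if abs(n_exc - round(n_exc)) > 1e-9:
                raise ValueError(
                    "frame_interval must be an integer multiple of repetition_time"
                )
            object.__setattr__(self, "excitations_per_frame", int(round(n_exc)))
        elif self.excitations_per_frame < 1:
            raise ValueError("excitations_per_frame must be >= 1")

    @property
    def total_duration(self) -> float:
        """Total imaging duration in seconds (n_frames x frame_interval)."""
        return self.n_frames * self.frame_interval

    @property
    def frame_times(self) -> np.ndarray:
        """Frame sampling times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    @property
    def center_frequency_hz(self) -> float:
        """Absolute 13C transmit frequency (Hz) at the protocol field strength."""
        return GAMMA_13C_HZ_PER_T * self.field_strength

    def validate_basis(self, basis: "MetaboliteBasis") -> None:
        """Check that the echo schedule can encode ``basis``."""
        if len(self.echo_shifts) < len(basis.names):
            raise ValueError(
                f"{len(self.echo_shifts)} echo shifts cannot encode "
                f"{len(basis.names)} metabolites"
            )


@dataclass(frozen=True)
class MetaboliteBasis:
    """Named metabolite species with chemical shifts.

    Frequencies are derived from the ppm offsets relative to the transmit
    centre: ``f = (ppm - center_ppm) * 1e-6 * gamma * B0``, so the centre
    species is at 0 Hz and the mapping is linear in field strength.
    """

    names: tuple
    chemical_shifts_ppm: tuple
    field_strength: float = 3.0
    center_frequency_ppm: float = 171.0

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("metabolite names must be unique")
        if len(self.names) != len(self.chemical_shifts_ppm):
            raise ValueError("names and chemical_shifts_ppm differ in length")
        if self.field_strength <= 0:
            raise ValueError("field_strength must be > 0")

    @property
    def frequencies_hz(self) -> np.ndarray:
        """Resonance offsets from the transmit centre, in Hz."""
        ppm = np.asarray(self.chemical_shifts_ppm, dtype=float)
        return (ppm - self.center_frequency_ppm) * 1e-6 * GAMMA_13C_HZ_PER_T * self.field_strength

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.names)


def default_basis(field_strength: float = 3.0,
                  include_hydrate: bool = False) -> MetaboliteBasis:
    """Pyruvate / lactate / bicarbonate basis with pyruvate on resonance."""
    names = ("pyruvate", "lactate", "bicarbonate")
    shifts = (171.0, 183.0, 161.0)
    if include_hydrate:
        names = names + ("pyruvate_hydrate",)
        shifts = shifts + (177.0,)
    return MetaboliteBasis(names=names, chemical_shifts_ppm=shifts,
                           field_strength=field_strength,
                           center_frequency_ppm=171.0)
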