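"""Shared containers, acquisition protocols, and cohort-level defaults.

Everything downstream (signal generators, voxelwise fitters, the correlation
network) exchanges data through the small dataclasses defined here plus plain
numpy arrays and pandas frames.  Units are locked per quantity and noted on the
field; rates for contrast-agent and tracer kinetics are per minute, times and
water-exchange lifetimes are in seconds, diffusivities in mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "AcquisitionProtocol",
    "METRIC_NAMES",
    "FRACTION_METRICS",
    "TABLE1_MARGINALS",
    "default_dwi_protocol",
    "default_dce_protocol",
    "default_pet_protocol",
    "rng_for",
    "child_seed",
]


# --------------------------------------------------------------------------
# sampled curves
# --------------------------------------------------------------------------

@dataclass
class TimeSeries:
    """A sampled curve: DW signal over b-values, a DCE signal-time course, or a
    frame-averaged PET time-activity curve.

    ``times`` holds b-values (s/mm^2) for DWI and seconds otherwise.
    ``durations`` is the PET frame-duration vector (seconds) and ``None`` for
    the MR modalities.
    """

    times: np.ndarray
    values: np.ndarray
    durations: np.ndarray | None = None
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.durations is not None:
            self.durations = np.asarray(self.durations, dtype=float)
        if self.times.shape[0] != self.values.shape[-1]:
            raise ValueError(
                f"times ({self.times.shape[0]}) and values "
                f"({self.values.shape[-1]}) length mismatch"
            )

    @property
    def midpoints(self) -> np.ndarray:
        """Frame midpoints (equals ``times`` when there are no durations)."""
        if self.durations is None:
            return self.times
        return self.times + 0.5 * self.durations


# --------------------------------------------------------------------------
# acquisition protocols
# --------------------------------------------------------------------------

@dataclass
class AcquisitionProtocol:
    """Acquisition settings for the three modalities.

    The defaults (see the ``default_*_protocol`` constructors) reproduce the
    study protocol the package emulates: a ten-b-value EPI diffusion series, a
    3 T SPGR variable-flip-angle + 40-frame dynamic DCE series, and a 30-min
    dynamic PET acquisition followed by two late static frames.
    """

    b_values: np.ndarray = field(default_factory=lambda: np.array([]))
    n_averages: int = 1
    tr_ms: float = 7.0
    te_ms: float = 2.7
    flip_angles_deg: tuple[float, ...] = (5.0, 15.0, 30.0)
    dynamic_flip_deg: float = 15.0
    n_dynamics: int = 40
    dt_dynamic_s: float = 8.0
    n_precontrast: int = 6
    pet_frame_schedule: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))
    static_times_min: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.b_values.size:
            if np.any(self.b_values < 0):
                raise ValueError("b-values must be nonnegative")
            if np.any(np.diff(self.b_values) <= 0):
                raise ValueError("b-values must be strictly ascending")
        self.pet_frame_schedule = np.asarray(self.pet_frame_schedule, dtype=float)
        if self.pet_frame_schedule.size:
            starts = self.pet_frame_schedule[:, 0]
            ends = starts + self.pet_frame_schedule[:, 1]
            if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < ends[:-1] - 1e-9):
                raise ValueError("PET frame schedule must be ascending and non-overlapping")

    @property
    def dynamic_times_s(self) -> np.ndarray:
        """DCE frame acquisition times (frame midpoints), seconds."""
        return (np.arange(self.n_dynamics) + 0.5) * self.dt_dynamic_s

    @property
    def pet_frame_starts(self) -> np.ndarray:
        return self.pet_frame_schedule[:, 0]

    @property
    def pet_frame_durations(self) -> np.ndarray:
        return self.pet_frame_schedule[:, 1]


DWI_B_VALUES = (0.0, 20.0, 50.0, 80.0, 200.0, 300.0, 500.0, 800.0, 1500.0, 2000.0)


def default_dwi_protocol() -> AcquisitionProtocol:
    """Ten-b-value diffusion protocol (b = 0 ... 2000 s/mm^2), two signal
    averages (NA = 2)."""
    return AcquisitionProtocol(b_values=np.array(DWI_B_VALUES), n_averages=2)


def default_dce_protocol() -> AcquisitionProtocol:
    """SPGR protocol: flip angles 5/15/30 deg, TR/TE = 7/2.7 ms, 40 dynamic
    frames at 8 s with a 15 deg dynamic flip angle and 6 pre-contrast frames."""
    return AcquisitionProtocol()


def _dynamic_pet_frames() -> np.ndarray:
    """30-min dynamic binning: 6x5 s, 3x10 s, 4x60 s, 2x150 s, 2x300 s, 1x600 s,
    plus 10-min statics starting at ~90 and ~160 min post injection."""
    durations = [5.0] * 6 + [10.0] * 3 + [60.0] * 4 + [150.0] * 2 + [300.0] * 2 + [600.0]
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    dyn = np.column_stack([starts, durations])
    statics = np.array([[90.0 * 60.0, 600.0], [160.0 * 60.0, 600.0]])
    return np.vstack([dyn, statics])


def default_pet_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol(
        pet_frame_schedule=_dynamic_pet_frames(),
        static_times_min=(90.0, 160.0),
    )


# --------------------------------------------------------------------------
# canonical metric table layout and published summary statistics
# --------------------------------------------------------------------------

#: Canonical lesion-level metric columns, in fixed order.  "Vt-PET"/"Vt-MRI"
#: are the PET- and T2w-MRI-derived tumor volumes (cm^3); the remainder are the
#: kinetic and static quantitative-imaging metrics.
METRIC_NAMES: tuple[str, ...] = (
    "Vt-PET", "Vt-MRI", "ADC", "D", "D*", "f", "Ktrans", "ve", "tau_i", "kep",
    "SULmax", "SULmean", "K1", "k3max", "k3mean", "DV", "TBRmax", "TBRmean",
)

#: Metrics bounded in (0, 1); these get logit-normal marginals in the
#: synthetic cohort, everything else log-normal.
FRACTION_METRICS: frozenset[str] = frozenset({"f", "ve", "vb"})

#: Published cohort summary statistics (mean, SD) per metric, used as the
#: default marginal distributions of the synthetic cohort.  ADC/D/D* are in
#: mm^2/s, Ktrans/K1/k3/kep in 1/min, tau_i in s, volumes in cm^3; SUL, TBR,
#: DV and f/ve are dimensionless.
TABLE1_MARGINALS: dict[str, tuple[float, float]] = {
    "SULmax": (8.91, 3.94),
    "SULmean": (5.26, 2.76),
    "K1": (0.33, 0.15),
    "k3max": (0.0087, 0.0049),
    "k3mean": (0.0034, 0.0021),
    "TBRmax": (1.76, 0.53),
    "TBRmean": (1.29, 0.27),
    "DV": (0.89, 0.14),
    "ADC": (0.93e-3, 0.14e-3),
    "D": (0.67e-3, 0.13e-3),
    "D*": (9.02e-3, 1.80e-3),
    "f": (0.16, 0.06),
    "Ktrans": (0.18, 0.06),
    "ve": (0.32, 0.09),
    "tau_i": (0.670, 0.15),
    "Vt-PET": (13.59, 7.65),
    "Vt-MRI": (11.41, 10.09),
}


# --------------------------------------------------------------------------
# deterministic random streams
# --------------------------------------------------------------------------

def rng_for(seed: int, *stream: int | str) -> np.random.Generator:
    """Independent, reproducible generator for a named sub-stream of ``seed``.

    String stream components are hashed stably (by bytes) so call sites can
    name their streams without coordinating integer ids.
    """
    entropy: list[int] = [int(seed)]
    for s in stream:
        if isinstance(s, str):
            entropy.extend(s.encode())
        else:
            entropy.append(int(s))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(seed: int, *stream: int | str) -> int:
    """A 31-bit integer seed derived from ``seed`` and the stream name."""
    return int(rng_for(seed, *stream).integers(0, 2**31 - 1))
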