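"""Synthetic 16-channel plantar-pressure generator with ground-truth phases.

One gait cycle is normalized to [0, 1); the stance portion (default 62%) is
split into heel strike, foot flat, midstance, heel off and toe off, followed
by an all-zero swing.  Each anatomical zone carries a flat-topped bump with
short half-cosine tapers (a Tukey-style window): the plateau makes every
sensor reach its configured peak exactly and gives the first-order sensor
dynamics time to settle, while the tapers keep threshold crossings within a
frame or two of the nominal phase boundaries.

Sensor coordinates are not published anywhere; the table in
:func:`default_layout` places the 16 sensors by anatomical zone on a
250 mm x 85 mm (EU size 39) outline with the heel at y = 0.  All
center-of-pressure results are defined relative to this table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, FormatError, PressureRangeError
from .sensor_model import (
    DEFAULT_P_MAX,
    PressureTrace,
    SensorSpec,
    simulate_capacitance_trace,
)

__all__ = [
    "SENSOR_IDS",
    "ZONES",
    "PHASE_ORDER",
    "SWING",
    "SensorPosition",
    "InsoleLayout",
    "GaitSpec",
    "PressureFrameSeries",
    "default_layout",
    "default_peak_table",
    "simulate_gait",
    "to_capacitance",
]

#: Canonical channel order used by frames, CSV files and layouts.
SENSOR_IDS = (
    "T1", "T2", "T3", "T4",
    "ME1", "ME2", "ME3", "ME4", "ME5",
    "M1", "M2", "M3", "M4",
    "H1", "H2", "H3",
)

#: Anatomical zone -> member sensor ids.
ZONES = {
    "phalanges": ("T1", "T2", "T3", "T4"),
    "metatarsals": ("ME1", "ME2", "ME3", "ME4", "ME5"),
    "plantar_arch": ("M1", "M2", "M3", "M4"),
    "calcaneus": ("H1", "H2", "H3"),
}

ZONE_OF = {sid: zone for zone, ids in ZONES.items() for sid in ids}

#: Stance phases in canonical order; ``SWING`` closes the cycle.
PHASE_ORDER = ("heel_strike", "foot_flat", "midstance", "heel_off", "toe_off")
SWING = "swing"

INSOLE_LENGTH_MM = 250.0
INSOLE_WIDTH_MM = 85.0


@dataclass(frozen=True)
class SensorPosition:
    sensor_id: str
    zone: str
    x_mm: float
    y_mm: float


@dataclass(frozen=True)
class InsoleLayout:
    """Planar sensor arrangement inside the insole outline.

    x runs across the width, y along the length with the heel at y = 0.
    """

    sensors: tuple
    insole_length: float = INSOLE_LENGTH_MM
    insole_width: float = INSOLE_WIDTH_MM

    def __post_init__(self) -> None:
        ids = [s.sensor_id for s in self.sensors]
        if sorted(ids) != sorted(SENSOR_IDS):
            raise ConfigurationError("layout must contain exactly the 16 canonical sensors")
        for s in self.sensors:
            if ZONE_OF[s.sensor_id] != s.zone:
                raise ConfigurationError(f"sensor {s.sensor_id} assigned to wrong zone {s.zone}")
            if not (0 <= s.x_mm <= self.insole_width and 0 <= s.y_mm <= self.insole_length):
                raise ConfigurationError(f"sensor {s.sensor_id} outside the insole outline")

    @property
    def sensor_ids(self) -> tuple:
        return tuple(s.sensor_id for s in self.sensors)

    def position(self, sensor_id: str) -> SensorPosition:
        for s in self.sensors:
            if s.sensor_id == sensor_id:
                return s
        raise KeyError(sensor_id)

    def coordinates(self, order=SENSOR_IDS) -> np.ndarray:
        """(n, 2) array of (x, y) in mm in the requested channel order."""
        pos = {s.sensor_id: (s.x_mm, s.y_mm) for s in self.sensors}
        return np.array([pos[sid] for sid in order], dtype=float)


# Fixed coordinate table (mm).  Invented but anatomically ordered: heel
# sensors in the posterior 25% of the length, phalanges in the anterior 20%.
_DEFAULT_COORDS = {
    "H1": (42.0, 28.0), "H2": (29.0, 52.0), "H3": (55.0, 52.0),
    "M1": (30.0, 95.0), "M2": (52.0, 100.0), "M3": (33.0, 125.0), "M4": (54.0, 130.0),
    "ME1": (14.0, 168.0), "ME2": (29.0, 174.0), "ME3": (44.0, 178.0),
    "ME4": (57.0, 181.0), "ME5": (68.0, 183.0),
    "T1": (45.0, 228.0), "T2": (30.0, 224.0), "T3": (18.0, 216.0), "T4": (63.0, 222.0),
}


def default_layout() -> InsoleLayout:
    """The layout shipped with the package (16 sensors, 4 zones)."""
    sensors = tuple(
        SensorPosition(sid, ZONE_OF[sid], *_DEFAULT_COORDS[sid]) for sid in SENSOR_IDS
    )
    return InsoleLayout(sensors)


def default_peak_table() -> dict:
    """Default per-sensor peak pressures in kPa.

    Headline values: H1 = 295, T1 = 370, ME5 = 380, T4 = 127; the middle-toe
    sensors T2/T3 bear no pressure and the arch stays below 150 kPa.
    """
    return {
        "H1": 295.0, "H2": 250.0, "H3": 240.0,
        "M1": 90.0, "M2": 120.0, "M3": 110.0, "M4": 80.0,
        "ME1": 180.0, "ME2": 220.0, "ME3": 260.0, "ME4": 300.0, "ME5": 380.0,
        "T1": 370.0, "T2": 0.0, "T3": 0.0, "T4": 127.0,
    }


def _default_phase_timing() -> dict:
    return {
        "heel_strike": 0.0,
        "foot_flat": 0.12,
        "midstance": 0.30,
        "heel_off": 0.38,
        "toe_off": 0.50,
    }


@dataclass
class GaitSpec:
    """Parameters of the synthetic gait cycle.

    ``phase_timing`` maps each stance phase to its fractional onset within
    the cycle; swing starts at ``stance_fraction``.  ``taper`` is the
    half-cosine edge width of the zone bumps, as a fraction of the cycle.
    """

    cycle_duration: float = 1.5
    stance_fraction: float = 0.62
    peak_table: dict = field(default_factory=default_peak_table)
    phase_timing: dict = field(default_factory=_default_phase_timing)
    taper: float = 0.01
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cycle_duration <= 0:
            raise ConfigurationError("cycle_duration must be > 0")
        if not (0 < self.stance_fraction < 1):
            raise ConfigurationError("stance_fraction must lie in (0, 1)")
        if set(self.phase_timing) != set(PHASE_ORDER):
            raise ConfigurationError(f"phase_timing must define exactly {PHASE_ORDER}")
        onsets = [self.phase_timing[p] for p in PHASE_ORDER]
        if any(b <= a for a, b in zip(onsets, onsets[1:])) or onsets[0] < 0:
            raise ConfigurationError("phase onsets must be non-negative and strictly increasing")
        if onsets[-1] >= self.stance_fraction:
            raise ConfigurationError("last phase onset must precede the swing phase")
        if set(self.peak_table) != set(SENSOR_IDS):
            raise ConfigurationError("peak_table must cover exactly the 16 canonical sensors")
        for sid, peak in self.peak_table.items():
            if peak < 0:
                raise ConfigurationError(f"negative peak for {sid}")
            if peak > DEFAULT_P_MAX:
                raise PressureRangeError(
                    f"peak {peak} kPa for {sid} exceeds the {DEFAULT_P_MAX} kPa working range"
                )

    @property
    def cadence(self) -> float:
        """Cycles per minute."""
        return 60.0 / self.cycle_duration

    def zone_windows(self) -> dict:
        """Zone activation windows as (start, end) cycle fractions.

        The heel window starts half a taper before heel strike so the heel
        is already loaded on the very first frame of the cycle; the arch
        window extends a little past heel-off onset but the arch never
        dominates there.
        """
        ft = self.phase_timing
        return {
            "calcaneus": (ft["heel_strike"] - self.taper / 2, ft["midstance"]),
            "metatarsals": (ft["foot_flat"], ft["toe_off"]),
            "plantar_arch": (ft["foot_flat"], ft["heel_off"] + 0.04),
            "phalanges": (ft["heel_off"], self.stance_fraction),
        }


@dataclass
class PressureFrameSeries:
    """Time-ordered 16-channel pressure frames in kPa.

    ``frames`` has shape (n_frames, 16) in ``sensor_ids`` order; ``labels``
    is an optional per-frame phase tag and ``below_lod`` an optional per
    frame/channel flag set by calibration.
    """

    sample_rate: float
    frames: np.ndarray
    sensor_ids: tuple = SENSOR_IDS
    labels: list | None = None
    start_time: float = 0.0
    below_lod: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.sample_rate <= 0:
            raise FormatError("sample_rate must be > 0")
        if self.frames.ndim != 2 or self.frames.shape[1] != len(self.sensor_ids):
            raise FormatError("frames must be (n_frames, n_sensors)")
        if self.frames.size and (not np.all(np.isfinite(self.frames)) or self.frames.min() < 0):
            raise FormatError("frame values must be finite and >= 0")
        if self.labels is not None and len(self.labels) != len(self.frames):
            raise FormatError("labels must match the number of frames")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.frames)) / self.sample_rate

    def channel(self, sensor_id: str) -> np.ndarray:
        return self.frames[:, self.sensor_ids.index(sensor_id)]


def _bump(u: np.ndarray, a: float, b: float, r: float) -> np.ndarray:
    """Flat-topped unit bump on [a, b] with half-cosine tapers of width r."""
    out = np.zeros_like(u)
    if b <= a:
        return out
    r = min(r, (b - a) / 2)
    rise = (u >= a) & (u < a + r)
    out[rise] = 0.5 * (1 - np.cos(np.pi * (u[rise] - a) / r))
    out[(u >= a + r) & (u <= b - r)] = 1.0
    fall = (u > b - r) & (u <= b)
    out[fall] = 0.5 * (1 - np.cos(np.pi * (b - u[fall]) / r))
    return out


def _phase_of(u: float, spec: GaitSpec) -> str:
    if u >= spec.stance_fraction:
        return SWING
    label = PHASE_ORDER[0]
    for phase in PHASE_ORDER:
        if u >= spec.phase_timing[phase]:
            label = phase
    return label


def simulate_gait(
    spec: GaitSpec | None = None,
    layout: InsoleLayout | None = None,
    n_cycles: int = 3,
    sample_rate: float = 100.0,
) -> PressureFrameSeries:
    """Simulate ``n_cycles`` gait cycles of 16-channel plantar pressure.

    Noiseless channels reach their ``peak_table`` maxima exactly; ground
    truth phase labels are attached per frame.  Deterministic for a fixed
    ``spec.seed`` when ``spec.noise_sd > 0``.
    """
    spec = spec or GaitSpec()
    layout = layout or default_layout()
    if n_cycles < 1:
        raise ConfigurationError("n_cycles must be >= 1")
    n_per_cycle = int(round(spec.cycle_duration * sample_rate))
    u_cycle = np.arange(n_per_cycle) / n_per_cycle
    windows = spec.zone_windows()
    cycle_frames = np.zeros((n_per_cycle, len(SENSOR_IDS)))
    for j, sid in enumerate(SENSOR_IDS):
        a, b = windows[ZONE_OF[sid]]
        cycle_frames[:, j] = spec.peak_table[sid] * _bump(u_cycle, a, b, spec.taper)
    frames = np.tile(cycle_frames, (n_cycles, 1))
    labels = [_phase_of(u, spec) for u in u_cycle] * n_cycles
    if spec.noise_sd > 0:
        if spec.seed is None:
            raise ConfigurationError("a seed is required for noisy simulation")
        rng = np.random.default_rng(spec.seed)
        frames = np.clip(frames + rng.normal(0.0, spec.noise_sd, frames.shape), 0.0, None)
    return PressureFrameSeries(sample_rate, frames, SENSOR_IDS, labels)


def to_capacitance(
    frames: PressureFrameSeries,
    specs,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> dict:
    """Convert a frame series to 16 raw capacitance traces.

    ``specs`` is one :class:`SensorSpec` (replicated) or a sequence of 16, in
    ``frames.sensor_ids`` order; the in-insole profile is the natural choice.
    Per-channel noise streams are spawned from ``seed`` so a single integer
    reproduces the whole multichannel acquisition.
    """
    if isinstance(specs, SensorSpec):
        specs = [specs] * len(frames.sensor_ids)
    specs = list(specs)
    if len(specs) != len(frames.sensor_ids):
        raise ConfigurationError(
            f"need {len(frames.sensor_ids)} sensor specs, got {len(specs)}"
        )
    if noise_sd > 0 and seed is None:
        raise ConfigurationError("a seed is required for noisy simulation")
    child_seeds = (
        np.random.SeedSequence(seed).spawn(len(specs)) if noise_sd > 0 else [None] * len(specs)
    )
    traces = {}
    for j, (sid, sensor_spec) in enumerate(zip(frames.sensor_ids, specs)):
        ptrace = PressureTrace(frames.sample_rate, frames.frames[:, j], frames.start_time)
        traces[sid] = simulate_capacitance_trace(
            ptrace, sensor_spec, noise_sd=noise_sd, seed=child_seeds[j]
        )
    return traces
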